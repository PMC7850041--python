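"""Spectral-power subsequent memory effects (SMEs).

Pipeline: bipolar referencing and 60 Hz notch filtering, complex Morlet
decomposition (wave number 5) on buffered epochs, session-normalized
log-power features in the 400-1100 ms encoding window, a Welch t
contrast (recalled minus not-recalled) per electrode and frequency,
aggregation to region x band cells, and BH-FDR-corrected group
contrasts on the cells.

Sign convention throughout: positive t means *more* power during
successful encoding.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import signal, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import EpochTensor, SchemaError

__all__ = [
    "DEFAULT_SME_FREQS",
    "THETA_BAND",
    "HFA_BAND",
    "preprocess",
    "morlet_wavelet",
    "morlet_transform",
    "morlet_power",
    "encoding_power_features",
    "power_sme",
    "band_region_sme",
    "group_sme_contrast",
]

#: 20 wavelet centre frequencies, log-spaced on [3, 170] Hz inclusive.
DEFAULT_SME_FREQS = np.logspace(np.log10(3.0), np.log10(170.0), 20)

THETA_BAND = (4.0, 8.0)
HFA_BAND = (45.0, 170.0)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def preprocess(
    epochs: EpochTensor,
    electrodes: pd.DataFrame,
    montage: str = "bipolar",
    notch_hz: float = 60.0,
    require_hfa: bool = True,
) -> tuple[EpochTensor, pd.DataFrame]:
    """Reference, notch-filter and prune an epoch tensor.

    Monopolar montages are re-referenced to neighbour differences
    (channel i minus channel i+1 within the table order); already
    bipolar input passes through unchanged.  Line noise is removed with
    a zero-phase 4th-order Butterworth band-stop (58-62 Hz), and
    channels flagged ``excluded`` are dropped.
    """
    if require_hfa and epochs.fs < 2 * HFA_BAND[1]:
        raise SchemaError(
            f"fs={epochs.fs} too low for high-frequency analyses (need >= {2 * HFA_BAND[1]})"
        )
    elec = electrodes.reset_index(drop=True)
    keep = np.flatnonzero(~elec["excluded"].to_numpy(dtype=bool))
    epochs = epochs.select_channels(keep)
    elec = elec.iloc[keep].reset_index(drop=True)

    if montage == "monopolar":
        data = epochs.data[:, :-1, :] - epochs.data[:, 1:, :]
        labels = [f"{a}-{b}" for a, b in zip(elec["channel"][:-1], elec["channel"][1:])]
        epochs = replace(epochs, data=data, channels=labels)
        elec = elec.iloc[:-1].copy()
        elec["channel"] = labels
        elec = elec.reset_index(drop=True)
    elif montage != "bipolar":
        raise ValueError(f"unknown montage {montage!r}")

    sos = signal.butter(
        4, [notch_hz - 2.0, notch_hz + 2.0], btype="bandstop", fs=epochs.fs, output="sos"
    )
    data = signal.sosfiltfilt(sos, epochs.data, axis=-1)
    return replace(epochs, data=data), elec


# ---------------------------------------------------------------------------
# Morlet decomposition
# ---------------------------------------------------------------------------

def morlet_wavelet(freq: float, fs: float, wave_number: int = 5) -> np.ndarray:
    """Complex Morlet wavelet: a complex exponential under a Gaussian
    envelope with SD ``wave_number / (2 pi f)``, truncated at 3.5 SD and
    L1-normalized so a unit sinusoid at the centre frequency yields a
    response of order one."""
    sigma_t = wave_number / (2.0 * np.pi * freq)
    half = int(np.ceil(3.5 * sigma_t * fs))
    t = np.arange(-half, half + 1) / fs
    envelope = np.exp(-(t ** 2) / (2.0 * sigma_t ** 2))
    w = envelope * np.exp(2j * np.pi * freq * t)
    return w / envelope.sum()


def morlet_transform(
    epochs: EpochTensor,
    freqs: np.ndarray,
    wave_number: int = 5,
) -> tuple[np.ndarray, np.ndarray]:
    """Complex Morlet coefficients, buffer trimmed after convolution.

    Convolution is done in the frequency domain with the FFT of the
    data computed once and shared across wavelet frequencies.  Returns
    ``(coeffs, times)`` with ``coeffs`` of shape ``items x channels x
    freqs x samples`` and ``times`` in seconds relative to item onset.
    """
    from scipy import fft as sp_fft

    freqs = np.asarray(freqs, dtype=float)
    nyq = epochs.fs / 2.0
    if np.any(freqs >= nyq):
        raise SchemaError(f"wavelet frequency >= Nyquist ({nyq} Hz)")
    sigma_lo = wave_number / (2.0 * np.pi * freqs.min())
    if epochs.buffer < 3.0 * sigma_lo:
        raise SchemaError(
            f"epoch buffer {epochs.buffer:.3f}s < 3 wavelet SDs "
            f"({3.0 * sigma_lo:.3f}s) at {freqs.min():.2f} Hz"
        )
    n = epochs.n_samples
    n_buf = int(round(epochs.buffer * epochs.fs))
    n_keep = n - 2 * n_buf
    wavelets = [morlet_wavelet(f, epochs.fs, wave_number) for f in freqs]
    nfft = sp_fft.next_fast_len(n + max(len(w) for w in wavelets) - 1)
    D = sp_fft.fft(epochs.data, nfft, axis=-1)
    out = np.empty(
        (epochs.n_items, epochs.n_channels, len(freqs), n_keep), dtype=complex
    )
    for k, w in enumerate(wavelets):
        W = sp_fft.fft(w, nfft)
        conv = sp_fft.ifft(D * W, axis=-1)
        # 'same'-mode alignment: drop the wavelet half-length lead
        start = len(w) // 2 + n_buf
        out[:, :, k, :] = conv[:, :, start : start + n_keep]
    times = epochs.tmin + epochs.buffer + np.arange(n_keep) / epochs.fs
    return out, times


def morlet_power(
    epochs: EpochTensor, freqs: np.ndarray, wave_number: int = 5
) -> tuple[np.ndarray, np.ndarray]:
    """Wavelet power (squared magnitude), buffer trimmed."""
    coeffs, times = morlet_transform(epochs, freqs, wave_number)
    return (coeffs.real ** 2 + coeffs.imag ** 2), times


# ---------------------------------------------------------------------------
# features and contrasts
# ---------------------------------------------------------------------------

def _window_mask(times: np.ndarray, window: tuple) -> np.ndarray:
    dt = np.median(np.diff(times))
    return (times >= window[0] - dt / 2) & (times <= window[1] + dt / 2)


def encoding_power_features(
    power: np.ndarray,
    times: np.ndarray,
    sessions: np.ndarray,
    window: tuple = (0.400, 1.100),
) -> np.ndarray:
    """Session-normalized log-power features for the encoding window.

    Power is log-transformed, averaged over ``window``, then z-scored
    over items within each session for every channel x frequency, giving
    one value per item/channel/frequency with exact zero mean and unit
    SD per session.  Constant (zero-variance) cells map to 0.
    """
    sessions = np.asarray(sessions)
    if power.shape[0] != len(sessions):
        raise SchemaError("power item axis does not match session labels")
    mask = _window_mask(times, window)
    if not mask.any():
        raise SchemaError(f"window {window} outside epoch times")
    logp = np.log(np.clip(power[..., mask], 1e-300, None)).mean(axis=-1)
    feats = np.empty_like(logp)
    for sess in np.unique(sessions):
        idx = sessions == sess
        if idx.sum() < 2:
            raise SchemaError(f"session {sess!r} has <2 items; z-score undefined")
        x = logp[idx]
        mu = x.mean(axis=0)
        sd = x.std(axis=0, ddof=0)
        bad = sd == 0
        if bad.any():
            warnings.warn("constant power in some session cells; features set to 0")
            sd = np.where(bad, 1.0, sd)
        feats[idx] = (x - mu) / sd
    return feats


def power_sme(features: np.ndarray, recalled: np.ndarray) -> np.ndarray:
    """Welch t (recalled minus not-recalled) per channel x frequency."""
    recalled = np.asarray(recalled, dtype=bool)
    if recalled.sum() < 2 or (~recalled).sum() < 2:
        raise SchemaError("need >= 2 items in each recall class")
    t, _ = stats.ttest_ind(features[recalled], features[~recalled],
                           axis=0, equal_var=False)
    return t


def band_region_sme(
    t_stats: np.ndarray,
    freqs: np.ndarray,
    electrodes: pd.DataFrame,
    bands: dict | None = None,
) -> pd.DataFrame:
    """Mean SME t within each region x band cell.

    A grid frequency belongs to a band by closed-interval membership;
    regions with no channels yield NaN cells.
    """
    if bands is None:
        bands = {"theta": THETA_BAND, "hfa": HFA_BAND}
    freqs = np.asarray(freqs)
    regions = [r for r in electrodes["region"].unique()]
    rows = {}
    for region in regions:
        ch_idx = np.flatnonzero((electrodes["region"] == region).to_numpy())
        rows[region] = {}
        for band, (lo, hi) in bands.items():
            f_idx = np.flatnonzero((freqs >= lo) & (freqs <= hi))
            if len(ch_idx) == 0 or len(f_idx) == 0:
                rows[region][band] = np.nan
            else:
                rows[region][band] = float(np.nanmean(t_stats[np.ix_(ch_idx, f_idx)]))
    return pd.DataFrame(rows).T


def group_sme_contrast(
    cells: dict[str, pd.DataFrame],
    groups: pd.Series,
) -> pd.DataFrame:
    """Welch t + BH-FDR q per region x band cell, contrasting groups.

    ``cells`` maps subject id to a region x band DataFrame; all cells
    are corrected jointly by Benjamini-Hochberg step-up.
    """
    subjects = list(cells)
    g = groups.reindex(subjects)
    levels = sorted(g.dropna().unique())
    if len(levels) != 2:
        raise ValueError("exactly two groups required")
    for lv in levels:
        if (g == lv).sum() < 2:
            raise ValueError(f"group {lv!r} has <2 subjects")
    template = cells[subjects[0]]
    records = []
    for region in template.index:
        for band in template.columns:
            a = np.array([cells[s].loc[region, band] for s in subjects if g[s] == levels[0]])
            b = np.array([cells[s].loc[region, band] for s in subjects if g[s] == levels[1]])
            a, b = a[np.isfinite(a)], b[np.isfinite(b)]
            if len(a) < 2 or len(b) < 2:
                t, p = np.nan, np.nan
            else:
                t, p = stats.ttest_ind(a, b, equal_var=False)
            records.append({"region": region, "band": band,
                            "t": float(t), "p": float(p)})
    res = pd.DataFrame(records)
    ok = res["p"].notna()
    q = np.full(len(res), np.nan)
    if ok.any():
        q[ok.to_numpy()] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    res["q"] = q
    return res
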