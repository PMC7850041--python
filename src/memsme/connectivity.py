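"""Theta phase-locking connectivity networks with permutation nulls.

For every electrode pair, phase differences in the 400-1100 ms encoding
window are summarized per item by their circular mean at five theta
frequencies (4-8 Hz).  The phase-locking value (PLV) — the modulus of
the mean unit phasor over items — is computed separately for recalled
and not-recalled items; the connectivity subsequent-memory effect is
the PLV difference averaged over the five frequencies.  Its null
distribution comes from shuffling the recalled labels (one shared
shuffle sequence across all pairs, class sizes preserved), yielding a
permutation Z-score per pair that serves as the network edge weight.
"""

from __future__ import annotations

import warnings
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EpochTensor, SchemaError
from .spectral import morlet_transform

__all__ = [
    "THETA_FREQS",
    "item_phase_difference",
    "plv",
    "plv_by_class",
    "connectivity_sme_z",
    "roi_edges",
    "group_network_tests",
    "display_network",
]

#: The five theta-band wavelet frequencies, Hz.
THETA_FREQS = np.array([4.0, 5.0, 6.0, 7.0, 8.0])

DISPLAY_Z = 1.96  # |Z| threshold for exported display networks


def _unit(x: np.ndarray) -> np.ndarray:
    mag = np.abs(x)
    mag[mag == 0] = 1.0
    return x / mag


def _windowed_unit_phasors(
    epochs: EpochTensor,
    freqs: np.ndarray,
    window: tuple,
    wave_number: int = 5,
) -> np.ndarray:
    """Unit-modulus wavelet coefficients in the window,
    ``items x channels x freqs x samples`` (complex64)."""
    coeffs, times = morlet_transform(epochs, freqs, wave_number)
    dt = 1.0 / epochs.fs
    mask = (times >= window[0] - dt / 2) & (times <= window[1] + dt / 2)
    if not mask.any():
        raise SchemaError(f"window {window} outside epoch")
    return _unit(coeffs[..., mask]).astype(np.complex64)


def _pair_phasors(V: np.ndarray, pairs: list[tuple[int, int]]) -> np.ndarray:
    """Per-item circular-mean phase-difference unit phasors.

    Returns ``pairs x items x freqs`` complex with unit modulus; the
    angle is the circular mean over window samples of phi_a - phi_b.
    """
    out = np.empty((len(pairs), V.shape[0], V.shape[2]), dtype=complex)
    for k, (a, b) in enumerate(pairs):
        out[k] = _unit((V[:, a] * np.conj(V[:, b])).mean(axis=-1))
    return out


def item_phase_difference(
    epochs: EpochTensor,
    pair: tuple[int, int],
    freqs: np.ndarray = THETA_FREQS,
    window: tuple = (0.400, 1.100),
    wave_number: int = 5,
) -> np.ndarray:
    """Per-item circular-mean phase difference (radians), items x freqs."""
    V = _windowed_unit_phasors(epochs, np.asarray(freqs, float), window, wave_number)
    return np.angle(_pair_phasors(V, [tuple(pair)])[0])


def plv(phase_diffs: np.ndarray, axis: int = 0) -> np.ndarray:
    """Phase-locking value: modulus of the mean unit phasor over items."""
    return np.abs(np.mean(np.exp(1j * np.asarray(phase_diffs)), axis=axis))


def plv_by_class(phase_diffs: np.ndarray, recalled: np.ndarray) -> dict:
    """PLV per recall class per frequency from items x freqs angles."""
    recalled = np.asarray(recalled, dtype=bool)
    if recalled.sum() < 2 or (~recalled).sum() < 2:
        raise SchemaError("need >= 2 items in each recall class")
    return {
        "recalled": plv(phase_diffs[recalled], axis=0),
        "not_recalled": plv(phase_diffs[~recalled], axis=0),
    }


def connectivity_sme_z(
    epochs: EpochTensor,
    electrodes: pd.DataFrame,
    recalled: np.ndarray,
    n_perm: int = 500,
    rng_seed: int = 0,
    pairs: list[tuple[int, int]] | None = None,
    freqs: np.ndarray = THETA_FREQS,
    window: tuple = (0.400, 1.100),
) -> pd.DataFrame:
    """Permutation Z-score of the theta connectivity SME per pair.

    The observed SME is PLV(recalled) - PLV(not recalled) averaged over
    the five theta frequencies; the null shuffles the recalled labels
    ``n_perm`` times, the *same* shuffle sequence for every pair so that
    cross-pair dependence is preserved.  Returns one row per channel
    pair with columns ``chan_a, chan_b, region_a, region_b, sme, z``.
    """
    recalled = np.asarray(recalled, dtype=bool)
    n_items = len(recalled)
    if recalled.sum() < 2 or (~recalled).sum() < 2:
        raise SchemaError("need >= 2 items in each recall class")
    elec = electrodes.reset_index(drop=True)
    usable = np.flatnonzero(~elec["excluded"].to_numpy(dtype=bool))
    if len(usable) < 2:
        raise SchemaError("need >= 2 usable channels")
    if pairs is None:
        pairs = list(combinations(usable.tolist(), 2))

    # transform only the channels the pairs touch
    used = sorted({c for p in pairs for c in p})
    remap = {c: i for i, c in enumerate(used)}
    V = _windowed_unit_phasors(
        epochs.select_channels(np.asarray(used)), np.asarray(freqs, float), window
    )
    U = _pair_phasors(V, [(remap[a], remap[b]) for a, b in pairs])
    del V

    n_rec = int(recalled.sum())
    n_not = n_items - n_rec
    A = U.transpose(0, 2, 1).reshape(-1, n_items)   # (pairs*freqs) x items
    total = A.sum(axis=1, keepdims=True)

    def _sme(ind: np.ndarray) -> np.ndarray:
        """ind: items x k indicator of the recalled class."""
        s_rec = A @ ind
        plv_rec = np.abs(s_rec) / n_rec
        plv_not = np.abs(total - s_rec) / n_not
        d = (plv_rec - plv_not).reshape(len(pairs), len(freqs), -1)
        return d.mean(axis=1)            # pairs x k

    obs = _sme(recalled[:, None].astype(float))[:, 0]

    rng = np.random.default_rng(rng_seed)
    ind = np.empty((n_items, n_perm))
    for j in range(n_perm):
        ind[:, j] = rng.permutation(recalled.astype(float))
    null = _sme(ind)                     # pairs x n_perm
    mu = null.mean(axis=1)
    sd = null.std(axis=1, ddof=1)
    z = np.full(len(pairs), np.nan)
    ok = sd > 0
    if not ok.all():
        warnings.warn("zero null SD for some pairs; Z set to NaN")
    z[ok] = (obs[ok] - mu[ok]) / sd[ok]

    regions = elec["region"].to_numpy()
    chans = elec["channel"].to_numpy()
    ia = np.array([p[0] for p in pairs])
    ib = np.array([p[1] for p in pairs])
    return pd.DataFrame(
        {
            "chan_a": chans[ia],
            "chan_b": chans[ib],
            "region_a": regions[ia],
            "region_b": regions[ib],
            "sme": obs,
            "z": z,
        }
    )


def roi_edges(pair_z: pd.DataFrame) -> pd.DataFrame:
    """ROI-pair edge weights: mean pair Z over channel pairs spanning
    each unordered pair of *distinct* regions."""
    df = pair_z.copy()
    ab = np.sort(df[["region_a", "region_b"]].to_numpy(), axis=1)
    df["roi_a"], df["roi_b"] = ab[:, 0], ab[:, 1]
    inter = df[df["roi_a"] != df["roi_b"]]
    out = (
        inter.groupby(["roi_a", "roi_b"])
        .agg(mean_z=("z", "mean"), n_pairs=("z", "size"))
        .reset_index()
    )
    return out


def group_network_tests(
    subject_edges: dict[str, pd.DataFrame],
    groups: pd.Series,
) -> dict:
    """Group statistics on subject mean edge weights.

    For each subject the ROI-pair edges are averaged into one scalar;
    each group's distribution is compared to zero with a one-sample
    t-test and the two groups with an independent (Welch) t-test.
    Subjects with no inter-ROI pair are excluded.
    """
    means = {}
    for subj, edges in subject_edges.items():
        if len(edges) == 0:
            warnings.warn(f"subject {subj} has no inter-ROI pairs; excluded")
            continue
        means[subj] = float(edges["mean_z"].mean())
    s = pd.Series(means, name="subject_mean_edge")
    g = groups.reindex(s.index)
    levels = sorted(g.dropna().unique())
    out: dict = {"subject_mean_edge": s}
    for lv in levels:
        vals = s[g == lv].to_numpy()
        t, p = stats.ttest_1samp(vals, 0.0)
        out[f"one_sample_{lv}"] = {"t": float(t), "p": float(p), "n": int(len(vals))}
    if len(levels) == 2:
        a, b = (s[g == lv].to_numpy() for lv in levels)
        t, p = stats.ttest_ind(a, b, equal_var=False)
        out["two_sample"] = {"t": float(t), "p": float(p), "groups": levels}
    return out


def display_network(edges: pd.DataFrame, threshold: float = DISPLAY_Z) -> pd.DataFrame:
    """Edges whose |mean Z| exceeds the display threshold (default 1.96)."""
    return edges[np.abs(edges["mean_z"]) > threshold].reset_index(drop=True)
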