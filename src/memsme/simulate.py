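"""Synthetic delayed free-recall iEEG generator with injectable effects.

The generator emulates the structure of a multi-session delayed
free-recall experiment: each session presents up to 25 scored lists of
12 items (the first, practice, list of a real session is never scored
and is therefore not generated), items are recalled with a
serial-position-dependent probability, and the recall *order* follows a
sequential softmax sampler whose weights favour small temporal lags and
same-category transitions.  Epoched voltage is 1/f-shaped noise plus
band-limited components whose amplitudes depend on the recalled label,
so that every downstream statistic (spectral subsequent-memory effects,
theta phase-locking networks, classifier AUC) has a known ground truth.

All randomness flows through :class:`numpy.random.Generator` seeded
explicitly; identical seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import DEFAULT_REGIONS, EpochTensor, validate_events

__all__ = [
    "SimConfig",
    "EffectTruth",
    "SubjectDataset",
    "default_recall_base",
    "generate_behavioral_session",
    "generate_eeg_epochs",
    "generate_electrode_table",
    "generate_subject_dataset",
    "generate_cohort_table",
    "COHORT_DESIGN_COLUMNS",
]


def default_recall_base(n_positions: int = 12) -> np.ndarray:
    """Default per-position recall probability: a primacy advantage that
    decays over the list, with no recency boost (the post-list distractor
    of delayed free recall suppresses recency)."""
    pos = np.arange(n_positions)
    return 0.25 + 0.35 * np.exp(-pos / 2.5)


@dataclass
class SimConfig:
    """Structural parameters of the simulated experiment."""

    n_subjects_per_group: int = 10
    n_sessions: int = 1
    n_lists: int = 25          # scored lists per session (practice excluded)
    items_per_list: int = 12
    task_variant: str = "unrelated"
    fs: float = 500.0
    n_channels: int = 10
    region_labels: tuple = DEFAULT_REGIONS
    epoch_window: tuple = (-0.2, 1.5)   # s relative to item onset, pre-buffer
    buffer: float = 1.0                 # s of padding at each end
    rng_seed: int = 0

    def __post_init__(self):
        if self.items_per_list != 12:
            raise ValueError("items_per_list must be 12")
        if self.task_variant not in ("unrelated", "categorized"):
            raise ValueError(f"unknown task_variant {self.task_variant!r}")
        if self.fs < 2 * 180:
            raise ValueError("fs must cover the 180 Hz analysis ceiling (>= 360 Hz)")
        if self.epoch_window[1] <= self.epoch_window[0]:
            raise ValueError("empty epoch window")


@dataclass
class EffectTruth:
    """Injectable effect sizes; zeros give a fully exchangeable null.

    Power deltas are expressed in approximate z-units of the downstream
    session-normalized log-power features: the amplitude of the
    corresponding band component is multiplied by
    ``exp(delta * scale / 2)`` on recalled items, where the per-band
    ``*_effect_scale`` constants equal the typical item-to-item SD of
    windowed band log power under the default settings, so a delta of
    1 shifts the z-scored feature by roughly one SD.
    """

    recall_base: np.ndarray = field(default_factory=default_recall_base)
    temporal_clustering_strength: float = 0.0
    semantic_clustering_strength: float = 0.0
    theta_power_delta: float = 0.0      # negative = theta decrease when recalled
    hfa_power_delta: float = 0.0        # positive = broadband increase when recalled
    sync_pairs: tuple = ()              # channel-index pairs with injected coupling
    sync_plv_delta: float = 0.0         # target PLV(recalled) - PLV(not)
    base_plv: float = 0.2
    noise_exponent: float = 1.0
    theta_amp: float = 1.5
    hfa_amp: float = 1.0
    theta_effect_scale: float = 0.90
    hfa_effect_scale: float = 0.27
    subject_sd: float = 0.08    # SD of the per-subject recall-ability shift

    def __post_init__(self):
        self.recall_base = np.asarray(self.recall_base, dtype=float)
        if np.any((self.recall_base < 0) | (self.recall_base > 1)):
            raise ValueError("recall_base probabilities must lie in [0, 1]")
        for d in (self.theta_power_delta, self.hfa_power_delta, self.sync_plv_delta):
            if not np.isfinite(d):
                raise ValueError("effect deltas must be finite")
        if not (0.0 <= self.base_plv and self.base_plv + self.sync_plv_delta <= 1.0
                and self.base_plv + self.sync_plv_delta >= 0.0):
            raise ValueError("base_plv and sync_plv_delta must keep PLV in [0, 1]")
        if self.temporal_clustering_strength < 0 or self.semantic_clustering_strength < 0:
            raise ValueError("clustering strengths must be >= 0")


@dataclass
class SubjectDataset:
    events: pd.DataFrame
    electrodes: pd.DataFrame
    epochs: EpochTensor
    truth: EffectTruth
    subject: str = "S000"


# ---------------------------------------------------------------------------
# behaviour
# ---------------------------------------------------------------------------

def _categorized_layout(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Category label per serial position for one categorized list.

    Three categories x four exemplars arranged as successive
    same-category pairs, with successive pairs always from distinct
    categories (e.g. A A B B C C B B A A C C).  Sampled by rejection.
    """
    while True:
        pairs = rng.permutation(np.repeat(np.arange(3), 2))
        if np.all(pairs[1:] != pairs[:-1]):
            break
    cats = np.repeat(pairs, 2)
    exemplar = np.zeros(12, dtype=int)
    for c in range(3):
        exemplar[cats == c] = np.arange(4)
    return cats, exemplar


def _sample_recall_order(
    positions: np.ndarray,
    categories: np.ndarray | None,
    temporal_strength: float,
    semantic_strength: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Order the recalled items by a sequential softmax sampler.

    The first recall is drawn with weights ``exp(-s_t * (pos - 1))``
    (anchoring the deterministic limit at the list start); each later
    recall is drawn among the not-yet-recalled items with weight
    ``exp(-s_t * |lag|) * exp(s_c * same_category)``.  With both
    strengths zero the order is a uniform random permutation.
    """
    k = len(positions)
    order = np.empty(k, dtype=int)
    remaining = list(range(k))
    w = np.exp(-temporal_strength * (positions[remaining] - 1.0))
    for step in range(k):
        w = w / w.sum()
        pick = remaining[rng.choice(len(remaining), p=w)]
        order[step] = pick
        remaining.remove(pick)
        if not remaining:
            break
        lag = np.abs(positions[remaining] - positions[pick])
        logw = -temporal_strength * lag
        if categories is not None and semantic_strength > 0:
            same = categories[remaining] == categories[pick]
            logw = logw + semantic_strength * same
        logw -= logw.max()
        w = np.exp(logw)
    return order


def generate_behavioral_session(
    config: SimConfig,
    truth: EffectTruth,
    rng_seed: int,
    subject: str = "S000",
    session: int = 0,
) -> pd.DataFrame:
    """Generate one session's events table (``n_lists`` scored lists)."""
    rng = np.random.default_rng(rng_seed)
    if len(truth.recall_base) != config.items_per_list:
        raise ValueError("recall_base length must equal items_per_list")
    rows = []
    for lst in range(1, config.n_lists + 1):
        if config.task_variant == "categorized":
            cats, exemplar = _categorized_layout(rng)
            items = [f"L{lst:02d}C{c}E{e}" for c, e in zip(cats, exemplar)]
            cat_col: np.ndarray | None = cats
        else:
            items = [f"L{lst:02d}W{i:02d}" for i in range(12)]
            cat_col = None
        recalled = rng.random(12) < truth.recall_base
        out_pos = np.full(12, np.nan)
        idx = np.flatnonzero(recalled)
        if len(idx):
            order = _sample_recall_order(
                positions=np.arange(1, 13)[idx].astype(float),
                categories=cat_col[idx] if cat_col is not None else None,
                temporal_strength=truth.temporal_clustering_strength,
                semantic_strength=truth.semantic_clustering_strength,
                rng=rng,
            )
            out_pos[idx[order]] = np.arange(1, len(idx) + 1)
        for i in range(12):
            rows.append(
                {
                    "subject": subject,
                    "session": session,
                    "task_variant": config.task_variant,
                    "list": lst,
                    "serial_position": i + 1,
                    "item": items[i],
                    "category": int(cat_col[i]) if cat_col is not None else np.nan,
                    "recalled": bool(recalled[i]),
                    "output_position": out_pos[i],
                }
            )
    return validate_events(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# signals
# ---------------------------------------------------------------------------

def _shaped_noise(rng, shape, n_samples, fs, exponent):
    """1/f^exponent noise via spectral shaping of white noise, unit SD."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    gain = np.zeros_like(f)
    gain[1:] = f[1:] ** (-exponent / 2.0)
    spec *= gain
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _band_noise(rng, shape, n_samples, fs, lo, hi):
    """Band-limited unit-SD noise via a frequency-domain boxcar."""
    white = rng.standard_normal(shape + (n_samples,))
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    spec *= (f >= lo) & (f <= hi)
    x = np.fft.irfft(spec, n=n_samples, axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def generate_eeg_epochs(
    events: pd.DataFrame,
    electrodes: pd.DataFrame,
    config: SimConfig,
    truth: EffectTruth,
    rng_seed: int,
) -> EpochTensor:
    """Synthesize buffered epochs aligned 1:1 with ``events`` rows.

    Each epoch is 1/f noise plus a theta (4-8 Hz) component and a
    broadband high-frequency (45-170 Hz) component.  On recalled items
    the theta amplitude is scaled by ``exp(theta_power_delta / 2)`` and
    the high-frequency amplitude by ``exp(hfa_power_delta / 2)``.  For
    every channel pair in ``truth.sync_pairs`` the two theta components
    are replaced, on a per-item basis, by a *shared* waveform with
    probability ``base_plv`` (not recalled) or ``base_plv +
    sync_plv_delta`` (recalled), which yields an empirical PLV contrast
    close to ``sync_plv_delta``.
    """
    rng = np.random.default_rng(rng_seed)
    n_items = len(events)
    n_channels = len(electrodes)
    start = config.epoch_window[0] - config.buffer
    end = config.epoch_window[1] + config.buffer
    if config.epoch_window[1] < 1.366:
        raise ValueError(
            "epoch window must extend to 1.366 s post-onset to cover analysis windows"
        )
    n = int(round((end - start) * config.fs))
    recalled = events["recalled"].to_numpy(dtype=bool)

    data = _shaped_noise(rng, (n_items, n_channels), n, config.fs, truth.noise_exponent)

    theta_gain = np.where(
        recalled,
        np.exp(truth.theta_effect_scale * truth.theta_power_delta / 2.0), 1.0)
    hfa_gain = np.where(
        recalled,
        np.exp(truth.hfa_effect_scale * truth.hfa_power_delta / 2.0), 1.0)

    theta = _band_noise(rng, (n_items, n_channels), n, config.fs, 4.0, 8.0)

    # injected phase coupling: shared theta waveform on aligned items
    sync_channels = sorted({c for pair in truth.sync_pairs for c in pair})
    if sync_channels:
        shared = _band_noise(rng, (n_items,), n, config.fs, 4.0, 8.0)
        p_align = np.where(recalled, truth.base_plv + truth.sync_plv_delta, truth.base_plv)
        for c1, c2 in truth.sync_pairs:
            aligned = rng.random(n_items) < p_align
            theta[aligned, c1, :] = shared[aligned]
            theta[aligned, c2, :] = shared[aligned]

    hfa = _band_noise(rng, (n_items, n_channels), n, config.fs, 45.0, 170.0)

    data += truth.theta_amp * theta_gain[:, None, None] * theta
    data += truth.hfa_amp * hfa_gain[:, None, None] * hfa

    return EpochTensor(
        data=data,
        fs=config.fs,
        tmin=start,
        buffer=config.buffer,
        channels=list(electrodes["channel"]),
    )


def generate_electrode_table(config: SimConfig) -> pd.DataFrame:
    """Round-robin assignment of channels to the configured regions."""
    regions = [config.region_labels[i % len(config.region_labels)]
               for i in range(config.n_channels)]
    return pd.DataFrame(
        {
            "channel": [f"ch{i:02d}" for i in range(config.n_channels)],
            "region": regions,
            "excluded": False,
        }
    )


def generate_subject_dataset(
    config: SimConfig,
    truth: EffectTruth,
    rng_seed: int,
    subject: str = "S000",
) -> SubjectDataset:
    """Generate a full subject: events for all sessions plus epochs.

    A per-subject recall-ability shift (SD ``truth.subject_sd``) is
    added to the serial-position curve, giving the between-subject
    variance that real cohorts show (and that random-intercept models
    require).
    """
    from dataclasses import replace as _replace

    ss = np.random.SeedSequence(rng_seed)
    seeds = ss.generate_state(2 * config.n_sessions + 1)
    if truth.subject_sd > 0:
        shift = np.random.default_rng(int(seeds[-1])).normal(0, truth.subject_sd)
        truth = _replace(
            truth, recall_base=np.clip(truth.recall_base + shift, 0.02, 0.98)
        )
    frames, tensors = [], []
    electrodes = generate_electrode_table(config)
    for sess in range(config.n_sessions):
        ev = generate_behavioral_session(
            config, truth, int(seeds[2 * sess]), subject=subject, session=sess
        )
        ep = generate_eeg_epochs(ev, electrodes, config, truth, int(seeds[2 * sess + 1]))
        frames.append(ev)
        tensors.append(ep)
    events = pd.concat(frames, ignore_index=True)
    epochs = EpochTensor(
        data=np.concatenate([t.data for t in tensors], axis=0),
        fs=tensors[0].fs,
        tmin=tensors[0].tmin,
        buffer=tensors[0].buffer,
        channels=tensors[0].channels,
    )
    return SubjectDataset(events=events, electrodes=electrodes, epochs=epochs,
                          truth=truth, subject=subject)


# ---------------------------------------------------------------------------
# cohort covariates
# ---------------------------------------------------------------------------

#: Design columns (in order) matched by the coefficient vector of
#: :func:`generate_cohort_table`; the first coefficient is the intercept.
COHORT_DESIGN_COLUMNS = [
    "age",
    "sex_male",
    "hand_L",
    "hand_A",
    "prior_resection",
    "education_years",
    "seizure_onset_age",
    "cov_frontal",
    "cov_MTL",
    "cov_LTC",
    "cov_parietal",
    "soz_frontal",
    "soz_MTL",
    "soz_LTC",
    "soz_parietal",
]


def cohort_design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix (without intercept) from a cohort table.

    Continuous covariates are standardized so coefficient magnitudes are
    comparable across covariates.
    """
    X = pd.DataFrame(index=cohort.index)
    X["age"] = (cohort["age"] - 40.0) / 12.0
    X["sex_male"] = (cohort["sex"] == "M").astype(float)
    X["hand_L"] = (cohort["handedness"] == "L").astype(float)
    X["hand_A"] = (cohort["handedness"] == "A").astype(float)
    X["prior_resection"] = cohort["prior_resection"].astype(float)
    X["education_years"] = (cohort["education_years"] - 13.0) / 2.5
    X["seizure_onset_age"] = (cohort["seizure_onset_age"] - 22.0) / 12.0
    for r in DEFAULT_REGIONS:
        X[f"cov_{r}"] = cohort[f"cov_{r}"].astype(float)
        X[f"soz_{r}"] = cohort[f"soz_{r}"].astype(float)
    return X[COHORT_DESIGN_COLUMNS]


def generate_cohort_table(
    n_total: int,
    coefficients: np.ndarray,
    rng_seed: int,
) -> pd.DataFrame:
    """Draw a cohort covariate table with a logistic group model.

    ``coefficients`` has length ``1 + len(COHORT_DESIGN_COLUMNS)``
    (intercept first) and acts on the standardized design matrix.  The
    truth vector is retained in ``df.attrs['truth_coefficients']`` for
    recovery tests.
    """
    if n_total < 8:
        raise ValueError("need at least 8 subjects for matching to be defined")
    coefficients = np.asarray(coefficients, dtype=float)
    if len(coefficients) != 1 + len(COHORT_DESIGN_COLUMNS):
        raise ValueError(
            f"expected {1 + len(COHORT_DESIGN_COLUMNS)} coefficients "
            f"(intercept + {len(COHORT_DESIGN_COLUMNS)})"
        )
    rng = np.random.default_rng(rng_seed)
    df = pd.DataFrame(
        {
            "subject": [f"P{i:04d}" for i in range(n_total)],
            "age": np.clip(rng.normal(40, 12, n_total), 18, 75).round(1),
            "sex": rng.choice(["M", "F"], n_total, p=[0.55, 0.45]),
            "handedness": rng.choice(["R", "L", "A"], n_total, p=[0.80, 0.15, 0.05]),
            "prior_resection": rng.random(n_total) < 0.15,
            "education_years": np.clip(rng.normal(13.5, 2.5, n_total), 6, 22).round(1),
            "seizure_onset_age": np.clip(rng.normal(22, 12, n_total), 0, 60).round(1),
        }
    )
    for r in DEFAULT_REGIONS:
        df[f"cov_{r}"] = rng.random(n_total) < 0.7
    for r in DEFAULT_REGIONS:
        df[f"soz_{r}"] = rng.random(n_total) < 0.3
    X = cohort_design_matrix(df).to_numpy()
    eta = coefficients[0] + X @ coefficients[1:]
    p = 1.0 / (1.0 + np.exp(-eta))
    df["group"] = np.where(rng.random(n_total) < p, "case", "control")
    df.attrs["truth_coefficients"] = coefficients
    return df
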