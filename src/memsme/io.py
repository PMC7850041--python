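"""On-disk formats: TSV tables and a flat binary epoch container.

TSV dialect: tab-separated, UTF-8, header row, missing values written
as empty strings.  Epochs are stored as a raw binary array
(item x channel x sample, C order) next to a JSON sidecar recording
dtype, shape, sampling rate, window start and buffer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import (
    EpochTensor,
    SchemaError,
    check_alignment,
    validate_electrodes,
    validate_events,
)

__all__ = [
    "RunConfig",
    "write_table",
    "read_events",
    "read_electrodes",
    "read_cohort",
    "write_epochs",
    "read_epochs",
    "write_dataset",
    "read_dataset",
]


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, na_rep="")


def _read_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_events(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    try:
        return validate_events(df)
    except SchemaError as e:
        raise SchemaError(f"{path}: {e}") from e


def read_electrodes(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path)
    try:
        return validate_electrodes(df)
    except SchemaError as e:
        raise SchemaError(f"{path}: {e}") from e


def read_cohort(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path)


def write_epochs(epochs: EpochTensor, path: str | Path) -> None:
    """Write ``path`` (raw binary) and ``path + '.json'`` (sidecar)."""
    path = Path(path)
    data = np.ascontiguousarray(epochs.data, dtype=np.float64)
    data.tofile(path)
    sidecar = {
        "dtype": "float64",
        "shape": list(data.shape),
        "axis_order": ["item", "channel", "sample"],
        "fs": epochs.fs,
        "tmin": epochs.tmin,
        "buffer": epochs.buffer,
        "channels": list(epochs.channels),
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_epochs(path: str | Path) -> EpochTensor:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=sidecar["dtype"]).reshape(sidecar["shape"])
    return EpochTensor(
        data=data,
        fs=sidecar["fs"],
        tmin=sidecar["tmin"],
        buffer=sidecar["buffer"],
        channels=sidecar["channels"],
    )


def write_dataset(outdir: str | Path, events, electrodes, epochs) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(events, outdir / "events.tsv")
    write_table(electrodes, outdir / "electrodes.tsv")
    write_epochs(epochs, outdir / "epochs.bin")


def read_dataset(indir: str | Path):
    """Load and cross-validate events + electrodes + epochs."""
    indir = Path(indir)
    events = read_events(indir / "events.tsv")
    electrodes = read_electrodes(indir / "electrodes.tsv")
    epochs = read_epochs(indir / "epochs.bin")
    check_alignment(events, epochs)
    extra = set(epochs.channels) - set(electrodes["channel"])
    if extra:
        raise SchemaError(f"epoch channels absent from electrode table: {sorted(extra)}")
    return events, electrodes, epochs


@dataclasses.dataclass
class RunConfig:
    """All tunable parameters of the pipeline, with defaults at the
    analysis's canonical values."""

    # simulation
    n_subjects_per_group: int = 10
    n_sessions: int = 1
    n_lists: int = 25
    n_channels: int = 10
    task_variant: str = "unrelated"
    fs: float = 500.0
    theta_power_delta: float = -0.5
    hfa_power_delta: float = 1.0
    sync_plv_delta: float = 0.3
    temporal_clustering_strength: float = 0.7
    semantic_clustering_strength: float = 0.7
    # analysis
    sme_window: tuple = (0.400, 1.100)
    classifier_window: tuple = (0.0, 1.366)
    n_perm_connectivity: int = 500
    n_perm_classifier: int = 1000
    C: float = 2.4e-4
    match_ratio: int = 3
    # plumbing
    rng_seed: int = 0
    outdir: str = "results"
    stages: tuple = ("behavior", "sme", "connectivity", "classify", "match")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        bad = set(raw) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        for key in ("sme_window", "classifier_window", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        for key in ("sme_window", "classifier_window", "stages"):
            d[key] = list(d[key])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("outdir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]
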