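import numpy as np
import pandas as pd
import pytest

from memsme.simulate import EffectTruth, SimConfig, generate_subject_dataset


def make_events(records):
    """Build a minimal valid events table from compact per-list specs.

    ``records`` is a list of dicts with keys: list, positions (list
    length), recalled_order (serial positions in recall order) and
    optional categories (per position).
    """
    rows = []
    for rec in records:
        n = rec.get("n", 12)
        cats = rec.get("categories", [np.nan] * n)
        order = {p: k + 1 for k, p in enumerate(rec["recalled_order"])}
        for i in range(n):
            pos = i + 1
            rows.append(
                {
                    "subject": rec.get("subject", "S0"),
                    "session": rec.get("session", 0),
                    "task_variant": rec.get("task_variant", "unrelated"),
                    "list": rec["list"],
                    "serial_position": pos,
                    "item": f"L{rec['list']}I{pos}",
                    "category": cats[i],
                    "recalled": pos in order,
                    "output_position": order.get(pos, np.nan),
                }
            )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def null_subject():
    """One null-effect subject: 12 lists, 6 channels, all deltas zero."""
    cfg = SimConfig(n_lists=12, n_channels=6)
    return generate_subject_dataset(cfg, EffectTruth(), rng_seed=314)


@pytest.fixture(scope="session")
def effect_subject():
    """A subject with the canonical injected effects."""
    cfg = SimConfig(n_lists=15, n_channels=8)
    truth = EffectTruth(
        theta_power_delta=-0.5,
        hfa_power_delta=1.0,
        sync_pairs=((0, 1),),
        sync_plv_delta=0.3,
        temporal_clustering_strength=0.7,
    )
    return generate_subject_dataset(cfg, truth, rng_seed=271)
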