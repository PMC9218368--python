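import numpy as np
import pandas as pd
import pytest

from decompmeta import ExperimentDataset, SimulationParams, simulate_meta_dataset
from decompmeta.effects import EFFECT_COLUMNS, EffectTable


def make_summaries(rows):
    return pd.DataFrame(
        rows,
        columns=["study_id", "litter_id", "time_days", "treatment_id",
                 "response_type", "mean", "sd", "n"],
    )


def make_moderators(study_ids, **overrides):
    base = dict(
        setting="laboratory",
        environment="terrestrial",
        inoculum_complexity="whole_community",
        inoculum_taxa="both",
        max_richness=np.nan,
        litter_cn=45.0,
        litter_lignin_pct=12.0,
        n_inoculum_treatments=2,
    )
    base.update(overrides)
    return pd.DataFrame([{"study_id": s, **base} for s in study_ids])


def make_effects(y, v, study_ids, metric="CV", **extra):
    """Minimal effect table straight from estimate/variance vectors."""
    n = len(y)
    rec = pd.DataFrame(
        {
            "study_id": list(study_ids),
            "litter_id": extra.get("litter_id", ["L1"] * n),
            "time_days": extra.get("time_days", [30.0] * n),
            "response_type": extra.get("response_type", ["mass_loss_pct"] * n),
            "metric": metric,
            "estimate": np.asarray(y, float),
            "sampling_variance": np.asarray(v, float),
            "k_treatments": extra.get("k_treatments", [3] * n),
        },
        columns=EFFECT_COLUMNS,
    )
    return EffectTable(rec)


@pytest.fixture
def toy_dataset():
    """2 studies x 2 treatments x 3 time points, one litter each: 12 rows."""
    rows = []
    for s, base in [("S1", 20.0), ("S2", 30.0)]:
        for t in (30.0, 60.0, 90.0):
            for trt, shift in [("T1", 0.0), ("T2", 5.0)]:
                rows.append((s, "L1", t, trt, "mass_loss_pct",
                             base + shift + t / 10.0, 2.0, 5))
    summaries = make_summaries(rows)
    moderators = make_moderators(["S1", "S2"])
    return ExperimentDataset.from_frames(summaries, moderators)


@pytest.fixture(scope="session")
def default_sim():
    """One default-scenario simulated dataset shared across tests."""
    return simulate_meta_dataset(SimulationParams(seed=2024))
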