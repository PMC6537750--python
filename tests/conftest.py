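import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from brainclock import pipeline as pl
from brainclock import synth

settings.register_profile(
    "ci", deadline=None, derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

DEMO_SEED = 0  # the bundled seed for all golden-run checks


@pytest.fixture(scope="session")
def demo_core():
    """The default demo analysis (3 cohorts x 250 samples, 2,000 genes,
    500 age genes, rate SD 5 yr) at the bundled seed, run once per session."""
    return pl.core_run(pl.RunConfig(seed=DEMO_SEED))


@pytest.fixture(scope="session")
def small_sim():
    """A small two-cohort simulation for cheap unit tests."""
    cfg = synth.SimConfig(
        n_genes=300,
        n_up=40,
        n_down=40,
        cohorts=(
            synth.CohortSpec("a", 100, (25.0, 97.0)),
            synth.CohortSpec("b", 100, (25.0, 90.0)),
        ),
        seed=42,
    )
    return cfg, synth.generate_multi_cohort(cfg)


@pytest.fixture()
def toy_truth():
    """A minimal truth record with a known offset vector (no expression)."""
    rng = np.random.default_rng(7)
    idx = pd.Index([f"s{i:03d}" for i in range(400)], name="sample_id")
    delta = pd.Series(rng.normal(0, 5.0, len(idx)), index=idx, name="delta_true")
    return synth.TruthRecord(
        delta=delta,
        slopes=pd.Series(dtype=float),
        directions=pd.Series(dtype=object),
        rate_sd=5.0,
        config=None,
    )
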