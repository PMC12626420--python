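import numpy as np
import pytest

from mescreen.behavior_features import DeltaPixelTrace
from mescreen.synthetic import (
    EffectSpec,
    SimConfig,
    make_atlas,
    make_default_schedule,
    simulate_behavior_cohort,
)


def make_trace(dpix, dt=1.0, x=None, y=None, larva_id="f000", bursts=None):
    """Build a trace from a dpix vector with uniform sampling."""
    dpix = np.asarray(dpix, dtype=float)
    n = dpix.size
    t = np.arange(n) * dt
    if x is None:
        x = np.zeros(n)
    if y is None:
        y = np.zeros(n)
    return DeltaPixelTrace(larva_id, t, dpix, x, y, bursts or {})


@pytest.fixture(scope="session")
def small_atlas():
    return make_atlas((6, 16, 16), 4, seed=7)


@pytest.fixture(scope="session")
def null_behavior_cohort():
    cfg = SimConfig(n_per_genotype=8, genotypes=("+/+", "-/-"),
                    duration_s=900.0, seed=11)
    return simulate_behavior_cohort(cfg, make_default_schedule())


@pytest.fixture(scope="session")
def planted_behavior_cohort():
    cfg = SimConfig(
        n_per_genotype=10, genotypes=("+/+", "-/-"), duration_s=900.0,
        effect_spec=EffectSpec(bout_rate_mult=2.0), seed=12,
    )
    return simulate_behavior_cohort(cfg, make_default_schedule())
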