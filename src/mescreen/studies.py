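"""Monte-Carlo validation studies over the synthetic cohorts.

Each study runs the full pipeline path (simulate -> extract -> test) across
many seeds and reports recovery or false-positive statistics.  They back the
package's own validation suite and the reproduction script; the problem
sizes are desk-scale (half-hour 1 Hz recordings, 32x32x8 stacks for the
planted-region study) except where the calibration target fixes them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .behavior_features import build_measure_matrix
from .behavior_stats import compare_all_measures, summarize_categories
from .brain_mapping import (
    calibrate_threshold,
    median_difference,
    null_calibration_study,
    region_quantify,
    significance_map,
    stack_group,
    voxel_zmap,
)
from .pipeline import default_epochs
from .synthetic import (
    EffectSpec,
    SimConfig,
    make_atlas,
    simulate_behavior_cohort,
    simulate_brain_cohort,
)

__all__ = [
    "null_calibration_study",
    "bout_rate_recovery_study",
    "region_recovery_study",
    "null_false_positive_study",
]


def _child_seeds(seed: int, n: int) -> np.ndarray:
    return np.random.default_rng(seed).integers(2**31, size=n)


def bout_rate_recovery_study(
    n_seeds: int = 100,
    n_per_group: int = 20,
    rate_mult: float = 2.0,
    duration_s: float = 1800.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of seeds recovering a positive-sign frequency bubble.

    Each seed simulates a cohort with the bout-rate multiplier planted in
    homozygotes, extracts baseline measures, compares -/- vs +/+ and checks
    that the frequency category shows an increased-sign bubble with
    percent_significant > 0.
    """
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(
            n_per_genotype=n_per_group, genotypes=("+/+", "-/-"),
            duration_s=duration_s,
            effect_spec=EffectSpec(bout_rate_mult=rate_mult), seed=int(s),
        )
        traces, gmap = simulate_behavior_cohort(cfg)
        matrix, _ = build_measure_matrix(traces, default_epochs(duration_s))
        results = compare_all_measures(matrix, gmap, alpha=alpha)
        bubbles = summarize_categories(results)
        hit = (
            (bubbles["category"] == "frequency")
            & (bubbles["sign"] == "increased")
            & (bubbles["percent_significant"] > 0)
        ).any()
        hits += bool(hit)
    return hits / n_seeds


def region_recovery_study(
    n_seeds: int = 50,
    n_per_group: int = 10,
    delta: float = 5.0,
    shape: tuple[int, int, int] = (8, 32, 32),
    n_regions: int = 5,
    target_region: int = 2,
    target_fraction: float = 0.0005,
    n_splits: int = 20,
    seed: int = 0,
) -> float:
    """Fraction of seeds ranking the planted region first.

    The planted additive delta (in units of the voxel noise SD) goes into
    one atlas region of the homozygous stacks; each seed calibrates on the
    wild-type cohort, maps -/- vs +/+ and checks that region_quantify ranks
    the planted region first by increased signal.
    """
    atlas = make_atlas(shape, n_regions, seed=seed)
    hits = 0
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(
            n_per_genotype=n_per_group, genotypes=("+/+", "-/-"),
            effect_spec=EffectSpec(regional_activity_delta=delta,
                                   target_region=target_region),
            seed=int(s),
        )
        stacks, gmap = simulate_brain_cohort(cfg, atlas)
        a = stack_group(stacks, gmap.ids_of("-/-"))
        b = stack_group(stacks, gmap.ids_of("+/+"))
        cal = calibrate_threshold(b, target_fraction, n_splits, seed=int(s))
        sig = significance_map(voxel_zmap(a, b), median_difference(a, b), cal)
        rq = region_quantify(sig, atlas)
        if rq["increased"].max() > 0:
            hits += rq.loc[rq["increased"].idxmax(), "region"] == target_region
    return hits / n_seeds


def null_false_positive_study(
    n_seeds: int = 200,
    n_per_group: int = 20,
    duration_s: float = 900.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-measure significant-call rates on null cohorts.

    With no planted effect the two genotype groups are exchangeable, so each
    measure's rate of p < alpha across seeds should sit inside the binomial
    envelope around alpha.  Returns a frame with columns measure, rate, n.
    """
    counts: dict[str, int] = {}
    tested: dict[str, int] = {}
    for s in _child_seeds(seed, n_seeds):
        cfg = SimConfig(n_per_genotype=n_per_group, genotypes=("+/+", "-/-"),
                        duration_s=duration_s, seed=int(s))
        traces, gmap = simulate_behavior_cohort(cfg)
        matrix, _ = build_measure_matrix(traces, default_epochs(duration_s))
        results = compare_all_measures(matrix, gmap, alpha=alpha)
        for _, row in results.iterrows():
            if not row["testable"]:
                continue
            tested[row["measure"]] = tested.get(row["measure"], 0) + 1
            counts[row["measure"]] = counts.get(row["measure"], 0) + int(row["significant"])
    return pd.DataFrame(
        [{"measure": m, "rate": counts.get(m, 0) / n, "n": n}
         for m, n in tested.items()]
    )
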