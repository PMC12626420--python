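"""Run-level orchestration: configuration, stage wiring, provenance.

A run configuration (YAML/dict) selects stages and parameters; outputs are
tables and volumes in a run directory together with the resolved
configuration and a provenance record (config hash, seed, version), so a
rerun with the same resolved configuration reproduces every artifact.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from . import io
from .behavior_features import EpochSpec, StimulusSubset, build_measure_matrix
from .behavior_stats import compare_all_measures, summarize_categories
from .brain_mapping import (
    calibrate_threshold,
    median_difference,
    region_quantify,
    significance_map,
    stack_group,
    sum_of_slices,
    total_signal,
    voxel_zmap,
)
from .synthetic import (
    EffectSpec,
    NoiseSpec,
    SimConfig,
    StimulusSchedule,
    make_atlas,
    make_default_schedule,
    simulate_behavior_cohort,
    simulate_brain_cohort,
)

__all__ = [
    "ConfigError",
    "DataError",
    "default_epochs",
    "default_subsets",
    "resolve_config",
    "run_pipeline",
    "export_heatmap_tables",
]


class ConfigError(ValueError):
    """Invalid or unknown run configuration."""


class DataError(ValueError):
    """Missing or inconsistent input data."""


_KIND_CODES = {
    "dark_flash": "df",
    "light_flash": "lf",
    "acoustic_weak": "aw",
    "acoustic_strong": "as",
    "acoustic_prepulse": "pp",
}


def default_epochs(duration_s: float, bin_s: float | None = None,
                   label: str = "combo") -> list[EpochSpec]:
    """One epoch spanning the whole recording ("combo"), binned hourly or by
    the whole duration when shorter than an hour."""
    if bin_s is None:
        bin_s = min(3600.0, duration_s)
    return [EpochSpec(label, 0.0, duration_s, bin_s)]


def default_subsets(schedule: StimulusSchedule, epoch_prefix: str = "day5dpf",
                    head: int = 10) -> list[StimulusSubset]:
    """Subsets per (stimulus kind, block): the first ``head`` events form the
    'a' subset, any remainder the 'b' subset (early vs late responses)."""
    groups: dict[tuple[str, int], list[int]] = {}
    for ev_id, event in enumerate(schedule.events):
        groups.setdefault((event.kind, event.block_id), []).append(ev_id)
    subsets = []
    for (kind, block), ids in sorted(groups.items()):
        code = _KIND_CODES[kind]
        subsets.append(
            StimulusSubset(f"{epoch_prefix}{code}{block}a", tuple(ids[:head]))
        )
        if len(ids) > head:
            subsets.append(
                StimulusSubset(f"{epoch_prefix}{code}{block}b", tuple(ids[head:]))
            )
    return subsets


_DEFAULTS: dict = {
    "seed": 0,
    "stages": ["simulate", "behavior", "stats", "brain"],
    "behavior": {
        "n_per_genotype": 20,
        "genotypes": ["+/+", "-/-"],
        "duration_s": 1800.0,
        "frame_rate_hz": 1.0,
        "replicate": "1",
        "effect": {},
        "schedule": {"n_dark_flashes": 10, "n_acoustic_strong": 10},
        "bout_threshold": 0.0,
        "merge_gap_s": 0.2,
        "min_duration_s": 0.0,
        "response_threshold": 1.0,
    },
    "stats": {
        "alpha": 0.05,
        "group_pair": ["-/-", "+/+"],
        "method": "auto",
    },
    "brain": {
        "shape": [8, 32, 32],
        "n_regions": 5,
        "n_per_genotype": 10,
        "genotypes": ["+/+", "-/-"],
        "channel": "activity",
        "effect": {},
        "target_fraction": 0.0005,
        "n_splits": 20,
        "group_pair": ["-/-", "+/+"],
    },
}


def _merge(defaults: Mapping, given: Mapping, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in given.items():
        if key not in defaults:
            raise ConfigError(f"unknown configuration key {path + key!r}")
        if isinstance(defaults[key], Mapping) and key not in ("effect", "schedule"):
            if not isinstance(value, Mapping):
                raise ConfigError(f"{path + key!r} must be a mapping")
            out[key] = _merge(defaults[key], value, path + key + ".")
        else:
            out[key] = value
    return out


def resolve_config(config: Mapping | None) -> dict:
    """Fill defaults and reject unknown keys; returns the resolved config."""
    resolved = _merge(_DEFAULTS, dict(config or {}))
    unknown_stages = set(resolved["stages"]) - {"simulate", "behavior", "stats", "brain"}
    if unknown_stages:
        raise ConfigError(f"unknown stages {sorted(unknown_stages)}")
    effect_fields = set(EffectSpec.__dataclass_fields__)
    for section in ("behavior", "brain"):
        bad = set(resolved[section]["effect"]) - effect_fields
        if bad:
            raise ConfigError(f"unknown effect keys in {section}: {sorted(bad)}")
    return resolved


def _config_hash(resolved: Mapping) -> str:
    return hashlib.sha256(
        json.dumps(resolved, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: Mapping | None, out_dir: Path | str) -> Path:
    """Execute the selected stages in dependency order into ``out_dir``.

    Writes measure tables, comparison tables, bubble summaries, significance
    maps, region summaries, calibration JSON and a provenance record.
    Rerunning with the same resolved configuration reproduces the outputs.
    """
    resolved = resolve_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.resolved.yaml").write_text(yaml.safe_dump(resolved, sort_keys=True))

    from . import __version__

    provenance = {
        "config_hash": _config_hash(resolved),
        "seed": resolved["seed"],
        "version": __version__,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))

    stages = resolved["stages"]
    seed = int(resolved["seed"])
    traces = gmap = schedule = None

    if "simulate" in stages:
        bc = resolved["behavior"]
        schedule = make_default_schedule(**bc["schedule"])
        sim = SimConfig(
            n_per_genotype=int(bc["n_per_genotype"]),
            genotypes=tuple(bc["genotypes"]),
            frame_rate_hz=float(bc["frame_rate_hz"]),
            duration_s=float(bc["duration_s"]),
            effect_spec=EffectSpec(**bc["effect"]),
            replicate=str(bc["replicate"]),
            seed=seed,
        )
        traces, gmap = simulate_behavior_cohort(sim, schedule)
        io.write_traces(traces, out / "traces.tsv", out / "bursts.tsv")
        io.write_schedule(schedule, out / "schedule.yaml")
        io.write_genotypes(gmap, out / "genotypes.tsv")

    if "behavior" in stages:
        if traces is None:
            try:
                traces = io.read_traces(out / "traces.tsv", out / "bursts.tsv")
                schedule = io.read_schedule(out / "schedule.yaml")
                gmap = io.read_genotypes(out / "genotypes.tsv")
            except FileNotFoundError as exc:
                raise DataError(f"behavior stage input missing: {exc}") from exc
        bc = resolved["behavior"]
        epochs = default_epochs(float(bc["duration_s"]))
        subsets = default_subsets(schedule)
        matrix, metadata = build_measure_matrix(
            traces, epochs, subsets,
            bout_threshold=float(bc["bout_threshold"]),
            merge_gap_s=float(bc["merge_gap_s"]),
            min_duration_s=float(bc["min_duration_s"]),
            response_threshold=float(bc["response_threshold"]),
        )
        io.write_measure_matrix(matrix, metadata, out / "measures.tsv")

    if "stats" in stages:
        try:
            matrix, _ = io.read_measure_matrix(out / "measures.tsv")
            gmap = gmap or io.read_genotypes(out / "genotypes.tsv")
        except FileNotFoundError as exc:
            raise DataError(f"stats stage input missing: {exc}") from exc
        sc = resolved["stats"]
        results = compare_all_measures(
            matrix, gmap, tuple(sc["group_pair"]), float(sc["alpha"]), sc["method"]
        )
        results.to_csv(out / "comparisons.tsv", sep="\t", index=False)
        bubbles = summarize_categories(results)
        bubbles.to_csv(out / "bubble_summary.tsv", sep="\t", index=False)

    if "brain" in stages:
        bc = resolved["brain"]
        atlas = make_atlas(tuple(bc["shape"]), int(bc["n_regions"]), seed=seed)
        effect = dict(bc["effect"])
        sim = SimConfig(
            n_per_genotype=int(bc["n_per_genotype"]),
            genotypes=tuple(bc["genotypes"]),
            effect_spec=EffectSpec(**effect),
            seed=seed + 1,
        )
        stacks, fish_map = simulate_brain_cohort(sim, atlas, bc["channel"])
        io.write_atlas(atlas, out / "atlas.tif")
        ga, gb = bc["group_pair"]
        group_a = stack_group(stacks, fish_map.ids_of(ga))
        group_b = stack_group(stacks, fish_map.ids_of(gb))
        cal = calibrate_threshold(
            group_b, float(bc["target_fraction"]), int(bc["n_splits"]), seed=seed
        )
        io.write_calibration(cal, out / "calibration.json")
        z = voxel_zmap(group_a, group_b)
        sig = significance_map(z, median_difference(group_a, group_b), cal)
        io.write_stack(sig, out / "significance_map.tif")
        summary = region_quantify(sig, atlas)
        summary.to_csv(out / "region_summary.tsv", sep="\t", index=False)
        totals = pd.DataFrame(
            [{"comparison": f"{ga}_vs_{gb}", "total_signal": total_signal(sig)}]
        )
        totals.to_csv(out / "total_signal.tsv", sep="\t", index=False)
        for axis in ("z", "x"):
            np.savetxt(out / f"projection_{axis}.tsv", sum_of_slices(sig, axis),
                       delimiter="\t")
    return out


def export_heatmap_tables(
    summaries: Mapping[str, pd.DataFrame],
) -> dict[str, pd.DataFrame]:
    """Mutant x region matrices (increased/decreased channels) with rows and
    columns ordered by average-linkage clustering, ready for heatmap export."""
    if len(summaries) < 2:
        raise DataError("need at least 2 comparisons to build a heatmap table")
    region_sets = {m: tuple(df["name"]) for m, df in summaries.items()}
    if len(set(region_sets.values())) > 1:
        raise DataError(f"inconsistent region sets across comparisons: {region_sets}")
    out = {}
    for channel in ("increased", "decreased"):
        mat = pd.DataFrame(
            {m: df.set_index("name")[channel] for m, df in sorted(summaries.items())}
        ).T
        out[channel] = mat.iloc[_cluster_order(mat.to_numpy()),
                                _cluster_order(mat.to_numpy().T)]
    return out


def _cluster_order(x: np.ndarray) -> list[int]:
    if x.shape[0] < 2:
        return list(range(x.shape[0]))
    if np.allclose(pdist(x), 0):
        return list(range(x.shape[0]))  # all rows identical: stable order
    return list(leaves_list(linkage(pdist(x), method="average")))
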