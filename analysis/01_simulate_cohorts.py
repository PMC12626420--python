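#!/usr/bin/env python
"""Simulate the screen's input data with known planted effects.

Generates, for a fictive microexon mutant line with a mild behavioral and
brain phenotype (the regime the screen is designed to detect):

* two biological replicates of a behavioral cohort (+/+, +/-, -/- siblings;
  bout-rate x1.5 and a dark-flash response deficit in homozygotes),
* a registered brain-stack cohort with a +3 SD activity increase planted in
  one atlas region, plus the synthetic labeled atlas,
* a microexon sequence set spanning canonical/partial/noncanonical upstream
  layouts and in/out-of-definition exon lengths.

Everything is written under results/data/ as TSV/YAML/TIFF.
"""

from pathlib import Path

from mescreen import io
from mescreen.synthetic import (
    EffectSpec,
    SimConfig,
    make_atlas,
    make_default_schedule,
    simulate_behavior_cohort,
    simulate_brain_cohort,
    simulate_microexon_set,
)

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 2026

BEHAVIOR_EFFECT = EffectSpec(bout_rate_mult=1.5, response_prob_delta=-0.3)
BRAIN_EFFECT = EffectSpec(regional_activity_delta=3.0, target_region=2)


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    schedule = make_default_schedule(n_dark_flashes=10, n_acoustic_strong=10)
    io.write_schedule(schedule, OUT / "schedule.yaml")

    for rep in ("1", "2"):
        cfg = SimConfig(
            n_per_genotype=20, duration_s=1800.0, effect_spec=BEHAVIOR_EFFECT,
            replicate=rep, seed=SEED + int(rep),
        )
        traces, gmap = simulate_behavior_cohort(cfg, schedule)
        io.write_traces(traces, OUT / f"traces_rep{rep}.tsv", OUT / f"bursts_rep{rep}.tsv")
        io.write_genotypes(gmap, OUT / f"genotypes_rep{rep}.tsv")
        print(f"replicate {rep}: {len(traces)} larvae, "
              f"{len(schedule.events)} stimulus events")

    atlas = make_atlas((8, 32, 32), 6, seed=SEED)
    io.write_atlas(atlas, OUT / "atlas.tif")
    cfg = SimConfig(n_per_genotype=12, genotypes=("+/+", "-/-"),
                    effect_spec=BRAIN_EFFECT, seed=SEED + 10)
    stacks, fish_map = simulate_brain_cohort(cfg, atlas)
    stack_dir = OUT / "stacks"
    stack_dir.mkdir(exist_ok=True)
    for s in stacks:
        io.write_stack(s, stack_dir / f"{s.fish_id}.tif")
    io.write_genotypes(fish_map, OUT / "genotypes_brain.tsv")
    print(f"brain cohort: {len(stacks)} stacks {stacks[0].voxels.shape}, "
          f"activity delta +{BRAIN_EFFECT.regional_activity_delta} SD in region "
          f"{BRAIN_EFFECT.target_region}")

    records = simulate_microexon_set(40, seed=SEED)
    import pandas as pd

    pd.DataFrame([r.__dict__ for r in records]).to_csv(
        OUT / "microexons.tsv", sep="\t", index=False
    )
    print(f"microexon set: {len(records)} records -> {OUT / 'microexons.tsv'}")


if __name__ == "__main__":
    main()
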