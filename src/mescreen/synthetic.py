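"""Synthetic screen cohorts with known planted effects.

Every downstream stage of the pipeline (behavioral profiling, brain mapping,
sequence analyses) is exercised on cohorts generated here, so the planted
ground truth is always available for validation:

* behavioral traces: an alternating exponential on/off bout process with
  gamma-distributed per-frame movement during bouts, square-wave day/night
  rate modulation on the 14/10 h light cycle, well positions on the unit
  circle, and high-speed (285 Hz, 1 s) response bursts per stimulus event;
* brain stacks: baseline intensity plus i.i.d. Gaussian noise, with an
  additive activity delta (or multiplicative structure scale) restricted to
  a target atlas region in mutants;
* atlas: compact nonoverlapping labeled regions inside an ellipsoidal brain;
* microexon records: peptide/ortholog pairs with controlled identity and
  upstream introns built to a requested regulatory layout class.

Effects apply in full to homozygous mutants (-/-) and scaled by
``het_effect_scale`` to heterozygotes (+/-).  All randomness flows from one
seeded generator, so identical (config, seed) reproduces identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .behavior_features import DeltaPixelTrace
from .brain_mapping import BrainStack, RegionAtlas
from .microexon_sequences import MicroexonRecord

__all__ = [
    "EffectSpec",
    "NoiseSpec",
    "LightCycle",
    "SimConfig",
    "StimulusEvent",
    "StimulusSchedule",
    "GenotypeMap",
    "simulate_behavior_cohort",
    "simulate_brain_cohort",
    "make_atlas",
    "simulate_microexon_set",
    "make_default_schedule",
]

GENOTYPES = ("+/+", "+/-", "-/-")

#: Baseline response probability and latency (ms) by stimulus kind.
RESPONSE_BASELINES = {
    "dark_flash": (0.8, 250.0),
    "light_flash": (0.5, 300.0),
    "acoustic_weak": (0.3, 150.0),
    "acoustic_strong": (0.9, 100.0),
    "acoustic_prepulse": (0.6, 120.0),
}

_EFFECT_FIELDS = {
    "bout_rate_mult",
    "bout_mag_mult",
    "center_shift",
    "response_prob_delta",
    "latency_shift_ms",
    "regional_activity_delta",
    "regional_scale",
    "target_region",
}


@dataclass(frozen=True)
class EffectSpec:
    """Planted-effect descriptors, all expressed relative to wild type.

    Multipliers act on the wild-type rate/magnitude parameters; deltas are
    additive.  ``target_region`` names the atlas region receiving the brain
    effects (``regional_activity_delta`` for the activity channel,
    ``regional_scale`` for the structure channel).
    """

    bout_rate_mult: float = 1.0
    bout_mag_mult: float = 1.0
    center_shift: float = 0.0
    response_prob_delta: float = 0.0
    latency_shift_ms: float = 0.0
    regional_activity_delta: float = 0.0
    regional_scale: float = 1.0
    target_region: int | str | None = None

    def scaled(self, factor: float) -> "EffectSpec":
        """Effect attenuated toward null (heterozygote dosage)."""
        return replace(
            self,
            bout_rate_mult=1.0 + (self.bout_rate_mult - 1.0) * factor,
            bout_mag_mult=1.0 + (self.bout_mag_mult - 1.0) * factor,
            center_shift=self.center_shift * factor,
            response_prob_delta=self.response_prob_delta * factor,
            latency_shift_ms=self.latency_shift_ms * factor,
            regional_activity_delta=self.regional_activity_delta * factor,
            regional_scale=1.0 + (self.regional_scale - 1.0) * factor,
        )


@dataclass(frozen=True)
class NoiseSpec:
    """Dispersion parameters of the generator."""

    mean_off_s: float = 20.0       # mean inter-bout interval (day), seconds
    mean_on_s: float = 1.0         # mean bout duration, seconds
    dpix_gamma_shape: float = 2.0  # per-frame movement during a bout
    dpix_gamma_scale: float = 5.0
    night_rate_factor: float = 0.3  # bout-rate multiplier at night
    latency_sd_ms: float = 20.0
    response_amp: float = 10.0     # scale of response-burst dpix
    stack_baseline: float = 100.0  # activity-channel baseline intensity
    stack_noise_sd: float = 1.0
    structure_baseline: float = 1.0  # Jacobian determinant around unity
    structure_noise_sd: float = 0.05


@dataclass(frozen=True)
class LightCycle:
    """14/10 h square-wave day/night cycle; night begins at lights-off."""

    day_h: float = 14.0
    night_h: float = 10.0
    start_in_day: bool = True
    offset_h: float = 0.0

    @property
    def period_h(self) -> float:
        return self.day_h + self.night_h

    def is_day(self, t_s: np.ndarray | float) -> np.ndarray | bool:
        phase = (np.asarray(t_s) / 3600.0 + self.offset_h) % self.period_h
        return (phase < self.day_h) == self.start_in_day


@dataclass(frozen=True)
class StimulusEvent:
    time_s: float
    kind: str
    block_id: int = 1
    params: dict = field(default_factory=dict)


@dataclass(frozen=True)
class StimulusSchedule:
    """Ordered stimulus events with high-speed burst capture settings."""

    events: tuple[StimulusEvent, ...]
    burst_window_s: float = 1.0
    burst_rate_hz: float = 285.0

    def __post_init__(self) -> None:
        times = [e.time_s for e in self.events]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("events must be strictly increasing in time")
        if any(b - a < self.burst_window_s for a, b in zip(times, times[1:])):
            raise ValueError("burst windows must not overlap")
        for e in self.events:
            if e.kind not in RESPONSE_BASELINES:
                raise ValueError(f"unknown stimulus kind {e.kind!r}")

    @property
    def burst_samples(self) -> int:
        return int(round(self.burst_window_s * self.burst_rate_hz))

    def end_s(self) -> float:
        return (self.events[-1].time_s + self.burst_window_s) if self.events else 0.0


@dataclass(frozen=True)
class SimConfig:
    """Cohort design: who is simulated and which effects are planted."""

    n_per_genotype: int = 20
    genotypes: tuple[str, ...] = GENOTYPES
    frame_rate_hz: float = 1.0
    duration_s: float = 3600.0
    light_cycle: LightCycle = field(default_factory=LightCycle)
    effect_spec: EffectSpec = field(default_factory=EffectSpec)
    noise_spec: NoiseSpec = field(default_factory=NoiseSpec)
    het_effect_scale: float = 0.5
    replicate: str = "1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_genotype < 2:
            raise ValueError("n_per_genotype must be >= 2")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.frame_rate_hz <= 0:
            raise ValueError("frame_rate_hz must be positive")
        for g in self.genotypes:
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype label {g!r}")
        es = self.effect_spec
        if min(es.bout_rate_mult, es.bout_mag_mult, es.regional_scale) <= 0:
            raise ValueError("effect multipliers must be positive")

    def effect_for(self, genotype: str) -> EffectSpec:
        if genotype == "-/-":
            return self.effect_spec
        if genotype == "+/-":
            return self.effect_spec.scaled(self.het_effect_scale)
        return EffectSpec()


class GenotypeMap:
    """larva/fish id -> genotype label, plus biological-replicate id."""

    def __init__(self, genotype: dict[str, str], replicate: dict[str, str]):
        if set(genotype) != set(replicate):
            raise ValueError("genotype and replicate must cover the same ids")
        for g in genotype.values():
            if g not in GENOTYPES:
                raise ValueError(f"unknown genotype label {g!r}")
        self.genotype = dict(genotype)
        self.replicate = dict(replicate)

    def ids_of(self, genotype: str) -> list[str]:
        return sorted(i for i, g in self.genotype.items() if g == genotype)

    def __len__(self) -> int:
        return len(self.genotype)

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.genotype)
        return pd.DataFrame(
            {
                "larva_id": ids,
                "genotype": [self.genotype[i] for i in ids],
                "replicate": [self.replicate[i] for i in ids],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "GenotypeMap":
        return cls(
            dict(zip(df["larva_id"], df["genotype"])),
            dict(zip(df["larva_id"], df["replicate"].astype(str))),
        )


def make_default_schedule(
    n_dark_flashes: int = 10,
    n_acoustic_strong: int = 10,
    start_s: float = 60.0,
    spacing_s: float = 30.0,
) -> StimulusSchedule:
    """A compact stand-in stimulus block: dark flashes then strong taps."""
    events = []
    t = start_s
    for _ in range(n_dark_flashes):
        events.append(StimulusEvent(t, "dark_flash", block_id=1))
        t += spacing_s
    for _ in range(n_acoustic_strong):
        events.append(StimulusEvent(t, "acoustic_strong", block_id=1,
                                    params={"frequency_hz": 1000}))
        t += spacing_s
    return StimulusSchedule(tuple(events))


# ---------------------------------------------------------------------------
# behavioral cohort
# ---------------------------------------------------------------------------

def _simulate_trace(
    larva_id: str,
    config: SimConfig,
    schedule: StimulusSchedule,
    effect: EffectSpec,
    rng: np.random.Generator,
) -> DeltaPixelTrace:
    ns = config.noise_spec
    dt = 1.0 / config.frame_rate_hz
    n = int(round(config.duration_s * config.frame_rate_hz))
    t = np.arange(n) * dt
    dpix = np.zeros(n)
    x = np.zeros(n)
    y = np.zeros(n)

    p_center = float(np.clip(0.25 + effect.center_shift, 0.0, 1.0))

    def draw_position() -> tuple[float, float]:
        if rng.uniform() < p_center:
            r = 0.5 * np.sqrt(rng.uniform())
        else:
            r = np.sqrt(0.25 + 0.75 * rng.uniform())
        theta = rng.uniform(0, 2 * np.pi)
        return r * np.cos(theta), r * np.sin(theta)

    pos = draw_position()
    clock = 0.0
    while clock < config.duration_s:
        rate_mult = effect.bout_rate_mult
        if not config.light_cycle.is_day(clock):
            rate_mult *= ns.night_rate_factor
        off = rng.exponential(ns.mean_off_s / rate_mult)
        on = max(dt, rng.exponential(ns.mean_on_s))
        i0 = int(np.ceil((clock + off) / dt))
        i1 = int(np.ceil((clock + off + on) / dt))
        if i0 >= n:
            # mark remaining samples at the resting position
            i_rest = int(np.ceil(clock / dt))
            x[i_rest:], y[i_rest:] = pos
            break
        i1 = min(i1, n)
        i_rest = int(np.ceil(clock / dt))
        x[i_rest:i0], y[i_rest:i0] = pos
        pos = draw_position()
        k = max(i1 - i0, 1)
        dpix[i0:i0 + k] = rng.gamma(
            ns.dpix_gamma_shape, ns.dpix_gamma_scale * effect.bout_mag_mult, size=k
        )
        x[i0:i0 + k], y[i0:i0 + k] = pos
        clock = (i0 + k) * dt

    bursts: dict[int, np.ndarray] = {}
    m = schedule.burst_samples
    for ev_id, event in enumerate(schedule.events):
        p0, lat0 = RESPONSE_BASELINES[event.kind]
        p = float(np.clip(p0 + effect.response_prob_delta, 0.0, 1.0))
        burst = np.zeros(m)
        if rng.uniform() < p:
            lat_ms = lat0 + effect.latency_shift_ms + rng.normal(0.0, ns.latency_sd_ms)
            onset = int(round(lat_ms / 1000.0 * schedule.burst_rate_hz))
            onset = int(np.clip(onset, 0, m - 20))
            amp = rng.gamma(4.0, ns.response_amp * effect.bout_mag_mult / 4.0)
            k = min(40, m - onset)
            profile = amp * np.exp(-np.arange(k) / 10.0)
            burst[onset:onset + k] = np.maximum(profile, 1.5)
        bursts[ev_id] = burst
    return DeltaPixelTrace(larva_id, t, dpix, x, y, bursts)


def simulate_behavior_cohort(
    config: SimConfig, schedule: StimulusSchedule | None = None
) -> tuple[list[DeltaPixelTrace], GenotypeMap]:
    """Simulate one behavioral cohort; one trace per larva.

    Mutant larvae realize the planted effects (bout rate and magnitude
    multipliers, center-preference shift, response probability/latency
    changes); wild-type siblings are the reference process.
    """
    if schedule is None:
        schedule = StimulusSchedule(())
    if schedule.events and schedule.end_s() > config.duration_s:
        raise ValueError("stimulus schedule does not fit within duration")
    rng = np.random.default_rng(config.seed)
    traces: list[DeltaPixelTrace] = []
    genotype: dict[str, str] = {}
    replicate: dict[str, str] = {}
    idx = 0
    for g in config.genotypes:
        effect = config.effect_for(g)
        for _ in range(config.n_per_genotype):
            larva_id = f"f{idx:03d}"
            traces.append(_simulate_trace(larva_id, config, schedule, effect, rng))
            genotype[larva_id] = g
            replicate[larva_id] = config.replicate
            idx += 1
    return traces, GenotypeMap(genotype, replicate)


# ---------------------------------------------------------------------------
# brain cohort and atlas
# ---------------------------------------------------------------------------

def make_atlas(
    shape: tuple[int, int, int], n_regions: int, seed: int = 0
) -> RegionAtlas:
    """Synthetic labeled brain: Voronoi cells of random seed points inside an
    ellipsoidal foreground.  Labels 1..n_regions partition the foreground."""
    if n_regions < 1:
        raise ValueError("n_regions must be >= 1")
    shape = tuple(int(s) for s in shape)
    if len(shape) != 3:
        raise ValueError("shape must be 3D (z, y, x)")
    rng = np.random.default_rng(seed)
    zz, yy, xx = np.meshgrid(*[np.arange(s) for s in shape], indexing="ij")
    center = [(s - 1) / 2.0 for s in shape]
    radii = [max(s * 0.45, 0.5) for s in shape]
    fg = (
        ((zz - center[0]) / radii[0]) ** 2
        + ((yy - center[1]) / radii[1]) ** 2
        + ((xx - center[2]) / radii[2]) ** 2
    ) <= 1.0
    coords = np.argwhere(fg)
    if len(coords) < n_regions:
        raise ValueError(
            f"shape {shape} too small for {n_regions} regions "
            f"({len(coords)} foreground voxels)"
        )
    seeds = coords[rng.choice(len(coords), size=n_regions, replace=False)]
    d2 = ((coords[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1) + 1
    labels = np.zeros(shape, dtype=np.uint16)
    labels[tuple(coords.T)] = nearest
    return RegionAtlas(labels)


def simulate_brain_cohort(
    config: SimConfig,
    atlas: RegionAtlas,
    channel: str = "activity",
) -> tuple[list[BrainStack], GenotypeMap]:
    """Simulate registered per-fish volumes sharing the atlas geometry.

    Activity stacks are ``baseline + N(0, sd)`` with the planted additive
    delta inside the target region for mutants; structure stacks are a unit
    Jacobian determinant with noise, scaled inside the target region.
    """
    if channel not in ("activity", "structure"):
        raise ValueError(f"unknown channel {channel!r}")
    es = config.effect_spec
    target_mask = None
    has_effect = (channel == "activity" and es.regional_activity_delta != 0.0) or (
        channel == "structure" and es.regional_scale != 1.0
    )
    if has_effect:
        if es.target_region is None:
            raise ValueError("effect_spec plants a regional effect but names no target_region")
        target_mask = atlas.mask(es.target_region)  # raises if absent
    ns = config.noise_spec
    baseline = ns.stack_baseline if channel == "activity" else ns.structure_baseline
    sd = ns.stack_noise_sd if channel == "activity" else ns.structure_noise_sd

    rng = np.random.default_rng(config.seed)
    stacks: list[BrainStack] = []
    genotype: dict[str, str] = {}
    replicate: dict[str, str] = {}
    idx = 0
    for g in config.genotypes:
        effect = config.effect_for(g)
        for _ in range(config.n_per_genotype):
            fish_id = f"f{idx:03d}"
            vol = baseline + rng.normal(0.0, sd, size=atlas.labels.shape)
            if target_mask is not None:
                if channel == "activity":
                    vol[target_mask] += effect.regional_activity_delta
                else:
                    vol[target_mask] *= effect.regional_scale
            stacks.append(BrainStack(vol, fish_id, channel))
            genotype[fish_id] = g
            replicate[fish_id] = config.replicate
            idx += 1
    return stacks, GenotypeMap(genotype, replicate)


# ---------------------------------------------------------------------------
# microexon sequence set
# ---------------------------------------------------------------------------

_AA = "ACDEFGHIKLMNPQRSTVWY"
_CODON = {  # one representative codon per residue (DNA alphabet)
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}
_LAYOUTS = ("canonical", "partial", "noncanonical")


def _make_upstream(layout: str, rng: np.random.Generator, length: int = 120) -> str:
    """Upstream intron (DNA, 5'->3', ending at the exon boundary).

    canonical: >=3 TGC repeats in the proximal 30 nt plus a 15 nt
    polypyrimidine (TC) tract; partial: exactly one of the two features;
    noncanonical: purine-only (no pyrimidine run, no TGC).
    """
    purine = lambda k: "".join(rng.choice(list("AG"), size=k))
    tract = "".join(rng.choice(list("TC"), size=15))
    ugc = "TGC" * 3
    if layout == "canonical":
        proximal = tract + ugc + purine(3)
    elif layout == "partial":
        if rng.uniform() < 0.5:
            proximal = purine(15) + ugc + purine(3)
        else:
            proximal = tract + purine(6)
    elif layout == "noncanonical":
        proximal = purine(21)
    else:
        raise ValueError(f"unknown layout {layout!r}")
    return purine(length - len(proximal)) + proximal


def simulate_microexon_set(
    n: int,
    identity_targets: Sequence[float] | None = None,
    layout_mix: Sequence[float] = (0.45, 0.45, 0.10),
    seed: int = 0,
    include_length_outliers: bool = True,
) -> list[MicroexonRecord]:
    """Generate microexon records with controlled conservation and layout.

    ``identity_targets`` are per-record ortholog identity fractions in
    [0, 1] (cycled if shorter than ``n``); by default they are drawn from a
    high-conservation Beta(8, 1).  ``layout_mix`` gives the proportions of
    canonical / partial / noncanonical upstream layouts.  When
    ``include_length_outliers`` is set, every fifth record is drawn outside
    the 3-30 nt definition window to exercise the length filter.
    """
    if identity_targets is not None:
        for f in identity_targets:
            if not 0.0 <= f <= 1.0:
                raise ValueError("identity targets must be in [0, 1]")
    mix = np.asarray(layout_mix, dtype=float)
    if mix.size != 3 or mix.min() < 0 or mix.sum() <= 0:
        raise ValueError("layout_mix must be three nonnegative proportions")
    mix = mix / mix.sum()
    rng = np.random.default_rng(seed)
    records: list[MicroexonRecord] = []
    for i in range(n):
        if include_length_outliers and i % 5 == 4:
            aa_len = int(rng.integers(11, 16))  # beyond the 1-10 aa window
        else:
            aa_len = int(rng.integers(1, 11))
        peptide = "".join(rng.choice(list(_AA), size=aa_len))
        nt = "".join(_CODON[a] for a in peptide)
        if identity_targets is not None:
            target = float(identity_targets[i % len(identity_targets)])
        else:
            target = float(rng.beta(8.0, 1.0))
        ortholog = list(peptide)
        for j in range(aa_len):
            if rng.uniform() > target:
                choices = [a for a in _AA if a != ortholog[j]]
                ortholog[j] = choices[int(rng.integers(len(choices)))]
        layout = _LAYOUTS[int(rng.choice(3, p=mix))]
        records.append(
            MicroexonRecord(
                gene=f"me{i:03d}",
                nt_seq=nt,
                peptide=peptide,
                ortholog_peptide="".join(ortholog),
                full_protein_identity=float(np.clip(target * rng.uniform(0.55, 0.9), 0.05, 1.0)),
                upstream_intron=_make_upstream(layout, rng),
                frame_preserving=True,
                layout_class=layout,
            )
        )
    return records
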