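"""Behavioral feature extraction for larval zebrafish tracking data.

The raw substrate is a per-larva delta-pixel trace (one movement-magnitude
value and one centroid per baseline sample) plus short high-speed bursts
(285 samples/s over 1 s) attached to stimulus events.  This module turns
those into the named measure matrix used by the screen statistics:

* bout detection (contiguous supra-threshold movement episodes),
* baseline measures per epoch and bin — movement frequency
  (``numberofbouts``, ``activeseconds``), magnitude
  (``boutcumulativemovement``, ``boutvelocity``) and location preference
  (``boutcenterfraction``),
* stimulus-response measures per stimulus subset
  (``responsefrequency``, ``responselatency``, ``responsemagnitude``).

Measure columns follow the ``epoch_measure[_suffix]`` naming grammar, e.g.
``day0night_boutcenterfraction_3600`` or ``day6dpfdf1a_responselatency``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DeltaPixelTrace",
    "Bout",
    "EpochSpec",
    "StimulusSubset",
    "detect_bouts",
    "baseline_measures",
    "stimulus_measures",
    "measure_name",
    "parse_measure_name",
    "build_measure_matrix",
    "CATEGORY_BY_MEASURE",
    "CENTER_BOUNDARY",
]

#: Well geometry: unit-circle well, "center" is radius <= 0.5 (area fraction 1/4).
CENTER_BOUNDARY = 0.5

#: Summarized category for each base measure name.
CATEGORY_BY_MEASURE: Mapping[str, str] = {
    "numberofbouts": "frequency",
    "activeseconds": "frequency",
    "responsefrequency": "frequency",
    "boutcumulativemovement": "magnitude",
    "boutvelocity": "magnitude",
    "responsemagnitude": "magnitude",
    "boutcenterfraction": "location",
    "responselatency": "latency",
}


@dataclass
class DeltaPixelTrace:
    """Per-larva movement trace.

    ``t`` is seconds since experiment start (strictly increasing), ``dpix``
    the nonnegative per-sample movement magnitude, ``x``/``y`` the centroid
    in well coordinates (unit circle).  ``bursts`` maps event id to the
    high-speed dpix vector recorded around that stimulus.
    """

    larva_id: str
    t: np.ndarray
    dpix: np.ndarray
    x: np.ndarray
    y: np.ndarray
    bursts: dict[int, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.dpix = np.asarray(self.dpix, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError(f"trace {self.larva_id}: t must be strictly increasing")
        if np.any(self.dpix < 0):
            raise ValueError(f"trace {self.larva_id}: dpix must be nonnegative")
        n = self.t.size
        if not (self.dpix.size == self.x.size == self.y.size == n):
            raise ValueError(f"trace {self.larva_id}: field lengths differ")

    @property
    def dt(self) -> float:
        """Sample period in seconds (median spacing)."""
        if self.t.size < 2:
            return 1.0
        return float(np.median(np.diff(self.t)))


@dataclass(frozen=True)
class Bout:
    """A contiguous supra-threshold movement episode."""

    start_s: float
    end_s: float
    cumulative_movement: float  # sum of dpix over the bout, pixels
    peak: float                 # max dpix within the bout
    mean_velocity: float        # cumulative_movement / duration
    center_fraction: float      # fraction of bout samples with radius <= boundary

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass(frozen=True)
class EpochSpec:
    """A labeled time window carved into fixed bins.

    A trailing partial bin (``end_s - start_s`` not a multiple of ``bin_s``)
    is dropped.
    """

    label: str
    start_s: float
    end_s: float
    bin_s: float

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise ValueError(f"epoch {self.label}: end must exceed start")
        if self.bin_s <= 0:
            raise ValueError(f"epoch {self.label}: bin_s must be positive")

    def bin_edges(self) -> np.ndarray:
        n_bins = int(np.floor((self.end_s - self.start_s) / self.bin_s + 1e-9))
        return self.start_s + self.bin_s * np.arange(n_bins + 1)


@dataclass(frozen=True)
class StimulusSubset:
    """A named group of stimulus events summarized together.

    ``label`` is the epoch-like name component (e.g. ``day6dpfdf1a``),
    ``suffix`` an optional stimulus-code tail (e.g. ``1_a1f1000d5p``).
    """

    label: str
    event_ids: tuple[int, ...]
    suffix: str | None = None


# ---------------------------------------------------------------------------
# bout detection
# ---------------------------------------------------------------------------

def detect_bouts(
    trace: DeltaPixelTrace,
    threshold: float = 0.0,
    merge_gap_s: float = 0.2,
    min_duration_s: float = 0.0,
    center_boundary: float = CENTER_BOUNDARY,
) -> list[Bout]:
    """Detect movement bouts as maximal runs of samples with ``dpix > threshold``.

    Runs separated by gaps strictly shorter than ``merge_gap_s`` are merged
    (the sub-threshold gap samples then belong to the merged bout); runs with
    duration strictly shorter than ``min_duration_s`` are discarded.  Bouts
    are non-overlapping and ordered by start time.
    """
    if threshold < 0 or merge_gap_s < 0 or min_duration_s < 0:
        raise ValueError("bout detection parameters must be nonnegative")
    if trace.t.size == 0:
        return []

    active = trace.dpix > threshold
    if not active.any():
        return []
    padded = np.concatenate(([False], active, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[0::2], edges[1::2] - 1  # inclusive sample indices

    dt = trace.dt
    # merge runs separated by short gaps
    merged: list[list[int]] = [[int(starts[0]), int(ends[0])]]
    for s, e in zip(starts[1:], ends[1:]):
        prev_end_time = trace.t[merged[-1][1]] + dt
        gap = trace.t[s] - prev_end_time
        if gap < merge_gap_s:
            merged[-1][1] = int(e)
        else:
            merged.append([int(s), int(e)])

    radius = np.hypot(trace.x, trace.y)
    bouts: list[Bout] = []
    for s, e in merged:
        start_s = float(trace.t[s])
        end_s = float(trace.t[e] + dt)
        duration = end_s - start_s
        if duration < min_duration_s:
            continue
        seg = trace.dpix[s : e + 1]
        cum = float(seg.sum())
        bouts.append(
            Bout(
                start_s=start_s,
                end_s=end_s,
                cumulative_movement=cum,
                peak=float(seg.max()),
                mean_velocity=cum / duration,
                center_fraction=float(np.mean(radius[s : e + 1] <= center_boundary)),
            )
        )
    return bouts


# ---------------------------------------------------------------------------
# measure naming grammar
# ---------------------------------------------------------------------------

def measure_name(epoch_label: str, measure: str, suffix: str | None = None) -> str:
    """Join epoch, measure and optional bin/stimulus suffix into a column name."""
    for part, what in ((epoch_label, "epoch"), (measure, "measure")):
        if not part:
            raise ValueError(f"empty {what} component")
        if "_" in part:
            raise ValueError(f"reserved separator '_' in {what} component {part!r}")
    if suffix is not None:
        if suffix == "":
            raise ValueError("empty suffix component")
        return f"{epoch_label}_{measure}_{suffix}"
    return f"{epoch_label}_{measure}"


def parse_measure_name(name: str) -> tuple[str, str, str | None]:
    """Invert :func:`measure_name`: ``name -> (epoch, measure, suffix)``."""
    parts = name.split("_")
    if len(parts) < 2 or not all(parts):
        raise ValueError(f"unparseable measure name {name!r}")
    epoch, measure = parts[0], parts[1]
    suffix = "_".join(parts[2:]) if len(parts) > 2 else None
    return epoch, measure, suffix


# ---------------------------------------------------------------------------
# baseline measures
# ---------------------------------------------------------------------------

def baseline_measures(
    bouts: Sequence[Bout],
    trace: DeltaPixelTrace,
    epochs: Sequence[EpochSpec],
    center_boundary: float = CENTER_BOUNDARY,
) -> dict[str, float]:
    """Per-epoch baseline measures for one larva.

    Each epoch is carved into ``bin_s`` bins; a bout belongs to the bin
    containing its start.  Frequency measures average per-bin counts over
    bins (empty bins count as zero); magnitude and location measures average
    over bins that contain bouts and are missing (NaN) when no bin does.
    """
    if trace.t.size == 0:
        raise ValueError("empty trace")
    t0, t1 = float(trace.t[0]), float(trace.t[-1] + trace.dt)
    starts = np.array([b.start_s for b in bouts])
    out: dict[str, float] = {}
    for epoch in epochs:
        if epoch.start_s < t0 - 1e-9 or epoch.end_s > t1 + 1e-9:
            raise ValueError(
                f"epoch {epoch.label} [{epoch.start_s}, {epoch.end_s}) outside trace span [{t0}, {t1})"
            )
        edges = epoch.bin_edges()
        n_bins = len(edges) - 1
        suffix = f"{epoch.bin_s:g}"
        if n_bins == 0:
            for m in ("numberofbouts", "activeseconds", "boutcumulativemovement",
                      "boutvelocity", "boutcenterfraction"):
                out[measure_name(epoch.label, m, suffix)] = np.nan
            continue
        counts = np.zeros(n_bins)
        active = np.zeros(n_bins)
        cum: list[list[float]] = [[] for _ in range(n_bins)]
        vel: list[list[float]] = [[] for _ in range(n_bins)]
        cf_num = np.zeros(n_bins)
        cf_den = np.zeros(n_bins)
        if len(bouts):
            idx = np.floor((starts - epoch.start_s) / epoch.bin_s).astype(int)
            for b, i in zip(bouts, idx):
                if 0 <= i < n_bins and b.start_s >= epoch.start_s:
                    counts[i] += 1
                    active[i] += b.duration_s
                    cum[i].append(b.cumulative_movement)
                    vel[i].append(b.mean_velocity)
                    cf_num[i] += b.center_fraction * b.duration_s
                    cf_den[i] += b.duration_s
        out[measure_name(epoch.label, "numberofbouts", suffix)] = float(counts.mean())
        out[measure_name(epoch.label, "activeseconds", suffix)] = float(active.mean())
        cum_bin = [np.mean(v) for v in cum if v]
        vel_bin = [np.mean(v) for v in vel if v]
        cf_bin = [cf_num[i] / cf_den[i] for i in range(n_bins) if cf_den[i] > 0]
        out[measure_name(epoch.label, "boutcumulativemovement", suffix)] = (
            float(np.mean(cum_bin)) if cum_bin else np.nan
        )
        out[measure_name(epoch.label, "boutvelocity", suffix)] = (
            float(np.mean(vel_bin)) if vel_bin else np.nan
        )
        out[measure_name(epoch.label, "boutcenterfraction", suffix)] = (
            float(np.mean(cf_bin)) if cf_bin else np.nan
        )
    return out


# ---------------------------------------------------------------------------
# stimulus-response measures
# ---------------------------------------------------------------------------

def stimulus_measures(
    trace: DeltaPixelTrace,
    subsets: Sequence[StimulusSubset],
    response_threshold: float = 1.0,
    burst_rate_hz: float = 285.0,
) -> dict[str, float]:
    """Per-subset stimulus-response measures for one larva.

    A larva responded to an event iff its burst contains a sample above
    ``response_threshold``; latency is time to response onset (first
    supra-threshold sample) in ms, averaged over responded events only;
    magnitude is the mean cumulative burst dpix over responded events.
    """
    out: dict[str, float] = {}
    for subset in subsets:
        if len(subset.event_ids) == 0:
            raise ValueError(f"subset {subset.label} references zero events")
        latencies: list[float] = []
        magnitudes: list[float] = []
        n_resp = 0
        for ev in subset.event_ids:
            if ev not in trace.bursts:
                raise ValueError(
                    f"trace {trace.larva_id}: no burst recorded for event {ev} "
                    f"(subset {subset.label})"
                )
            burst = np.asarray(trace.bursts[ev], dtype=float)
            supra = np.flatnonzero(burst > response_threshold)
            if supra.size:
                n_resp += 1
                latencies.append(supra[0] / burst_rate_hz * 1000.0)
                magnitudes.append(float(burst.sum()))
        sfx = subset.suffix
        out[measure_name(subset.label, "responsefrequency", sfx)] = n_resp / len(subset.event_ids)
        out[measure_name(subset.label, "responselatency", sfx)] = (
            float(np.mean(latencies)) if latencies else np.nan
        )
        out[measure_name(subset.label, "responsemagnitude", sfx)] = (
            float(np.mean(magnitudes)) if magnitudes else np.nan
        )
    return out


# ---------------------------------------------------------------------------
# cohort-level matrix
# ---------------------------------------------------------------------------

def build_measure_matrix(
    traces: Iterable[DeltaPixelTrace],
    epochs: Sequence[EpochSpec],
    subsets: Sequence[StimulusSubset] = (),
    bout_threshold: float = 0.0,
    merge_gap_s: float = 0.2,
    min_duration_s: float = 0.0,
    response_threshold: float = 1.0,
    burst_rate_hz: float = 285.0,
    center_boundary: float = CENTER_BOUNDARY,
) -> tuple[pd.DataFrame, dict[str, dict]]:
    """Assemble the larva x measure matrix plus per-column metadata.

    Returns ``(matrix, metadata)`` where metadata maps each column name to
    ``{"category", "epoch", "suffix", "measure"}``.
    """
    rows = {}
    for trace in traces:
        bouts = detect_bouts(
            trace, bout_threshold, merge_gap_s, min_duration_s, center_boundary
        )
        row = baseline_measures(bouts, trace, epochs, center_boundary)
        if subsets:
            row.update(
                stimulus_measures(trace, subsets, response_threshold, burst_rate_hz)
            )
        rows[trace.larva_id] = row
    matrix = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    metadata = {}
    for col in matrix.columns:
        epoch, measure, suffix = parse_measure_name(col)
        metadata[col] = {
            "category": CATEGORY_BY_MEASURE[measure],
            "epoch": epoch,
            "measure": measure,
            "suffix": suffix,
        }
    return matrix, metadata
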