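"""Plain-text and TIFF interchange for every pipeline stage.

Traces, bursts, genotypes, measure matrices and region summaries travel as
TSV; stimulus schedules and run configurations as YAML; per-column measure
metadata and calibration results as JSON; image stacks, atlases and signed
significance maps as TIFF with axis order (z, y, x).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile
import yaml

from .behavior_features import DeltaPixelTrace
from .brain_mapping import BrainStack, CalibrationResult, RegionAtlas
from .synthetic import GenotypeMap, StimulusEvent, StimulusSchedule

__all__ = [
    "write_traces", "read_traces",
    "write_schedule", "read_schedule",
    "write_genotypes", "read_genotypes",
    "write_measure_matrix", "read_measure_matrix",
    "write_stack", "read_stack", "read_stack_cohort",
    "write_atlas", "read_atlas",
    "write_calibration", "read_calibration",
]


# --- behavioral traces ------------------------------------------------------

def write_traces(
    traces: Iterable[DeltaPixelTrace], trace_path: Path | str, burst_path: Path | str
) -> None:
    """Write baseline samples and high-speed bursts as two long-format TSVs."""
    trace_rows = []
    burst_rows = []
    for tr in traces:
        trace_rows.append(
            pd.DataFrame(
                {"larva_id": tr.larva_id, "t_s": tr.t, "dpix": tr.dpix,
                 "x": tr.x, "y": tr.y}
            )
        )
        for ev, burst in sorted(tr.bursts.items()):
            burst_rows.append(
                pd.DataFrame(
                    {"larva_id": tr.larva_id, "event_id": ev,
                     "frame": np.arange(len(burst)), "dpix": burst}
                )
            )
    pd.concat(trace_rows).to_csv(trace_path, sep="\t", index=False)
    if burst_rows:
        pd.concat(burst_rows).to_csv(burst_path, sep="\t", index=False)
    else:
        pd.DataFrame(columns=["larva_id", "event_id", "frame", "dpix"]).to_csv(
            burst_path, sep="\t", index=False
        )


def read_traces(trace_path: Path | str, burst_path: Path | str) -> list[DeltaPixelTrace]:
    df = pd.read_csv(trace_path, sep="\t")
    bursts = pd.read_csv(burst_path, sep="\t")
    out = []
    burst_groups: dict[str, dict[int, np.ndarray]] = {}
    if len(bursts):
        for (larva, ev), grp in bursts.groupby(["larva_id", "event_id"], sort=True):
            burst_groups.setdefault(str(larva), {})[int(ev)] = (
                grp.sort_values("frame")["dpix"].to_numpy()
            )
    for larva, grp in df.groupby("larva_id", sort=True):
        grp = grp.sort_values("t_s")
        out.append(
            DeltaPixelTrace(
                str(larva),
                grp["t_s"].to_numpy(),
                grp["dpix"].to_numpy(),
                grp["x"].to_numpy(),
                grp["y"].to_numpy(),
                burst_groups.get(str(larva), {}),
            )
        )
    return out


# --- schedules --------------------------------------------------------------

def write_schedule(schedule: StimulusSchedule, path: Path | str) -> None:
    doc = {
        "burst_window_s": schedule.burst_window_s,
        "burst_rate_hz": schedule.burst_rate_hz,
        "events": [
            {"time_s": e.time_s, "kind": e.kind, "block_id": e.block_id,
             "params": dict(e.params)}
            for e in schedule.events
        ],
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_schedule(path: Path | str) -> StimulusSchedule:
    doc = yaml.safe_load(Path(path).read_text())
    events = tuple(
        StimulusEvent(float(e["time_s"]), e["kind"], int(e.get("block_id", 1)),
                      dict(e.get("params", {})))
        for e in doc.get("events", [])
    )
    return StimulusSchedule(events, float(doc.get("burst_window_s", 1.0)),
                            float(doc.get("burst_rate_hz", 285.0)))


# --- genotypes --------------------------------------------------------------

def write_genotypes(gmap: GenotypeMap, path: Path | str) -> None:
    gmap.to_frame().to_csv(path, sep="\t", index=False)


def read_genotypes(path: Path | str) -> GenotypeMap:
    return GenotypeMap.from_frame(pd.read_csv(path, sep="\t", dtype=str))


# --- measure matrices -------------------------------------------------------

def write_measure_matrix(
    matrix: pd.DataFrame, metadata: dict, path: Path | str,
    metadata_path: Path | str | None = None,
) -> None:
    matrix.to_csv(path, sep="\t", index_label="larva_id")
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".meta.json")
    Path(metadata_path).write_text(json.dumps(metadata, indent=2))


def read_measure_matrix(
    path: Path | str, metadata_path: Path | str | None = None
) -> tuple[pd.DataFrame, dict]:
    matrix = pd.read_csv(path, sep="\t", index_col="larva_id")
    matrix.index.name = None
    if metadata_path is None:
        metadata_path = Path(path).with_suffix(".meta.json")
    metadata = json.loads(Path(metadata_path).read_text())
    return matrix, metadata


# --- stacks and atlases -----------------------------------------------------

def write_stack(volume: np.ndarray | BrainStack, path: Path | str) -> None:
    vol = volume.voxels if isinstance(volume, BrainStack) else np.asarray(volume)
    tifffile.imwrite(str(path), vol.astype(np.float32), photometric="minisblack")


def read_stack(path: Path | str, fish_id: str | None = None,
               channel: str = "activity") -> BrainStack:
    vol = tifffile.imread(str(path))
    return BrainStack(vol, fish_id or Path(path).stem, channel)


def read_stack_cohort(paths: Sequence[Path | str], channel: str = "activity") -> list[BrainStack]:
    """Load a cohort of registered stacks, enforcing congruent shapes."""
    stacks = [read_stack(p, channel=channel) for p in paths]
    shapes = {s.voxels.shape for s in stacks}
    if len(shapes) > 1:
        raise ValueError(f"stacks are not congruent: shapes {sorted(shapes)}")
    return stacks


def write_atlas(atlas: RegionAtlas, path: Path | str,
                names_path: Path | str | None = None) -> None:
    tifffile.imwrite(str(path), atlas.labels.astype(np.uint16), photometric="minisblack")
    if names_path is None:
        names_path = Path(path).with_suffix(".names.json")
    Path(names_path).write_text(
        json.dumps({str(k): v for k, v in atlas.names.items()}, indent=2)
    )


def read_atlas(path: Path | str, names_path: Path | str | None = None) -> RegionAtlas:
    labels = tifffile.imread(str(path)).astype(np.int32)
    if names_path is None:
        names_path = Path(path).with_suffix(".names.json")
    names = {}
    p = Path(names_path)
    if p.exists():
        names = {int(k): v for k, v in json.loads(p.read_text()).items()}
    return RegionAtlas(labels, names)


# --- calibration ------------------------------------------------------------

def write_calibration(result: CalibrationResult, path: Path | str) -> None:
    Path(path).write_text(result.to_json())


def read_calibration(path: Path | str) -> CalibrationResult:
    doc = json.loads(Path(path).read_text())
    return CalibrationResult(
        doc["z_threshold"], doc["target_fraction"], doc["realized_fraction"],
        doc["n_splits"], doc["seed"],
    )
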