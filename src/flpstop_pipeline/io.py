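"""Readers and writers for the pipeline's on-disk formats.

Conventions: CSV is UTF-8, comma-separated, '.' decimal, header row required;
times are seconds, lengths µm, Ct values cycles.  TIFF stacks are grayscale
multi-frame; mask images use nonzero = member.  Schema violations raise
``ValueError`` naming the offending column.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from flpstop_pipeline.stimulus import StimulusLog, StimulusSpec, Transition
from flpstop_pipeline.traces import RoiTrace, StimLockedAverage

TRACE_COLUMNS = ("roi_id", "t_s", "F")
SPOT_COLUMNS = ("x_um", "y_um", "z_um", "channel")
CT_COLUMNS = ("genotype", "gene", "biological_replicate", "technical_replicate", "ct")
COUNT_COLUMNS = ("genotype_class", "count")


def _require_columns(df: pd.DataFrame, columns: Sequence[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {', '.join(missing)}")


# --- trace tables ----------------------------------------------------------


def write_traces_csv(traces: Iterable[RoiTrace], path: str | Path) -> None:
    """Long-format trace table (roi_id, t_s, F) plus a sidecar *_meta.csv."""
    path = Path(path)
    frames = []
    meta_rows = []
    for tr in traces:
        frames.append(pd.DataFrame({"roi_id": tr.roi_id, "t_s": tr.times_s, "F": tr.F}))
        meta_rows.append({"roi_id": tr.roi_id, **tr.meta})
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    pd.DataFrame(meta_rows).to_csv(path.with_name(path.stem + "_meta.csv"), index=False)


def read_traces_csv(path: str | Path) -> list[RoiTrace]:
    path = Path(path)
    df = pd.read_csv(path)
    _require_columns(df, TRACE_COLUMNS, f"trace table {path.name}")
    meta_path = path.with_name(path.stem + "_meta.csv")
    meta: dict[str, dict] = {}
    if meta_path.exists():
        mdf = pd.read_csv(meta_path)
        _require_columns(mdf, ("roi_id",), f"trace metadata {meta_path.name}")
        meta = {
            row["roi_id"]: {k: v for k, v in row.items() if k != "roi_id"}
            for row in mdf.to_dict("records")
        }
    traces = []
    for roi_id, sub in df.groupby("roi_id", sort=False):
        traces.append(RoiTrace(
            roi_id=str(roi_id),
            times_s=sub["t_s"].to_numpy(),
            F=sub["F"].to_numpy(),
            meta=meta.get(roi_id, {}),
        ))
    return traces


# --- stimulus logs ---------------------------------------------------------


def write_stimulus_log_json(log: StimulusLog, path: str | Path) -> None:
    payload = {
        "spec": dataclasses.asdict(log.spec),
        "delay_compensated": log.delay_compensated,
        "transitions": [{"t_s": tr.t_s, "type": tr.type} for tr in log.transitions],
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_stimulus_log_json(path: str | Path) -> StimulusLog:
    payload = json.loads(Path(path).read_text())
    for key in ("spec", "transitions"):
        if key not in payload:
            raise ValueError(f"stimulus log JSON is missing required key: {key}")
    spec_dict = dict(payload["spec"])
    if "screen_span_deg" in spec_dict:
        spec_dict["screen_span_deg"] = tuple(spec_dict["screen_span_deg"])
    spec = StimulusSpec(**spec_dict)
    transitions = tuple(
        Transition(t_s=float(tr["t_s"]), type=tr["type"]) for tr in payload["transitions"]
    )
    return StimulusLog(
        spec=spec, transitions=transitions,
        delay_compensated=bool(payload.get("delay_compensated", False)),
    )


# --- spots, Ct, counts -----------------------------------------------------


def write_spots_csv(spot_sets, path: str | Path) -> None:
    rows = []
    for ss in spot_sets:
        for x, y, z in ss.points:
            rows.append({
                "x_um": x, "y_um": y, "z_um": z,
                "channel": ss.channel, "specimen_id": ss.specimen_id,
            })
    pd.DataFrame(rows).to_csv(Path(path), index=False)


def read_spots_csv(path: str | Path):
    from flpstop_pipeline.coloc import SpotSet

    df = pd.read_csv(path)
    _require_columns(df, SPOT_COLUMNS, f"spot table {Path(path).name}")
    if "specimen_id" not in df.columns:
        df["specimen_id"] = ""
    df["specimen_id"] = df["specimen_id"].fillna("")
    out = []
    for (channel, specimen), sub in df.groupby(["channel", "specimen_id"], sort=False):
        out.append(SpotSet(
            points=sub[["x_um", "y_um", "z_um"]].to_numpy(),
            channel=str(channel), specimen_id=str(specimen),
        ))
    return out


def write_ct_csv(ct: pd.DataFrame, path: str | Path) -> None:
    _require_columns(ct, CT_COLUMNS, "Ct table")
    ct.to_csv(Path(path), index=False)


def read_ct_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, CT_COLUMNS, f"Ct table {Path(path).name}")
    return df


def write_counts_csv(counts: pd.DataFrame, path: str | Path) -> None:
    _require_columns(counts, COUNT_COLUMNS, "count table")
    counts.to_csv(Path(path), index=False)


def read_counts_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, COUNT_COLUMNS, f"count table {Path(path).name}")
    if (df["count"] < 0).any():
        raise ValueError("column 'count' must be nonnegative")
    return df


# --- stimulus-locked averages and peaks ------------------------------------


def write_stim_locked_csv(avg: StimLockedAverage, path: str | Path) -> None:
    pd.DataFrame({
        "grid_s": avg.grid_s, "mean": avg.mean_dff,
        "sem": avg.sem_dff, "n": avg.n_per_bin,
    }).to_csv(Path(path), index=False)


def write_peaks_csv(peaks: pd.DataFrame, path: str | Path) -> None:
    peaks.to_csv(Path(path), index=False)


def read_peaks_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, ("roi_id", "genotype", "peak"), f"peak table {Path(path).name}")
    return df


# --- TIFF stacks and masks -------------------------------------------------


def write_tiff_stack(stack: np.ndarray, path: str | Path) -> None:
    stack = np.asarray(stack)
    if stack.ndim != 3:
        raise ValueError("stack must be (n_frames, h, w)")
    tifffile.imwrite(Path(path), stack.astype(np.uint16), photometric="minisblack")


def read_tiff_stack(path: str | Path) -> np.ndarray:
    stack = tifffile.imread(Path(path))
    if stack.ndim == 2:
        stack = stack[None]
    if stack.ndim != 3:
        raise ValueError(f"TIFF {Path(path).name} is not a uniform 2D frame stack")
    return stack


def write_mask(mask: np.ndarray, path: str | Path) -> None:
    tifffile.imwrite(Path(path), (np.asarray(mask) != 0).astype(np.uint8) * 255)


def read_mask(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)) != 0


# --- ground truth / generic JSON -------------------------------------------


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if dataclasses.is_dataclass(o):
            return dataclasses.asdict(o)
        raise TypeError(f"not JSON-serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=1, default=default))


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
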