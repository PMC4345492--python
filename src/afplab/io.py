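"""File formats: delimited time series, stroke segmentations, wall-pressure
tables and JSON reports.

Time series travel as two-column delimited text (``time_s``, ``force_N``)
with ``#``-prefixed header lines carrying units and provenance — chosen for
diff-ability and language neutrality.  Segmentations are three-column
(``start_s``, ``end_s``, ``phase``) with the flight bounds in the header.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .control_volume import WallPressureField
from .core import ForceTrace
from .signals import Stroke, StrokeSegmentation

PathLike = Union[str, Path]


def write_force_trace(path: PathLike, trace: ForceTrace, comment: str = "") -> None:
    """Write a force trace as delimited text with a provenance header."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# afplab force trace\n")
        fh.write("# columns: time_s force_N\n")
        if comment:
            fh.write(f"# {comment}\n")
        if trace.meta:
            fh.write(f"# meta: {json.dumps(trace.meta, default=str)}\n")
        for t, f in zip(trace.time, trace.force):
            fh.write(f"{t:.9g}\t{f:.9g}\n")


def read_force_trace(path: PathLike) -> ForceTrace:
    """Read a force trace written by :func:`write_force_trace` (or any
    two-column delimited file with ``#`` comments)."""
    path = Path(path)
    meta: dict = {}
    for line in path.open():
        if line.startswith("# meta: "):
            meta = json.loads(line[len("# meta: "):])
            break
        if not line.startswith("#"):
            break
    data = np.loadtxt(path, comments="#")
    data = np.atleast_2d(data)
    return ForceTrace(data[:, 0], data[:, 1], meta)


def write_segmentation(path: PathLike, seg: StrokeSegmentation) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# afplab stroke segmentation\n")
        fh.write("# columns: start_s end_s phase\n")
        fh.write(f"# flight_bounds: {seg.flight_bounds[0]:.9g} {seg.flight_bounds[1]:.9g}\n")
        for s in seg.strokes:
            fh.write(f"{s.start:.9g}\t{s.end:.9g}\t{s.phase}\n")


def read_segmentation(path: PathLike) -> StrokeSegmentation:
    path = Path(path)
    bounds = None
    strokes = []
    for line in path.open():
        line = line.strip()
        if line.startswith("# flight_bounds:"):
            parts = line.split(":", 1)[1].split()
            bounds = (float(parts[0]), float(parts[1]))
        elif line and not line.startswith("#"):
            a, b, phase = line.split()
            strokes.append(Stroke(float(a), float(b), phase))  # type: ignore[arg-type]
    if bounds is None:
        if not strokes:
            raise ValueError(f"no strokes in {path}")
        bounds = (strokes[0].start, strokes[-1].end)
    return StrokeSegmentation(strokes=tuple(strokes), flight_bounds=bounds)


def wall_pressure_table(field: WallPressureField) -> pd.DataFrame:
    """Flatten a wall-pressure field to a tidy table:
    columns wall_id, u_m, v_m, pressure_Pa."""
    rows = []
    for wid, w in field.walls.items():
        U, V = np.meshgrid(w["u"], w["v"], indexing="ij")
        rows.append(
            pd.DataFrame(
                {
                    "wall_id": wid,
                    "u_m": U.ravel(),
                    "v_m": V.ravel(),
                    "pressure_Pa": w["p"].ravel(),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def write_wall_pressure(path: PathLike, field: WallPressureField) -> None:
    table = wall_pressure_table(field)
    with Path(path).open("w") as fh:
        fh.write("# afplab wall pressure field\n")
        fh.write("# columns: wall_id u_m v_m pressure_Pa\n")
        table.to_csv(fh, sep="\t", index=False)


def write_json_report(path: PathLike, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, pd.DataFrame):
        return obj.to_dict(orient="records")
    return str(obj)
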