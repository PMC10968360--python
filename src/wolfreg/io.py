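"""Point-cloud file I/O and JSON run reports.

Supported cloud formats are deliberately narrow and text-only: ASCII PLY
restricted to float x, y, z vertex properties, plain whitespace XYZ, and
comma-separated CSV.  Coordinates are written as float64 at 17 significant
digits so a write/read round trip is exact to well below 1e-9.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .geometry import as_cloud

__all__ = [
    "read_cloud",
    "write_cloud",
    "write_report",
    "CloudParseError",
    "UnsupportedFormatError",
]


class CloudParseError(ValueError):
    """A cloud file could not be parsed; the message names the line."""


class UnsupportedFormatError(ValueError):
    """The file is in a recognized but unsupported encoding (binary PLY)."""


_FORMATS = ("ply", "xyz", "csv")


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in _FORMATS:
            raise ValueError(f"format must be one of {_FORMATS}, got {fmt!r}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in _FORMATS:
        return suffix
    if suffix in ("txt", "pts"):
        return "xyz"
    raise ValueError(
        f"cannot infer cloud format from {path.name!r}; pass format explicitly"
    )


def _read_ply(path: Path) -> np.ndarray:
    with open(path, "r", errors="replace") as fh:
        lines = fh.read().splitlines()
    if not lines or lines[0].strip() != "ply":
        raise CloudParseError(f"{path}: line 1: not a PLY file (missing 'ply' magic)")
    n_vertex = None
    props: list[str] = []
    body_start = None
    in_vertex_element = False
    for i, raw in enumerate(lines[1:], start=2):
        line = raw.strip()
        if line.startswith("format"):
            if "ascii" not in line:
                raise UnsupportedFormatError(
                    f"{path}: line {i}: only ASCII PLY is supported, got {line!r}"
                )
        elif line.startswith("element"):
            parts = line.split()
            in_vertex_element = len(parts) == 3 and parts[1] == "vertex"
            if in_vertex_element:
                try:
                    n_vertex = int(parts[2])
                except ValueError as exc:
                    raise CloudParseError(
                        f"{path}: line {i}: bad vertex count in {line!r}"
                    ) from exc
        elif line.startswith("property") and in_vertex_element:
            parts = line.split()
            if len(parts) == 3:
                props.append(parts[2])
        elif line == "end_header":
            body_start = i
            break
    if body_start is None or n_vertex is None:
        raise CloudParseError(f"{path}: malformed PLY header (no end_header/vertex element)")
    for axis in ("x", "y", "z"):
        if axis not in props:
            raise CloudParseError(f"{path}: vertex element lacks property {axis!r}")
    cols = [props.index(ax) for ax in ("x", "y", "z")]
    if n_vertex == 0:
        raise ValueError(f"{path}: empty point cloud")
    body = lines[body_start : body_start + n_vertex]
    if len(body) < n_vertex:
        raise CloudParseError(
            f"{path}: expected {n_vertex} vertex rows, file ends after {len(body)}"
        )
    out = np.empty((n_vertex, 3))
    for j, raw in enumerate(body):
        lineno = body_start + 1 + j
        parts = raw.split()
        if len(parts) < len(props):
            raise CloudParseError(
                f"{path}: line {lineno}: expected {len(props)} values, got {len(parts)}"
            )
        try:
            out[j] = [float(parts[c]) for c in cols]
        except ValueError as exc:
            raise CloudParseError(
                f"{path}: line {lineno}: non-numeric coordinate in {raw!r}"
            ) from exc
    return out


def _read_table(path: Path, delimiter: str | None) -> np.ndarray:
    rows = []
    with open(path, "r", errors="replace") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split(delimiter) if delimiter else line.split()
            parts = [p for p in parts if p != ""]
            if len(parts) < 3:
                raise CloudParseError(
                    f"{path}: line {lineno}: expected 3 coordinates, got {len(parts)}"
                )
            try:
                rows.append([float(p) for p in parts[:3]])
            except ValueError as exc:
                raise CloudParseError(
                    f"{path}: line {lineno}: non-numeric coordinate in {line!r}"
                ) from exc
    if not rows:
        raise ValueError(f"{path}: empty point cloud")
    return np.asarray(rows)


def read_cloud(path: str | Path, fmt: str | None = None) -> np.ndarray:
    """Read a point cloud, preserving point order.

    ``fmt`` is one of 'ply', 'xyz', 'csv'; when omitted it is inferred
    from the file suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such cloud file: {path}")
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        pts = _read_ply(path)
    elif fmt == "csv":
        pts = _read_table(path, ",")
    else:
        pts = _read_table(path, None)
    return as_cloud(pts)


def write_cloud(path: str | Path, cloud: np.ndarray, fmt: str | None = None) -> None:
    """Write a point cloud as ASCII PLY, XYZ, or CSV at full precision."""
    path = Path(path)
    pts = as_cloud(cloud)
    fmt = _infer_format(path, fmt)
    if fmt == "ply":
        with open(path, "w") as fh:
            fh.write("ply\nformat ascii 1.0\n")
            fh.write(f"element vertex {pts.shape[0]}\n")
            fh.write("property double x\nproperty double y\nproperty double z\n")
            fh.write("end_header\n")
            for p in pts:
                fh.write(f"{p[0]:.17g} {p[1]:.17g} {p[2]:.17g}\n")
    else:
        sep = "," if fmt == "csv" else " "
        with open(path, "w") as fh:
            for p in pts:
                fh.write(f"{p[0]:.17g}{sep}{p[1]:.17g}{sep}{p[2]:.17g}\n")


def write_report(path: str | Path, report: dict) -> None:
    """Write a JSON run report (floats keep full precision)."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2)
        fh.write("\n")
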