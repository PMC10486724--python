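"""Height-map container and plain-text I/O.

An AFM image is a rectangular grid of surface heights with a known lateral
sampling step. The native on-disk form is a whitespace-separated text matrix
(``<name>.hm.txt``) plus a JSON sidecar (``<name>.hm.json``) carrying the
pixel size, units and free-form metadata; a generic ASCII-grid export with a
``#``-comment header is also importable. All heights and lengths are held in
nanometres internally.

Coordinate convention: indices are 0-based and refer to pixel centres; the
physical position of pixel ``(row, col)`` is ``origin + index * pixel_size``.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "HeightMap", "Profile", "FormatError",
    "read_heightmap", "write_heightmap", "crop_region", "extract_profile",
]

#: multiplicative factors to nanometres
_UNIT_TO_NM = {"m": 1e9, "mm": 1e6, "um": 1e3, "µm": 1e3, "nm": 1.0, "pm": 1e-3}


class FormatError(ValueError):
    """Raised when a height-map file cannot be parsed."""


@dataclass
class HeightMap:
    """Rectangular grid of surface heights (nm) with physical pixel size.

    Parameters
    ----------
    heights : ndarray, shape (rows, cols)
        Surface heights in nm.
    pixel_size_nm : float
        Lateral sampling step, identical in x and y, in nm/pixel.
    origin_nm : tuple of float
        Physical (x, y) coordinates of the centre of pixel (0, 0), in nm.
    metadata : dict
        Free-form key-value annotations.
    """

    heights: np.ndarray
    pixel_size_nm: float
    origin_nm: tuple[float, float] = (0.0, 0.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2:
            raise ValueError("heights must be a 2-D array")
        if self.heights.shape[0] < 2 or self.heights.shape[1] < 2:
            raise ValueError("height map needs at least 2 rows and 2 columns")
        if not np.all(np.isfinite(self.heights)):
            raise ValueError("heights must all be finite")
        if not (self.pixel_size_nm > 0):
            raise ValueError("pixel_size_nm must be positive")
        self.origin_nm = (float(self.origin_nm[0]), float(self.origin_nm[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def field_size_nm(self) -> tuple[float, float]:
        """Physical extent (x, y) in nm, counting full pixels."""
        rows, cols = self.heights.shape
        return cols * self.pixel_size_nm, rows * self.pixel_size_nm

    def copy(self) -> "HeightMap":
        return HeightMap(self.heights.copy(), self.pixel_size_nm,
                         self.origin_nm, dict(self.metadata))


@dataclass
class Profile:
    """1-D height cross-section along a grid row or column."""

    distances_nm: np.ndarray
    heights_nm: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.distances_nm = np.asarray(self.distances_nm, dtype=float)
        self.heights_nm = np.asarray(self.heights_nm, dtype=float)
        if self.distances_nm.shape != self.heights_nm.shape:
            raise ValueError("distances and heights must have equal length")

    @property
    def spacing_nm(self) -> float:
        return float(self.distances_nm[1] - self.distances_nm[0])

    def __len__(self) -> int:
        return len(self.heights_nm)


def _sidecar_path(path: Path) -> Path:
    name = path.name
    if name.endswith(".hm.txt"):
        return path.with_name(name[: -len(".hm.txt")] + ".hm.json")
    return path.with_suffix(path.suffix + ".json")


def write_heightmap(hmap: HeightMap, path) -> None:
    """Write the native text-matrix + JSON-sidecar pair.

    The matrix file holds one row of the grid per line; the sidecar records
    ``pixel_size_nm``, ``units`` (always nm on write), origin and metadata.
    """
    path = Path(path)
    np.savetxt(path, hmap.heights, fmt="%.10g")
    sidecar = {
        "units": "nm",
        "pixel_size_nm": hmap.pixel_size_nm,
        "origin_nm": list(hmap.origin_nm),
        "rows": hmap.shape[0],
        "cols": hmap.shape[1],
        "metadata": hmap.metadata,
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1, sort_keys=True))


def _read_matrix(path: Path) -> np.ndarray:
    rows = []
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            try:
                row = [float(tok) for tok in line.split()]
            except ValueError as exc:
                raise FormatError(f"{path}: non-numeric cell at line {lineno}") from exc
            if width is None:
                width = len(row)
            elif len(row) != width:
                raise FormatError(
                    f"{path}: ragged row at line {lineno} "
                    f"({len(row)} values, expected {width})")
            rows.append(row)
    if not rows:
        raise FormatError(f"{path}: no data rows")
    return np.asarray(rows, dtype=float)


def _read_native(path: Path) -> HeightMap:
    grid = _read_matrix(path)
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise FormatError(f"missing sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    unit = meta.get("units", "nm")
    if unit not in _UNIT_TO_NM:
        raise FormatError(f"{sidecar}: unknown unit {unit!r}")
    scale = _UNIT_TO_NM[unit]
    if "pixel_size_nm" in meta:
        px = float(meta["pixel_size_nm"])
    elif "pixel_size" in meta:
        px = float(meta["pixel_size"]) * scale
    else:
        raise FormatError(f"{sidecar}: missing pixel size")
    origin = tuple(float(v) for v in meta.get("origin_nm", (0.0, 0.0)))
    return HeightMap(grid * scale if unit != "nm" else grid, px,
                     origin, meta.get("metadata", {}))


_ASCII_KV = re.compile(r"#\s*([\w\- ]+?)\s*[:=]\s*(.+?)\s*$")


def _read_asciigrid(path: Path) -> HeightMap:
    """Import a generic AFM ASCII grid: ``#``-comment header then the matrix.

    Recognised header keys (case-insensitive): ``width``/``height`` (pixels),
    ``x-size``/``y-size`` or ``width-physical`` (physical extent, value plus
    unit, e.g. ``5e-06 m`` or ``5000 nm``), ``units`` (height unit).
    """
    header: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            m = _ASCII_KV.match(line.rstrip())
            if m:
                header[m.group(1).strip().lower()] = m.group(2)
    grid = _read_matrix(path)

    def _phys(key: str) -> float | None:
        if key not in header:
            return None
        toks = header[key].split()
        value = float(toks[0])
        unit = toks[1] if len(toks) > 1 else "nm"
        if unit not in _UNIT_TO_NM:
            raise FormatError(f"{path}: unknown unit {unit!r} for {key}")
        return value * _UNIT_TO_NM[unit]

    x_size = _phys("x-size") or _phys("width-physical")
    if x_size is None:
        raise FormatError(f"{path}: header missing physical x-size")
    width_px = int(header.get("width", grid.shape[1]))
    if width_px != grid.shape[1]:
        raise FormatError(
            f"{path}: header width {width_px} != matrix columns {grid.shape[1]}")
    px = x_size / width_px
    hunit = header.get("units", "nm").strip()
    if hunit not in _UNIT_TO_NM:
        raise FormatError(f"{path}: unknown height unit {hunit!r}")
    return HeightMap(grid * _UNIT_TO_NM[hunit], px,
                     metadata={"source": str(path), **header})


def read_heightmap(path, dialect: str = "auto") -> HeightMap:
    """Read a height map from disk.

    Parameters
    ----------
    path : path-like
    dialect : {"auto", "native", "asciigrid"}
        ``native`` expects the text matrix + ``.hm.json`` sidecar;
        ``asciigrid`` a generic export with a ``#``-comment header. ``auto``
        picks native when a sidecar is present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "auto":
        dialect = "native" if _sidecar_path(path).exists() else "asciigrid"
    if dialect == "native":
        return _read_native(path)
    if dialect == "asciigrid":
        return _read_asciigrid(path)
    raise ValueError(f"unknown dialect {dialect!r}")


def crop_region(hmap: HeightMap, center_nm: tuple[float, float],
                width_nm: float, height_nm: float) -> HeightMap:
    """Extract a physical sub-rectangle as a new height map.

    The pixel count per side is ``floor(extent / pixel_size)`` with a floor
    of 2, so the crop never exceeds the requested physical size. The origin
    is updated; pixel size is unchanged.
    """
    px = hmap.pixel_size_nm
    rows, cols = hmap.shape
    if width_nm <= 0 or height_nm <= 0:
        raise IndexError("crop extent must be positive")
    n_cols = max(2, int(np.floor(width_nm / px)))
    n_rows = max(2, int(np.floor(height_nm / px)))
    cx, cy = center_nm
    col0 = round((cx - hmap.origin_nm[0]) / px - n_cols / 2)
    row0 = round((cy - hmap.origin_nm[1]) / px - n_rows / 2)
    if col0 < 0 or row0 < 0 or col0 + n_cols > cols or row0 + n_rows > rows:
        raise IndexError(
            f"crop {n_rows}x{n_cols} at ({row0},{col0}) outside {rows}x{cols} grid")
    sub = hmap.heights[row0:row0 + n_rows, col0:col0 + n_cols].copy()
    origin = (hmap.origin_nm[0] + col0 * px, hmap.origin_nm[1] + row0 * px)
    return HeightMap(sub, px, origin, dict(hmap.metadata))


def extract_profile(hmap: HeightMap, line) -> Profile:
    """Extract an axis-aligned cross-section.

    ``line`` is either an integer (row index), or a ``(axis, index)`` pair
    with axis in {"row", "col"}.
    """
    if isinstance(line, (int, np.integer)):
        axis, idx = "row", int(line)
    else:
        axis, idx = line
        idx = int(idx)
    rows, cols = hmap.shape
    if axis == "row":
        if not 0 <= idx < rows:
            raise IndexError(f"row {idx} outside grid of {rows} rows")
        h = hmap.heights[idx, :].copy()
    elif axis == "col":
        if not 0 <= idx < cols:
            raise IndexError(f"col {idx} outside grid of {cols} cols")
        h = hmap.heights[:, idx].copy()
    else:
        raise ValueError(f"axis must be 'row' or 'col', got {axis!r}")
    d = np.arange(len(h)) * hmap.pixel_size_nm
    return Profile(d, h, source=f"{axis} {idx}")
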