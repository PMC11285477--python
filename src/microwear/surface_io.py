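"""I/O and in-memory containers for gridded surface height maps and result tables.

A :class:`HeightMap` is a regular, axis-aligned grid of surface heights in µm
with lateral point spacings ``dx`` (columns, +x) and ``dy`` (rows, +y) and a
boolean mask flagging non-measured points.  Row index corresponds to y, column
index to x, origin at the top-left; angles are measured counter-clockwise from
+x in [0°, 180°).

Supported formats: ISO 25178-71 aSDF (ASCII "Surface Data File") height maps,
plain CSV grids (empty cell = non-measured), and CSV measurement tables with
the controlled 30-parameter header.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import FormatError, SchemaError
from .registry import ALL_PARAMS, validate_param_names

#: metadata columns of a measurement table, in canonical order
META_COLUMNS = ("specimen", "population", "sex", "age_class", "tooth", "facet", "scan")

TOOTH_VOCAB = ("P4", "M1", "m1", "m2")
FACET_VOCAB = ("3", "9")
SEX_VOCAB = ("female", "male", "unknown")

#: sentinel token for non-measured points in aSDF files
BAD_TOKEN = "BAD"


@dataclass
class HeightMap:
    """Regular grid of surface heights (µm) with a non-measured-point mask.

    ``mask`` is True where a point was NOT measured.  ``meta`` carries
    free-form provenance (specimen id, tooth, facet, scan index, ...).
    """

    heights: np.ndarray
    dx: float
    dy: float
    mask: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.heights = np.asarray(self.heights, dtype=float)
        if self.heights.ndim != 2 or min(self.heights.shape) < 2:
            raise ValueError("height grid must be 2-D with at least 2 rows and 2 columns")
        if not (np.isfinite(self.dx) and np.isfinite(self.dy) and self.dx > 0 and self.dy > 0):
            raise ValueError("dx and dy must be finite and positive")
        if self.mask is None:
            self.mask = np.zeros(self.heights.shape, dtype=bool)
        else:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.heights.shape:
                raise ValueError("mask shape must equal heights shape")
        if not np.all(np.isfinite(self.heights[~self.mask])):
            raise ValueError("unmasked heights must be finite")

    # -- convenience -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.heights.shape

    @property
    def valid(self) -> np.ndarray:
        """Boolean grid of measured points."""
        return ~self.mask

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    @property
    def area(self) -> float:
        """Evaluation area in µm²: valid-point count × dx·dy."""
        return self.n_valid * self.dx * self.dy

    def valid_heights(self) -> np.ndarray:
        return self.heights[self.valid]

    def copy_with(self, heights=None, mask=None, **meta) -> "HeightMap":
        hm = HeightMap(
            heights=self.heights.copy() if heights is None else heights,
            dx=self.dx,
            dy=self.dy,
            mask=self.mask.copy() if mask is None else mask,
            meta={**self.meta, **meta},
        )
        return hm


def fill_nonmeasured(hm: HeightMap) -> HeightMap:
    """Fill masked points by nearest-neighbour and flag the result "filled".

    Feature segmentation and FFT-based spatial parameters require a gap-free
    grid; nearest-neighbour filling never invents heights outside the measured
    range.  A map without masked points is returned unchanged.
    """
    if not hm.mask.any():
        return hm
    if not hm.valid.any():
        raise ValueError("cannot fill a fully masked height map")
    # indices of nearest valid point for every grid node
    _, (ri, ci) = ndimage.distance_transform_edt(
        hm.mask, sampling=(hm.dy, hm.dx), return_indices=True
    )
    filled = hm.heights[ri, ci]
    out = hm.copy_with(heights=filled, mask=np.zeros(hm.shape, dtype=bool), filled=True)
    return out


# ---------------------------------------------------------------------------
# ISO 25178-71 aSDF (ASCII)
# ---------------------------------------------------------------------------

_REQUIRED_SDF_FIELDS = ("NumPoints", "NumProfiles", "Xscale", "Yscale", "Zscale")


def read_sdf(path) -> HeightMap:
    """Read an ISO 25178-71 ASCII SDF height map; heights are scaled to µm.

    The header (``key = value`` records up to the first ``*``) must define
    NumPoints (columns), NumProfiles (rows) and the X/Y/Z scales in metres.
    The token ``BAD`` marks non-measured points.
    """
    with open(path, "r") as fh:
        lines = fh.readlines()
    if not lines:
        raise FormatError(f"{path}: empty file")

    header: dict[str, str] = {}
    i = 1  # line 0 is the version record
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("*"):
            break
        if line and "=" in line:
            key, _, value = line.partition("=")
            header[key.strip()] = value.strip()
        i += 1
    else:
        raise FormatError(f"{path}: missing '*' terminator after header")

    for name in _REQUIRED_SDF_FIELDS:
        if name not in header:
            raise FormatError(f"{path}: header is missing required field {name!r}")
    ncols = int(header["NumPoints"])
    nrows = int(header["NumProfiles"])
    xscale = float(header["Xscale"])
    yscale = float(header["Yscale"])
    zscale = float(header["Zscale"])

    values = np.empty(nrows * ncols, dtype=float)
    maskflat = np.zeros(nrows * ncols, dtype=bool)
    k = 0
    i += 1
    while i < len(lines) and k < values.size:
        line = lines[i].strip()
        if line.startswith("*"):
            break
        for tok in line.split():
            if k >= values.size:
                raise FormatError(f"{path}: more than NumPoints×NumProfiles data tokens")
            if tok.upper() == BAD_TOKEN:
                values[k] = 0.0
                maskflat[k] = True
            else:
                try:
                    values[k] = float(tok)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric height token {tok!r} on line {i + 1}"
                    ) from None
            k += 1
        i += 1
    if k != values.size:
        raise FormatError(f"{path}: expected {values.size} height values, found {k}")

    heights = values.reshape(nrows, ncols) * zscale * 1e6  # m -> µm
    mask = maskflat.reshape(nrows, ncols)
    heights[mask] = 0.0
    meta = {"source": str(path), "format": "sdf"}
    return HeightMap(heights, dx=xscale * 1e6, dy=yscale * 1e6, mask=mask, meta=meta)


def write_sdf(hm: HeightMap, path) -> None:
    """Write a HeightMap as ASCII SDF (scales in metres, heights in Zscale units)."""
    zscale = 1e-6  # 1 µm per stored unit keeps the round trip exact to float precision
    buf = io.StringIO()
    buf.write("aISO-1.0\n")
    buf.write("ManufacID       = microwear\n")
    buf.write("CreateDate      = 000000000000\n")
    buf.write("ModDate         = 000000000000\n")
    buf.write(f"NumPoints       = {hm.shape[1]}\n")
    buf.write(f"NumProfiles     = {hm.shape[0]}\n")
    buf.write(f"Xscale          = {hm.dx * 1e-6:.9e}\n")
    buf.write(f"Yscale          = {hm.dy * 1e-6:.9e}\n")
    buf.write(f"Zscale          = {zscale:.9e}\n")
    buf.write("Zresolution     = -1\n")
    buf.write("Compression     = 0\n")
    buf.write("DataType        = 7\n")
    buf.write("CheckType       = 0\n")
    buf.write("*\n")
    scaled = hm.heights / (zscale * 1e6)
    for r in range(hm.shape[0]):
        toks = [
            BAD_TOKEN if hm.mask[r, c] else f"{scaled[r, c]:.9g}" for c in range(hm.shape[1])
        ]
        buf.write(" ".join(toks) + "\n")
    buf.write("*\n")
    with open(path, "w") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# plain CSV grid
# ---------------------------------------------------------------------------


def read_csv_grid(path, dx: float, dy: float) -> HeightMap:
    """Read a rectangular numeric CSV as a HeightMap; empty cells become masked."""
    import csv

    rows: list[list[str]] = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if row:
                rows.append(row)
    if not rows:
        raise FormatError(f"{path}: empty CSV grid")
    width = len(rows[0])
    heights = np.zeros((len(rows), width))
    mask = np.zeros((len(rows), width), dtype=bool)
    for r, row in enumerate(rows):
        if len(row) != width:
            raise FormatError(
                f"{path}: ragged CSV — row {r + 1} has {len(row)} cells, expected {width}"
            )
        for c, cell in enumerate(row):
            cell = cell.strip()
            if cell == "":
                mask[r, c] = True
            else:
                try:
                    heights[r, c] = float(cell)
                except ValueError:
                    raise FormatError(
                        f"{path}: non-numeric cell {cell!r} at row {r + 1}, column {c + 1}"
                    ) from None
    return HeightMap(heights, dx=dx, dy=dy, mask=mask, meta={"source": str(path), "format": "csv"})


def write_csv_grid(hm: HeightMap, path) -> None:
    with open(path, "w") as fh:
        for r in range(hm.shape[0]):
            cells = ["" if hm.mask[r, c] else f"{hm.heights[r, c]:.9g}" for c in range(hm.shape[1])]
            fh.write(",".join(cells) + "\n")


# ---------------------------------------------------------------------------
# measurement table
# ---------------------------------------------------------------------------


@dataclass
class MeasurementTable:
    """Per-scan texture parameters with specimen/group metadata.

    Wraps a DataFrame with the metadata columns of :data:`META_COLUMNS`
    followed by the 30 registry parameter columns (and an optional free-form
    ``flags`` column recording degenerate/shortfall conditions per scan).
    """

    data: pd.DataFrame

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.data
        missing_meta = [c for c in META_COLUMNS if c not in df.columns]
        if missing_meta:
            raise SchemaError(f"missing metadata columns: {missing_meta}")
        param_cols = [c for c in df.columns if c not in META_COLUMNS and c != "flags"]
        validate_param_names(param_cols)
        if len(df) and df.duplicated(subset=["specimen", "tooth", "facet", "scan"]).any():
            raise SchemaError("duplicated (specimen, tooth, facet, scan) keys")

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other) -> bool:
        if not isinstance(other, MeasurementTable):
            return NotImplemented
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        if list(a.columns) != list(b.columns) or len(a) != len(b):
            return False
        for c in a.columns:
            if a[c].dtype.kind == "f":
                if not np.allclose(a[c], b[c], rtol=1e-9, atol=0, equal_nan=True):
                    return False
            elif not a[c].astype(str).equals(b[c].astype(str)):
                return False
        return True

    def subset(self, **filters) -> "MeasurementTable":
        """Rows matching all equality ``filters`` (values may be lists)."""
        df = self.data
        for col, val in filters.items():
            wanted = val if isinstance(val, (list, tuple, set)) else [val]
            df = df[df[col].astype(str).isin([str(v) for v in wanted])]
        return MeasurementTable(df.reset_index(drop=True))


def empty_table() -> MeasurementTable:
    cols = list(META_COLUMNS) + list(ALL_PARAMS)
    return MeasurementTable(pd.DataFrame({c: pd.Series(dtype=float if c in ALL_PARAMS else str) for c in cols}))


def write_table(table: MeasurementTable, path) -> None:
    """Serialize the table as CSV with >= 9 significant digits."""
    table.data.to_csv(path, index=False, float_format="%.10g")


def read_table(path) -> MeasurementTable:
    df = pd.read_csv(path, dtype={c: str for c in META_COLUMNS})
    if "flags" in df.columns:
        df["flags"] = df["flags"].fillna("").astype(str)
    for c in ALL_PARAMS:
        if c in df.columns:
            df[c] = df[c].astype(float)
    return MeasurementTable(df)
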