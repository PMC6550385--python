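"""Reading, validating, unit-converting and QC-filtering single-cell tables.

Multiplexed immunofluorescence platforms emit one row per segmented cell with
the centroid coordinates (in pixels), per-marker fluorescence intensities
(optionally per subcellular compartment), and per-cell quality-control
metrics: a nuclear alignment score in [0, 1] describing how well the cell's
image registered across staining rounds, the pixel count of each subcellular
compartment, and the number of nuclei assigned to the cell.  This module
turns such a delimited file into a validated :class:`CellTable` in micron
coordinates, and filters out poorly aligned, poorly segmented, or artifactual
cells.

The canonical in-memory container is a :class:`pandas.DataFrame` wrapped in
:class:`CellTable`, which additionally tracks the coordinate unit and the
marker column names.  Downstream modules add ``phenotype`` and
``hla1_status`` columns but never change the row identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError, SchemaError

__all__ = [
    "CellTable",
    "ColumnSchema",
    "FOVWindow",
    "QCConfig",
    "QCReport",
    "read_cell_table",
    "write_cell_table",
    "pixels_to_microns",
    "apply_qc",
]

#: canonical QC / identity column names used throughout the package
MANDATORY_COLUMNS = ("cell_id", "fov_id", "x", "y")
COMPARTMENTS = ("nucleus", "membrane", "cytoplasm")
COMPARTMENT_PIXEL_COLUMNS = tuple(f"{c}_pixels" for c in COMPARTMENTS)
QC_COLUMNS = ("qc_alignment",) + COMPARTMENT_PIXEL_COLUMNS + ("n_nuclei",)


@dataclass(frozen=True)
class ColumnSchema:
    """Mapping from the canonical column names to the columns of an input file.

    ``columns`` maps canonical names (``cell_id``, ``fov_id``, ``sample_id``,
    ``x``, ``y``, ``qc_alignment``, ``nucleus_pixels``, ``membrane_pixels``,
    ``cytoplasm_pixels``, ``n_nuclei``) to the file's column names; ``markers``
    maps marker names (e.g. ``"CD3"``) to intensity columns.  ``unit`` declares
    the coordinate unit of the file, ``"px"`` or ``"um"``.
    """

    columns: Mapping[str, str] = field(default_factory=dict)
    markers: Mapping[str, str] = field(default_factory=dict)
    unit: str = "um"

    def source(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)

    @classmethod
    def from_dict(cls, d: Mapping) -> "ColumnSchema":
        return cls(
            columns=dict(d.get("columns", {})),
            markers=dict(d.get("markers", {})),
            unit=d.get("unit", "um"),
        )


@dataclass
class CellTable:
    """A per-cell table with canonical columns plus marker intensities.

    Parameters
    ----------
    data
        One row per cell.  Canonical columns as in :class:`ColumnSchema`;
        marker intensities live in the columns named by ``markers``; any
        further columns are passthrough metadata and are preserved verbatim.
    unit
        Coordinate unit of ``x``/``y``: ``"px"`` or ``"um"``.
    markers
        Names of the marker intensity columns.
    meta
        Free-form provenance (thresholds used, config hashes, ...).
    """

    data: pd.DataFrame
    unit: str = "um"
    markers: tuple[str, ...] = ()
    meta: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def fov_ids(self) -> list:
        return list(pd.unique(self.data["fov_id"]))

    def for_fov(self, fov_id) -> "CellTable":
        """Sub-table restricted to one field of view (row order preserved)."""
        sub = self.data[self.data["fov_id"] == fov_id]
        return CellTable(sub.reset_index(drop=True), self.unit, self.markers, dict(self.meta))

    def subset(self, mask: np.ndarray) -> "CellTable":
        sub = self.data.loc[np.asarray(mask, dtype=bool)]
        return CellTable(sub.reset_index(drop=True), self.unit, self.markers, dict(self.meta))

    def coords(self) -> np.ndarray:
        """(n, 2) array of x/y coordinates."""
        return self.data[["x", "y"]].to_numpy(dtype=float)

    def validate(self) -> None:
        """Check structural invariants; raise :class:`DataError` on breach."""
        for col in MANDATORY_COLUMNS:
            if col not in self.data.columns:
                raise SchemaError(f"missing mandatory column {col!r}")
        xy = self.data[["x", "y"]].to_numpy()
        if not np.isfinite(xy).all():
            bad = int(np.where(~np.isfinite(xy).all(axis=1))[0][0])
            raise DataError(f"non-finite coordinate at row {bad}")
        if "qc_alignment" in self.data.columns:
            a = self.data["qc_alignment"].dropna()
            if ((a < 0) | (a > 1)).any():
                raise DataError("qc_alignment outside [0, 1]")
        if "n_nuclei" in self.data.columns:
            n = self.data["n_nuclei"].dropna()
            if (n < 0).any():
                raise DataError("negative n_nuclei")
        for m in self.markers:
            v = self.data[m].dropna()
            if (v < 0).any():
                raise DataError(f"negative intensity for marker {m!r}")


@dataclass(frozen=True)
class FOVWindow:
    """Rectangular analysis window of one field of view, in microns."""

    fov_id: object
    x_min: float
    x_max: float
    y_min: float
    y_max: float

    def __post_init__(self):
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ConfigError("FOVWindow requires x_min < x_max and y_min < y_max")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @classmethod
    def from_cells(cls, table: CellTable, fov_id=None, margin: float = 0.0) -> "FOVWindow":
        """Tight bounding box of the FOV's cells, expandable by ``margin`` μm.

        With a zero margin and a single cell (or collinear cells) the tight
        box would be degenerate; a minimal epsilon is added in that case.
        """
        sub = table if fov_id is None else table.for_fov(fov_id)
        if len(sub) == 0:
            raise DataError(f"no cells for FOV {fov_id!r}")
        xy = sub.coords()
        x0, y0 = xy.min(axis=0) - margin
        x1, y1 = xy.max(axis=0) + margin
        eps = 1e-9
        if x1 - x0 <= 0:
            x1 = x0 + eps
        if y1 - y0 <= 0:
            y1 = y0 + eps
        fid = fov_id if fov_id is not None else sub.data["fov_id"].iloc[0]
        return cls(fid, float(x0), float(x1), float(y0), float(y1))

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return (x >= self.x_min) & (x <= self.x_max) & (y >= self.y_min) & (y <= self.y_max)


@dataclass(frozen=True)
class QCConfig:
    """Per-cell quality-control thresholds (all boundaries inclusive).

    Defaults follow the acquisition platform's recommended filters: nuclear
    alignment ≥ 0.85, ≥ 10 pixels in each of the nucleus / membrane /
    cytoplasm compartments, and ≤ 2 nuclei per cell.  ``min_round_alignment``
    is an optional second alignment metric (alignment through all staining
    rounds); it is disabled (``None``) by default because no standard cutoff
    exists for it.
    """

    min_alignment: float = 0.85
    min_pixels_per_compartment: int = 10
    max_nuclei: int = 2
    pixel_size_um: float | None = None
    min_round_alignment: float | None = None
    on_missing: str = "reject"  # "reject" | "pass"

    def __post_init__(self):
        if not (0.0 <= self.min_alignment <= 1.0):
            raise ConfigError("min_alignment must be in [0, 1]")
        if self.min_pixels_per_compartment < 0:
            raise ConfigError("min_pixels_per_compartment must be >= 0")
        if self.max_nuclei < 1:
            raise ConfigError("max_nuclei must be >= 1")
        if self.pixel_size_um is not None and self.pixel_size_um <= 0:
            raise ConfigError("pixel_size_um must be > 0")
        if self.on_missing not in ("reject", "pass"):
            raise ConfigError("on_missing must be 'reject' or 'pass'")


@dataclass
class QCReport:
    """Bookkeeping from :func:`apply_qc`.

    ``excluded_by_rule`` counts failures per rule; a cell can fail several
    rules, so the per-rule counts may sum to more than ``n_excluded``.
    """

    n_input: int
    n_retained: int
    n_excluded: int
    excluded_by_rule: dict[str, int]
    empty_result: bool

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_retained": self.n_retained,
            "n_excluded": self.n_excluded,
            "excluded_by_rule": dict(self.excluded_by_rule),
            "empty_result": self.empty_result,
        }


def read_cell_table(path, schema: ColumnSchema | Mapping | None = None, sep: str = ",") -> CellTable:
    """Read a delimited per-cell table into a validated :class:`CellTable`.

    Parameters
    ----------
    path
        CSV/TSV file with one row per cell.
    schema
        :class:`ColumnSchema` (or a plain dict accepted by
        :meth:`ColumnSchema.from_dict`) mapping canonical names and markers
        to the file's columns.  With no schema, canonical column names are
        assumed and every unrecognised numeric column is ignored as
        passthrough metadata (no marker columns are declared).

    Raises
    ------
    SchemaError
        If a mapped or mandatory column is absent.
    DataError
        If a coordinate fails to parse as a number (the offending row index
        is named) or a validated field breaks its invariant.
    """
    path = Path(path)
    if schema is None:
        schema = ColumnSchema()
    elif not isinstance(schema, ColumnSchema):
        schema = ColumnSchema.from_dict(schema)

    raw = pd.read_csv(path, sep=sep)
    rename: dict[str, str] = {}
    for canonical in MANDATORY_COLUMNS + ("sample_id",) + QC_COLUMNS + ("qc_round_alignment", "phenotype", "hla1_status"):
        src = schema.source(canonical)
        if src in raw.columns:
            rename[src] = canonical
        elif canonical in MANDATORY_COLUMNS:
            raise SchemaError(f"missing mandatory column {canonical!r} (looked for {src!r}) in {path.name}")
    for marker, src in schema.markers.items():
        if src not in raw.columns:
            raise SchemaError(f"missing marker column {src!r} for marker {marker!r}")
        rename[src] = marker
    data = raw.rename(columns=rename)

    for col in ("x", "y"):
        parsed = pd.to_numeric(data[col], errors="coerce")
        bad = parsed.isna() & data[col].notna()
        if bad.any():
            raise DataError(f"non-numeric {col!r} at row {int(np.where(bad)[0][0])} of {path.name}")
        if parsed.isna().any():
            raise DataError(f"missing {col!r} at row {int(np.where(parsed.isna())[0][0])} of {path.name}")
        data[col] = parsed.astype(float)

    table = CellTable(data=data, unit=schema.unit, markers=tuple(schema.markers), meta={"source": str(path)})
    table.validate()
    return table


def write_cell_table(table: CellTable, path, sep: str = ",") -> Path:
    """Write a cell table with canonical column names; round-trips with
    :func:`read_cell_table` under the default schema (same unit flag must be
    re-declared by the reader's schema)."""
    path = Path(path)
    table.data.to_csv(path, sep=sep, index=False)
    return path


def pixels_to_microns(table: CellTable, pixel_size_um: float) -> CellTable:
    """Convert centroid coordinates from pixels to microns.

    Idempotent: a table already flagged as micron-based is returned unchanged,
    so accidental double conversion is impossible.
    """
    if pixel_size_um is None or pixel_size_um <= 0:
        raise ConfigError("pixel_size_um must be a positive number")
    if table.unit == "um":
        return table
    if table.unit != "px":
        raise DataError(f"unknown coordinate unit {table.unit!r}")
    data = table.data.copy()
    data["x"] = data["x"] * pixel_size_um
    data["y"] = data["y"] * pixel_size_um
    meta = dict(table.meta)
    meta["pixel_size_um"] = pixel_size_um
    return CellTable(data=data, unit="um", markers=table.markers, meta=meta)


def apply_qc(table: CellTable, cfg: QCConfig | None = None) -> tuple[CellTable, QCReport]:
    """Filter out cells failing the per-cell quality-control rules.

    Retention requires (inclusively) ``qc_alignment >= min_alignment``, every
    compartment pixel count ``>= min_pixels_per_compartment``, and
    ``n_nuclei <= max_nuclei``.  Filtering is per-cell independent.  Cells
    with missing QC fields are rejected by default (``cfg.on_missing``).

    Returns the retained table and a :class:`QCReport` with per-rule
    exclusion counts.
    """
    if cfg is None:
        cfg = QCConfig()
    n = len(table)
    fail = {}

    def _col(name):
        if name in table.data.columns:
            return pd.to_numeric(table.data[name], errors="coerce")
        return pd.Series(np.nan, index=table.data.index)

    align = _col("qc_alignment")
    fail["alignment"] = (align < cfg.min_alignment).to_numpy()
    missing = align.isna().to_numpy()

    pix_fail = np.zeros(n, dtype=bool)
    for col in COMPARTMENT_PIXEL_COLUMNS:
        v = _col(col)
        pix_fail |= (v < cfg.min_pixels_per_compartment).to_numpy()
        missing |= v.isna().to_numpy()
    fail["compartment_pixels"] = pix_fail

    nuc = _col("n_nuclei")
    fail["n_nuclei"] = (nuc > cfg.max_nuclei).to_numpy()
    missing |= nuc.isna().to_numpy()

    if cfg.min_round_alignment is not None:
        ra = _col("qc_round_alignment")
        fail["round_alignment"] = (ra < cfg.min_round_alignment).to_numpy()
        missing |= ra.isna().to_numpy()

    if cfg.on_missing == "reject":
        fail["missing_qc"] = missing

    any_fail = np.zeros(n, dtype=bool)
    for f in fail.values():
        any_fail |= f

    retained = table.subset(~any_fail)
    report = QCReport(
        n_input=n,
        n_retained=len(retained),
        n_excluded=int(any_fail.sum()),
        excluded_by_rule={k: int(v.sum()) for k, v in fail.items()},
        empty_result=len(retained) == 0,
    )
    return retained, report


def combine(tables: Iterable[CellTable]) -> CellTable:
    """Concatenate cell tables (same unit); marker set is the union."""
    tables = list(tables)
    if not tables:
        raise DataError("no tables to combine")
    units = {t.unit for t in tables}
    if len(units) != 1:
        raise DataError(f"mixed coordinate units: {sorted(units)}")
    markers: list[str] = []
    for t in tables:
        for m in t.markers:
            if m not in markers:
                markers.append(m)
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return CellTable(data=data, unit=tables[0].unit, markers=tuple(markers))
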