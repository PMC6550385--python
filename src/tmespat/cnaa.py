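"""Cell Neighborhood Analysis Algorithm (CNAA).

For every cell of a chosen *center* class the algorithm draws a circular
neighborhood of radius R (default 12 μm, the optimum found by scanning
neighborhood sizes 2–50 μm), counts the cells of each class inside it, and
measures the nearest-neighbor distance (NND) from the center to each target
class.  Distances are Euclidean in the μm plane; the boundary is inclusive
(d ≤ R) and the center cell never counts itself.  NNDs are
neighborhood-bounded: when no target-class cell lies within R the NND is
missing (an optional unbounded mode exists for diagnostics).

Records can be tagged by region — inside or outside the infiltration areas
produced by the aggregation algorithm — and summarised with a two-stage
mean: per-FOV mean of the per-cell NNDs, then the unweighted mean across
FOVs (a cell-weighted pooled mean is reported alongside).

Neighborhood queries use a k-d tree per FOV; correctness against the O(n²)
all-pairs computation is enforced by the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .caa import InfiltrationArea, region_mask
from .errors import ConfigError, DataError
from .io import CellTable
from .phenotype import class_mask

__all__ = [
    "NeighborhoodConfig",
    "neighborhoods",
    "tag_regions",
    "summarize_nnd",
]

REGION_INSIDE = "inside_IA"
REGION_OUTSIDE = "outside_IA"
REGION_NONE = "none"


@dataclass(frozen=True)
class NeighborhoodConfig:
    """Parameters of the neighborhood scan.

    radius_um
        Neighborhood radius in μm (default 12).
    center_classes
        Classes whose cells anchor neighborhoods (one record per such cell).
    counted_classes
        Classes counted inside each neighborhood (``count_<class>``
        columns).
    nnd_pairs
        (center class, target class) pairs for which the NND is measured;
        ``nnd_<target>`` columns are filled only on rows whose center class
        appears in a pair with that target.
    bounded
        When False, NNDs are measured over the whole FOV instead of being
        limited to the neighborhood (diagnostic mode).
    """

    radius_um: float = 12.0
    center_classes: tuple[str, ...] = ("CD3",)
    counted_classes: tuple[str, ...] = ("Tumor", "HLA1pos", "HLA1neg", "CD3", "CD20", "CD8PD1", "CD4FOXP3")
    nnd_pairs: tuple[tuple[str, str], ...] = (("CD3", "HLA1pos"), ("CD3", "HLA1neg"))
    bounded: bool = True

    def __post_init__(self):
        if self.radius_um <= 0:
            raise ConfigError("radius_um must be > 0")


def neighborhoods(cells: CellTable, cfg: NeighborhoodConfig | None = None) -> pd.DataFrame:
    """Per-center-cell neighborhood composition and NNDs.

    Returns a long-format frame with one row per center cell: identity
    (``cell_id``, ``fov_id``, ``sample_id`` if present, ``center_class``,
    ``x``, ``y``), one ``count_<class>`` column per counted class (center
    excluded from its own counts), one ``nnd_<target>`` column per NND
    target (NaN when missing), and a ``region`` column initialised to
    ``"none"``.
    """
    if cfg is None:
        cfg = NeighborhoodConfig()
    if "phenotype" not in cells.data.columns:
        raise DataError("phenotypes must be assigned before neighborhood analysis")

    nnd_targets = sorted({t for _, t in cfg.nnd_pairs})
    pair_targets: dict[str, set[str]] = {}
    for c, t in cfg.nnd_pairs:
        pair_targets.setdefault(c, set()).add(t)

    rows: list[dict] = []
    for fov in cells.fov_ids:
        sub = cells.for_fov(fov)
        xy = sub.coords()
        n = len(sub)
        if n == 0:
            continue
        masks = {lab: class_mask(sub, lab) for lab in set(cfg.counted_classes) | set(nnd_targets) | set(cfg.center_classes)}
        tree = cKDTree(xy)
        center_idx = np.where(np.any([masks[c] for c in cfg.center_classes], axis=0))[0] if cfg.center_classes else np.array([], dtype=int)
        if center_idx.size == 0:
            continue
        neigh_lists = tree.query_ball_point(xy[center_idx], r=cfg.radius_um)
        pheno = sub.data["phenotype"].to_numpy()
        has_sample = "sample_id" in sub.data.columns
        for k, i in enumerate(center_idx):
            nb = np.array([j for j in neigh_lists[k] if j != i], dtype=int)
            d = np.sqrt(((xy[nb] - xy[i]) ** 2).sum(axis=1)) if nb.size else np.empty(0)
            center_class = next(c for c in cfg.center_classes if masks[c][i])
            rec = {
                "cell_id": sub.data["cell_id"].iloc[i],
                "fov_id": fov,
                "center_class": center_class,
                "x": xy[i, 0],
                "y": xy[i, 1],
                "region": REGION_NONE,
            }
            if has_sample:
                rec["sample_id"] = sub.data["sample_id"].iloc[i]
            for lab in cfg.counted_classes:
                rec[f"count_{lab}"] = int(masks[lab][nb].sum()) if nb.size else 0
            for lab in nnd_targets:
                if lab not in pair_targets.get(center_class, ()):  # pair not requested for this center class
                    rec[f"nnd_{lab}"] = np.nan
                    continue
                if cfg.bounded:
                    sel = masks[lab][nb] if nb.size else np.empty(0, dtype=bool)
                    rec[f"nnd_{lab}"] = float(d[sel].min()) if nb.size and sel.any() else np.nan
                else:
                    cand = np.where(masks[lab])[0]
                    cand = cand[cand != i]
                    if cand.size:
                        dd = np.sqrt(((xy[cand] - xy[i]) ** 2).sum(axis=1))
                        rec[f"nnd_{lab}"] = float(dd.min())
                    else:
                        rec[f"nnd_{lab}"] = np.nan
            rows.append(rec)

    cols = ["cell_id", "fov_id"] + (["sample_id"] if "sample_id" in cells.data.columns else []) + [
        "center_class", "x", "y", "region",
    ] + [f"count_{lab}" for lab in cfg.counted_classes] + [f"nnd_{lab}" for lab in nnd_targets]
    df = pd.DataFrame(rows, columns=cols)
    df.attrs["radius_um"] = cfg.radius_um
    return df


def tag_regions(records: pd.DataFrame, ia: InfiltrationArea) -> pd.DataFrame:
    """Tag each record ``inside_IA``/``outside_IA`` by boundary-inclusive
    point-in-polygon of the center cell against the FOV's IA polygon.
    Records of other FOVs raise :class:`DataError`."""
    out = records.copy()
    sel = out["fov_id"] == ia.fov_id
    if not sel.all():
        raise DataError("records contain FOVs other than the infiltration area's")
    if ia.polygon.is_empty:
        out.loc[sel, "region"] = REGION_OUTSIDE
        return out
    import shapely

    pts = shapely.points(out.loc[sel, ["x", "y"]].to_numpy(dtype=float))
    inside = shapely.covers(ia.polygon, pts)
    out.loc[sel, "region"] = np.where(inside, REGION_INSIDE, REGION_OUTSIDE)
    return out


def summarize_nnd(
    records: pd.DataFrame,
    group_keys: Sequence[str] = ("region",),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Two-stage NND summary.

    Per group (``group_keys`` ⊆ {sample_id, region, center_class} plus the
    implicit NND target), first the mean of per-cell NNDs within each FOV,
    then the unweighted mean across FOVs.  FOVs where every NND of a pair is
    missing are excluded from that pair's cross-FOV mean and flagged in the
    per-FOV table.

    Returns
    -------
    per_fov : DataFrame
        One row per (group, fov, target): ``mean_nnd_um``, ``n_cells``.
    summary : DataFrame
        One row per (group, target): ``mean_nnd_um`` (unweighted across
        FOVs), ``mean_nnd_um_cell_weighted`` (pooled over cells),
        ``n_fovs``, ``n_cells``.
    """
    nnd_cols = [c for c in records.columns if c.startswith("nnd_")]
    if not nnd_cols:
        raise DataError("records contain no NND columns")
    long = records.melt(
        id_vars=[c for c in records.columns if not c.startswith("nnd_")],
        value_vars=nnd_cols,
        var_name="target",
        value_name="nnd_um",
    )
    long["target"] = long["target"].str.removeprefix("nnd_")
    keys = [k for k in group_keys if k in long.columns]

    per_fov = (
        long.groupby(keys + ["fov_id", "target"], dropna=False, observed=True)["nnd_um"]
        .agg(mean_nnd_um="mean", n_cells=lambda s: int(s.notna().sum()))
        .reset_index()
    )
    per_fov["all_missing"] = per_fov["n_cells"] == 0

    valid = per_fov[~per_fov["all_missing"]]
    summary = (
        valid.groupby(keys + ["target"], dropna=False, observed=True)
        .agg(mean_nnd_um=("mean_nnd_um", "mean"), n_fovs=("fov_id", "nunique"), n_cells=("n_cells", "sum"))
        .reset_index()
    )
    pooled = (
        long.dropna(subset=["nnd_um"])
        .groupby(keys + ["target"], dropna=False, observed=True)["nnd_um"]
        .mean()
        .rename("mean_nnd_um_cell_weighted")
        .reset_index()
    )
    summary = summary.merge(pooled, on=keys + ["target"], how="left")
    return per_fov, summary
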