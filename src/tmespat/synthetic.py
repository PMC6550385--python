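"""Synthetic FOV generator with known ground truth.

Emulates the spatial structure of a melanoma tumor microenvironment as seen
in multiplexed immunofluorescence cell tables: clustered tumor nests (disc-
shaped, uniform density) containing a mixture of HLA-1 positive and negative
tumor cells; immune cells (CD3 T cells, CD20 B cells, CD8+PD1+ cytotoxic
T cells, CD4+FOXP3+ regulatory T cells) scattered over the window; and a
tunable *attraction* of CD3 cells to HLA-1+ tumor cells, implemented as a
displacement-kernel mixture: with probability ``attraction/(1+attraction)``
a CD3 cell is planted at a Gaussian offset (scale ``attraction_sigma_um``)
from a randomly chosen HLA-1+ tumor cell, otherwise uniformly.  At
``attraction=0`` CD3 placement is complete spatial randomness.

Marker intensities are drawn from separated lognormal distributions
(positive vs background), so rule-based phenotyping recovers the true
labels with a small, known error rate.  A configurable fraction of cells
receives failing QC values; those cells — and exactly those — are removed
by the default QC filter.

All randomness flows from a single integer seed; tables are emitted in μm
and pass the I/O layer's validation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError
from .io import CellTable, FOVWindow, combine

__all__ = ["SyntheticConfig", "GroundTruth", "generate_fov", "generate_cohort", "SyntheticCohort"]

MARKERS = ("S100", "HLA1", "CD3", "CD20", "CD8", "PD1", "CD4", "FOXP3")

#: which markers are truly positive for each true class (HLA1 handled per status)
CLASS_MARKERS = {
    "Tumor": ("S100",),
    "CD3": ("CD3", "HLA1"),
    "CD20": ("CD20", "HLA1"),
    "CD8PD1": ("CD3", "CD8", "PD1", "HLA1"),
    "CD4FOXP3": ("CD3", "CD4", "FOXP3", "HLA1"),
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Ground-truth parameters of one synthetic FOV.

    Geometry is in μm.  ``n_immune`` gives the number of cells per immune
    class.  ``attraction`` ≥ 0 tunes CD3 placement (see module docstring);
    ``hla1pos_fraction`` is the per-cluster probability that a tumor cell is
    HLA-1 positive.  Intensity scales: positive markers ~
    LogNormal(ln ``intensity_pos``, ``intensity_sigma``), background ~
    LogNormal(ln ``intensity_bg``, ``intensity_sigma``); the default
    phenotype threshold of 30 sits between them.
    """

    seed: int = 0
    fov_id: str = "FOV01"
    sample_id: str = "S1"
    width_um: float = 1000.0
    height_um: float = 1000.0
    n_clusters: int = 3
    cluster_radius_um: float = 120.0
    cells_per_cluster: int = 300
    cluster_centers: tuple[tuple[float, float], ...] | None = None
    hla1pos_fraction: float = 0.7
    n_immune: dict = field(default_factory=lambda: {"CD3": 300, "CD20": 100, "CD8PD1": 100, "CD4FOXP3": 80})
    attraction: float = 0.0
    attraction_sigma_um: float = 8.0
    qc_fail_fraction: float = 0.0
    intensity_pos: float = 100.0
    intensity_bg: float = 5.0
    intensity_sigma: float = 0.3

    def __post_init__(self):
        if self.width_um <= 0 or self.height_um <= 0:
            raise ConfigError("window dimensions must be positive")
        if not (0 <= self.hla1pos_fraction <= 1):
            raise ConfigError("hla1pos_fraction must be in [0, 1]")
        if self.attraction < 0:
            raise ConfigError("attraction must be >= 0")
        if not (0 <= self.qc_fail_fraction <= 1):
            raise ConfigError("qc_fail_fraction must be in [0, 1]")
        if self.n_clusters > 0 and (
            2 * self.cluster_radius_um > self.width_um or 2 * self.cluster_radius_um > self.height_um
        ):
            raise ConfigError("cluster diameter exceeds the window")


@dataclass
class GroundTruth:
    """What the generator actually planted, keyed by ``cell_id``."""

    config: SyntheticConfig
    clusters: list[tuple[float, float, float]]  # (cx, cy, radius)
    true_class: pd.Series
    true_hla: pd.Series  # "HLA1pos"/"HLA1neg" for tumor cells, "" otherwise
    qc_fail: pd.Series

    def planted_squares(self, window: FOVWindow, square_size_um: float) -> set[tuple[int, int]]:
        """Grid squares whose center lies inside a planted tumor cluster —
        the ground truth against which aggregate recovery is scored."""
        s = square_size_um
        import math

        n_cols = max(1, math.ceil((window.width - 1e-12) / s))
        n_rows = max(1, math.ceil((window.height - 1e-12) / s))
        squares = set()
        for r in range(n_rows):
            for c in range(n_cols):
                cx = window.x_min + (c + 0.5) * s
                cy = window.y_min + (r + 0.5) * s
                for qx, qy, rad in self.clusters:
                    if (cx - qx) ** 2 + (cy - qy) ** 2 <= rad ** 2:
                        squares.add((r, c))
                        break
        return squares

    def sidecar(self) -> dict:
        """JSON-serialisable ground-truth record."""
        return {
            "config": asdict(self.config),
            "clusters": [list(c) for c in self.clusters],
            "true_class": self.true_class.to_dict(),
            "true_hla": self.true_hla.to_dict(),
            "qc_fail": {k: bool(v) for k, v in self.qc_fail.items()},
        }


def _uniform_in_disc(rng, n, cx, cy, radius):
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _intensities(rng, n, positive_markers, cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    out = {}
    for m in MARKERS:
        mu = np.log(cfg.intensity_pos) if m in positive_markers else np.log(cfg.intensity_bg)
        out[m] = rng.lognormal(mean=mu, sigma=cfg.intensity_sigma, size=n)
    return out


def generate_fov(cfg: SyntheticConfig) -> tuple[CellTable, GroundTruth]:
    """Generate one synthetic FOV cell table plus its ground truth.

    Deterministic given ``cfg.seed``.  Tumor cells are uniform within each
    cluster disc; HLA status is i.i.d. Bernoulli(``hla1pos_fraction``) per
    cell; CD3 cells follow the attraction mixture; other immune classes are
    uniform over the window.
    """
    rng = np.random.default_rng(cfg.seed)

    # cluster geometry
    if cfg.cluster_centers is not None:
        clusters = [(float(x), float(y), cfg.cluster_radius_um) for x, y in cfg.cluster_centers]
    else:
        clusters = []
        rad = cfg.cluster_radius_um
        for _ in range(cfg.n_clusters):
            cx = rng.uniform(rad, cfg.width_um - rad)
            cy = rng.uniform(rad, cfg.height_um - rad)
            clusters.append((float(cx), float(cy), rad))
    for cx, cy, rad in clusters:
        if cx - rad < 0 or cx + rad > cfg.width_um or cy - rad < 0 or cy + rad > cfg.height_um:
            raise ConfigError("cluster disc extends beyond the window")

    xs, ys, classes, hla = [], [], [], []

    # tumor cells
    tumor_xy = []
    for cx, cy, rad in clusters:
        pts = _uniform_in_disc(rng, cfg.cells_per_cluster, cx, cy, rad)
        tumor_xy.append(pts)
    tumor_xy = np.vstack(tumor_xy) if clusters else np.empty((0, 2))
    n_tumor = len(tumor_xy)
    tumor_pos = rng.uniform(size=n_tumor) < cfg.hla1pos_fraction
    xs.append(tumor_xy[:, 0]); ys.append(tumor_xy[:, 1])
    classes += ["Tumor"] * n_tumor
    hla += ["HLA1pos" if p else "HLA1neg" for p in tumor_pos]

    pos_tumor_xy = tumor_xy[tumor_pos]

    # CD3 cells: attraction mixture toward HLA-1+ tumor cells
    n_cd3 = int(cfg.n_immune.get("CD3", 0))
    w = cfg.attraction / (1.0 + cfg.attraction)
    cd3_pts = np.empty((n_cd3, 2))
    for i in range(n_cd3):
        if len(pos_tumor_xy) and rng.uniform() < w:
            anchor = pos_tumor_xy[rng.integers(len(pos_tumor_xy))]
            for _ in range(50):  # resample until inside the window
                p = anchor + rng.normal(scale=cfg.attraction_sigma_um, size=2)
                if 0 <= p[0] <= cfg.width_um and 0 <= p[1] <= cfg.height_um:
                    break
            else:
                p = np.clip(anchor, [0, 0], [cfg.width_um, cfg.height_um])
            cd3_pts[i] = p
        else:
            cd3_pts[i] = rng.uniform([0, 0], [cfg.width_um, cfg.height_um])
    xs.append(cd3_pts[:, 0]); ys.append(cd3_pts[:, 1])
    classes += ["CD3"] * n_cd3
    hla += [""] * n_cd3

    # other immune classes: uniform
    for lab in ("CD20", "CD8PD1", "CD4FOXP3"):
        n = int(cfg.n_immune.get(lab, 0))
        pts = rng.uniform([0, 0], [cfg.width_um, cfg.height_um], size=(n, 2))
        xs.append(pts[:, 0]); ys.append(pts[:, 1])
        classes += [lab] * n
        hla += [""] * n

    x = np.concatenate(xs) if xs else np.empty(0)
    y = np.concatenate(ys) if ys else np.empty(0)
    n_cells = len(x)
    classes = np.array(classes, dtype=object)
    hla = np.array(hla, dtype=object)

    # marker intensities per true class (HLA1 column driven by true HLA status)
    intensities = {m: np.empty(n_cells) for m in MARKERS}
    for lab in ("Tumor", "CD3", "CD20", "CD8PD1", "CD4FOXP3"):
        sel = classes == lab
        if not sel.any():
            continue
        draw = _intensities(rng, int(sel.sum()), CLASS_MARKERS[lab], cfg)
        for m in MARKERS:
            intensities[m][sel] = draw[m]
    tumor_sel = classes == "Tumor"
    if tumor_sel.any():
        pos_sel = tumor_sel & (hla == "HLA1pos")
        neg_sel = tumor_sel & (hla == "HLA1neg")
        intensities["HLA1"][pos_sel] = rng.lognormal(np.log(cfg.intensity_pos), cfg.intensity_sigma, int(pos_sel.sum()))
        intensities["HLA1"][neg_sel] = rng.lognormal(np.log(cfg.intensity_bg), cfg.intensity_sigma, int(neg_sel.sum()))

    # QC metrics: passing by default, a planted fraction failing one rule each
    qc_align = rng.uniform(0.90, 1.0, size=n_cells)
    nuc_px = rng.integers(30, 200, size=n_cells)
    mem_px = rng.integers(30, 200, size=n_cells)
    cyt_px = rng.integers(30, 200, size=n_cells)
    n_nuclei = rng.integers(1, 3, size=n_cells)  # 1 or 2
    qc_fail = rng.uniform(size=n_cells) < cfg.qc_fail_fraction
    which = rng.integers(0, 3, size=n_cells)
    qc_align[qc_fail & (which == 0)] = rng.uniform(0.0, 0.84, size=int((qc_fail & (which == 0)).sum()))
    nuc_px[qc_fail & (which == 1)] = rng.integers(0, 10, size=int((qc_fail & (which == 1)).sum()))
    n_nuclei[qc_fail & (which == 2)] = rng.integers(3, 6, size=int((qc_fail & (which == 2)).sum()))

    cell_ids = [f"{cfg.fov_id}_c{i:05d}" for i in range(n_cells)]
    data = pd.DataFrame({
        "cell_id": cell_ids,
        "fov_id": cfg.fov_id,
        "sample_id": cfg.sample_id,
        "x": x,
        "y": y,
        "qc_alignment": qc_align,
        "nucleus_pixels": nuc_px,
        "membrane_pixels": mem_px,
        "cytoplasm_pixels": cyt_px,
        "n_nuclei": n_nuclei,
        **{m: intensities[m] for m in MARKERS},
    })
    table = CellTable(data=data, unit="um", markers=MARKERS, meta={"synthetic_config": asdict(cfg)})
    table.validate()
    truth = GroundTruth(
        config=cfg,
        clusters=clusters,
        true_class=pd.Series(classes, index=cell_ids),
        true_hla=pd.Series(hla, index=cell_ids),
        qc_fail=pd.Series(qc_fail, index=cell_ids),
    )
    return table, truth


@dataclass
class SyntheticCohort:
    """Multi-sample synthetic dataset with per-FOV ground truths."""

    cells: CellTable
    truths: dict  # (sample_id, fov_id) -> GroundTruth
    group: dict  # sample_id -> "brisk" | "nonbrisk"


def brisk_config(**overrides) -> SyntheticConfig:
    """Template for a densely T-cell-infiltrated ('brisk TIL') sample:
    strong attraction and a high CD3 count, so CD3 aggregates overlap the
    tumor nests."""
    base = dict(attraction=6.0, n_immune={"CD3": 400, "CD20": 80, "CD8PD1": 120, "CD4FOXP3": 60})
    base.update(overrides)
    return SyntheticConfig(**base)


def nonbrisk_config(**overrides) -> SyntheticConfig:
    """Template for a sparsely infiltrated ('non-brisk TIL') sample: weak
    attraction and few CD3 cells, so CD3 rarely aggregates inside tumor."""
    base = dict(attraction=0.5, n_immune={"CD3": 80, "CD20": 120, "CD8PD1": 30, "CD4FOXP3": 100})
    base.update(overrides)
    return SyntheticConfig(**base)


def generate_cohort(
    brisk_configs: Sequence[SyntheticConfig],
    nonbrisk_configs: Sequence[SyntheticConfig],
    fovs_per_sample: int = 5,
    seed: int = 0,
) -> SyntheticCohort:
    """Generate a multi-sample cohort from per-sample config templates.

    Each template spawns ``fovs_per_sample`` FOVs with independent child
    seeds (derived from ``seed`` via a SeedSequence, so the cohort is fully
    reproducible).  Sample ids are ``B1..`` for brisk and ``N1..`` for
    non-brisk templates.
    """
    ss = np.random.SeedSequence(seed)
    tables, truths, group = [], {}, {}
    jobs = [("B", i, c, "brisk") for i, c in enumerate(brisk_configs, 1)]
    jobs += [("N", i, c, "nonbrisk") for i, c in enumerate(nonbrisk_configs, 1)]
    children = ss.spawn(len(jobs) * fovs_per_sample)
    k = 0
    for prefix, i, template, label in jobs:
        sample_id = f"{prefix}{i}"
        group[sample_id] = label
        for f in range(1, fovs_per_sample + 1):
            child_seed = int(children[k].generate_state(1)[0] % (2 ** 31))
            k += 1
            cfg = replace(template, seed=child_seed, sample_id=sample_id, fov_id=f"{sample_id}_FOV{f:02d}")
            t, g = generate_fov(cfg)
            tables.append(t)
            truths[(sample_id, cfg.fov_id)] = g
    return SyntheticCohort(cells=combine(tables), truths=truths, group=group)
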