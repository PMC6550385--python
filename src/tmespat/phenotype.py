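"""Rule-based cell phenotyping and HLA-1 status calling.

Cells are assigned at most one phenotype label from a list of marker
threshold rules (tumor via the S100 tumor-mask marker; T cells via CD3;
B cells via CD20; CD8+PD1+ cytotoxic T cells; CD4+FOXP3+ regulatory
T cells).  CD3 and CD20 are biologically mutually exclusive, so cells
positive for both are labelled ``"ambiguous"`` and excluded from downstream
counts; cells matching no rule are ``"unclassified"``.

Tumor-cell HLA-1 status is called against an internal control: CD3+ cells
ubiquitously express HLA-1, so the positivity threshold is a fraction
(default 10%) of a pooled statistic (default median) of the HLA-1 intensity
of CD3+ cells.  A tumor cell strictly above the threshold is ``HLA1pos``,
otherwise ``HLA1neg``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError
from .io import CellTable

__all__ = [
    "MarkerThreshold",
    "PhenotypeRule",
    "HLACallConfig",
    "default_rules",
    "assign_phenotypes",
    "call_hla1_status",
    "AMBIGUOUS",
    "UNCLASSIFIED",
]

AMBIGUOUS = "ambiguous"
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class MarkerThreshold:
    """A positivity criterion: intensity of ``marker`` strictly above
    ``threshold`` (in the optional subcellular ``compartment``, whose
    intensity column is ``{marker}_{compartment}``)."""

    marker: str
    threshold: float
    compartment: str | None = None

    def __post_init__(self):
        if self.threshold < 0:
            raise ConfigError(f"negative threshold for marker {self.marker!r}")

    @property
    def column(self) -> str:
        return f"{self.marker}_{self.compartment}" if self.compartment else self.marker


@dataclass(frozen=True)
class PhenotypeRule:
    """One phenotype: all ``required`` markers positive and no ``excluded``
    marker positive.  Lower ``priority`` wins when several rules match
    (e.g. CD8+PD1+ takes precedence over plain CD3); ties between distinct
    matching labels are labelled ambiguous."""

    label: str
    required: tuple[MarkerThreshold, ...]
    excluded: tuple[MarkerThreshold, ...] = ()
    priority: int = 0

    def __post_init__(self):
        req = {m.marker for m in self.required}
        exc = {m.marker for m in self.excluded}
        if req & exc:
            raise ConfigError(f"rule {self.label!r}: required and excluded markers overlap: {sorted(req & exc)}")


def default_rules(threshold: float = 30.0, tumor_marker: str = "S100") -> list[PhenotypeRule]:
    """Default rule set for the melanoma marker panel.

    A single intensity threshold is used for every marker; pass explicit
    :class:`PhenotypeRule` objects for per-marker thresholds.
    """
    t = threshold
    mt = MarkerThreshold
    return [
        PhenotypeRule("Tumor", (mt(tumor_marker, t),), priority=0),
        PhenotypeRule("CD8PD1", (mt("CD8", t), mt("PD1", t)), priority=1),
        PhenotypeRule("CD4FOXP3", (mt("CD4", t), mt("FOXP3", t)), priority=1),
        PhenotypeRule("CD3", (mt("CD3", t),), excluded=(mt("CD20", t),), priority=2),
        PhenotypeRule("CD20", (mt("CD20", t),), excluded=(mt("CD3", t),), priority=2),
    ]


def _positive(table: CellTable, mt: MarkerThreshold) -> np.ndarray:
    col = mt.column
    if col not in table.data.columns:
        raise ConfigError(f"rule references unknown marker column {col!r}")
    return table.data[col].to_numpy(dtype=float) > mt.threshold


def assign_phenotypes(
    table: CellTable,
    rules: Sequence[PhenotypeRule] | None = None,
    tumor_mask_marker: str | None = "S100",
) -> CellTable:
    """Assign one phenotype label per cell into a ``phenotype`` column.

    Resolution per cell:

    1. a rule *matches* when all required markers are strictly above their
       thresholds;
    2. no matching rule → ``"unclassified"``;
    3. a matching rule with a violated exclusion (e.g. a CD3+CD20+ double
       positive under the CD3 rule) → ``"ambiguous"``;
    4. otherwise the matching rule of lowest priority number wins; distinct
       labels tied on priority → ``"ambiguous"``.

    ``tumor_mask_marker`` declares the marker that drives the tumor label
    (the tumor segmentation mask stain); a rule using it must exist.
    """
    if rules is None:
        rules = default_rules(tumor_marker=tumor_mask_marker or "S100")
    if tumor_mask_marker is not None:
        used = {mt.marker for r in rules for mt in r.required}
        if tumor_mask_marker not in used:
            raise ConfigError(f"no rule uses tumor mask marker {tumor_mask_marker!r}")

    n = len(table)
    matched = np.zeros((len(rules), n), dtype=bool)
    conflicted = np.zeros((len(rules), n), dtype=bool)
    for i, rule in enumerate(rules):
        m = np.ones(n, dtype=bool)
        for mt in rule.required:
            m &= _positive(table, mt)
        matched[i] = m
        c = np.zeros(n, dtype=bool)
        for mt in rule.excluded:
            c |= _positive(table, mt)
        conflicted[i] = m & c

    labels = np.full(n, UNCLASSIFIED, dtype=object)
    priorities = np.array([r.priority for r in rules])
    any_match = matched.any(axis=0)
    ambiguous = conflicted.any(axis=0)

    # best (lowest) priority among matching rules; tie between distinct labels → ambiguous
    big = priorities.max() + 1
    prio_matrix = np.where(matched, priorities[:, None], big)
    best = prio_matrix.min(axis=0)
    for j in np.where(any_match & ~ambiguous)[0]:
        winners = {rules[i].label for i in np.where(prio_matrix[:, j] == best[j])[0]}
        labels[j] = winners.pop() if len(winners) == 1 else AMBIGUOUS
    labels[ambiguous] = AMBIGUOUS

    data = table.data.copy()
    data["phenotype"] = labels
    out = CellTable(data, table.unit, table.markers, dict(table.meta))
    out.meta["phenotype_rules"] = [r.label for r in rules]
    return out


@dataclass(frozen=True)
class HLACallConfig:
    """How the tumor HLA-1 positivity threshold is derived from CD3+ cells.

    ``method="fraction_of_stat"`` (default): threshold = ``fraction`` ×
    ``pooling_statistic`` (median or mean) of the HLA-1 intensity of control
    cells.  ``method="percentile"``: threshold = the ``100×fraction``-th
    percentile of the control intensities (alternative reading of "10% of
    the CD3+ HLA-1 intensity").  ``pooling_scope`` pools controls over the
    whole table (``"all_ROIs"``) or separately per FOV (``"per_FOV"``).
    """

    fraction: float = 0.10
    pooling_statistic: str = "median"  # "median" | "mean"
    pooling_scope: str = "all_ROIs"  # "all_ROIs" | "per_FOV"
    method: str = "fraction_of_stat"  # "fraction_of_stat" | "percentile"
    hla_marker: str = "HLA1"
    control_labels: tuple[str, ...] = ("CD3",)
    tumor_label: str = "Tumor"

    def __post_init__(self):
        if not (0 < self.fraction <= 1):
            raise ConfigError("fraction must be in (0, 1]")
        if self.pooling_statistic not in ("median", "mean"):
            raise ConfigError("pooling_statistic must be 'median' or 'mean'")
        if self.pooling_scope not in ("all_ROIs", "per_FOV"):
            raise ConfigError("pooling_scope must be 'all_ROIs' or 'per_FOV'")
        if self.method not in ("fraction_of_stat", "percentile"):
            raise ConfigError("method must be 'fraction_of_stat' or 'percentile'")


def _threshold(intensities: np.ndarray, cfg: HLACallConfig) -> float:
    if cfg.method == "percentile":
        return float(np.percentile(intensities, 100 * cfg.fraction))
    stat = np.median(intensities) if cfg.pooling_statistic == "median" else np.mean(intensities)
    return float(cfg.fraction * stat)


def call_hla1_status(table: CellTable, cfg: HLACallConfig | None = None) -> CellTable:
    """Label tumor cells ``HLA1pos``/``HLA1neg`` in an ``hla1_status`` column.

    The threshold is derived from CD3+ cells (internal control) per
    :class:`HLACallConfig`; tumor cells with HLA-1 intensity *strictly*
    greater than the threshold are positive.  The threshold(s) used are
    recorded in ``table.meta["hla1_threshold"]``.

    Raises
    ------
    DataError
        If no control (CD3+) cell exists within a pooling scope
        ("internal control unavailable").
    """
    if cfg is None:
        cfg = HLACallConfig()
    if "phenotype" not in table.data.columns:
        raise DataError("phenotypes must be assigned before HLA-1 calling")
    if cfg.hla_marker not in table.data.columns:
        raise ConfigError(f"unknown HLA marker column {cfg.hla_marker!r}")

    pheno = table.data["phenotype"]
    hla = table.data[cfg.hla_marker].to_numpy(dtype=float)
    is_control = pheno.isin(cfg.control_labels).to_numpy()
    is_tumor = (pheno == cfg.tumor_label).to_numpy()

    status = np.full(len(table), "", dtype=object)
    thresholds: dict = {}
    if cfg.pooling_scope == "all_ROIs":
        if not is_control.any():
            raise DataError("internal control unavailable: no CD3+ cells in scope")
        T = _threshold(hla[is_control], cfg)
        thresholds["all_ROIs"] = T
        status[is_tumor] = np.where(hla[is_tumor] > T, "HLA1pos", "HLA1neg")
    else:
        for fov in table.fov_ids:
            in_fov = (table.data["fov_id"] == fov).to_numpy()
            ctrl = is_control & in_fov
            if not ctrl.any():
                raise DataError(f"internal control unavailable: no CD3+ cells in FOV {fov!r}")
            T = _threshold(hla[ctrl], cfg)
            thresholds[fov] = T
            sel = is_tumor & in_fov
            status[sel] = np.where(hla[sel] > T, "HLA1pos", "HLA1neg")

    data = table.data.copy()
    data["hla1_status"] = status
    out = CellTable(data, table.unit, table.markers, dict(table.meta))
    out.meta["hla1_threshold"] = thresholds
    return out


def class_mask(table: CellTable, label: str) -> np.ndarray:
    """Boolean mask for a cell class.

    ``label`` is a phenotype label, or one of the derived classes
    ``"HLA1pos"`` / ``"HLA1neg"`` (tumor cells of that HLA-1 status).
    """
    if "phenotype" not in table.data.columns:
        raise DataError("phenotypes not assigned")
    pheno = table.data["phenotype"]
    if label in ("HLA1pos", "HLA1neg"):
        if "hla1_status" not in table.data.columns:
            raise DataError("HLA-1 status not called")
        return ((pheno == "Tumor") & (table.data["hla1_status"] == label)).to_numpy()
    return (pheno == label).to_numpy()
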