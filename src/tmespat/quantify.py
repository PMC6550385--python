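"""Per-FOV ratio metrics, correlograms, dispersion, and group comparisons.

The quantification layer reduces a phenotyped cell table to per-FOV ratio
metrics (HLA-1+ tumor / all tumor, CD3 / tumor, CD8+PD1+ / tumor, CD20 and
CD4+FOXP3+ / all immune, ...), optionally restricted to a region such as an
infiltration area; computes the pairwise Pearson correlation structure of
those ratios across the FOVs of a sample (with significance and
insufficient-data flags); and provides the comparison statistics used at
cohort level: coefficient of variation, the Cochran–Mantel–Haenszel test on
stratified 2×2 tables, and Welch's unequal-variance t test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, DataError
from .io import CellTable
from .phenotype import AMBIGUOUS, UNCLASSIFIED, class_mask

__all__ = [
    "DEFAULT_RATIOS",
    "IMMUNE_CLASSES",
    "fov_ratios",
    "CorrelogramResult",
    "correlogram",
    "coefficient_of_variation",
    "CMHResult",
    "cmh_test",
    "WelchResult",
    "welch_compare",
    "export_heatmap",
]

#: immune phenotype labels; "immune" as a denominator means their union
IMMUNE_CLASSES = ("CD3", "CD20", "CD8PD1", "CD4FOXP3")

#: ratio name -> (numerator class, denominator class); "immune" = all immune
DEFAULT_RATIOS: dict[str, tuple[str, str]] = {
    "hla1pos_tumor_over_tumor": ("HLA1pos", "Tumor"),
    "cd3_over_tumor": ("CD3", "Tumor"),
    "cd8pd1_over_tumor": ("CD8PD1", "Tumor"),
    "cd20_over_immune": ("CD20", "immune"),
    "cd4foxp3_over_immune": ("CD4FOXP3", "immune"),
}


def _count(table: CellTable, label: str) -> int:
    if label == "immune":
        return int(sum(class_mask(table, lab).sum() for lab in IMMUNE_CLASSES))
    return int(class_mask(table, label).sum())


def fov_ratios(
    cells: CellTable,
    region=None,
    ratios: Mapping[str, tuple[str, str]] | None = None,
) -> pd.DataFrame:
    """Per-FOV cell-count ratios.

    Parameters
    ----------
    cells
        Phenotyped (and, for HLA ratios, HLA-called) cell table.
    region
        Optional polygon (or mapping ``fov_id -> polygon``) restricting the
        counts to cells inside it — used for infiltration-area ratios.
    ratios
        ``name -> (numerator class, denominator class)``; the special
        denominator ``"immune"`` sums all immune classes.  Defaults to
        :data:`DEFAULT_RATIOS`.

    Returns a frame indexed by ``fov_id`` with one column per ratio plus
    ``n_<class>`` count columns.  Ratios with a zero denominator are NaN
    (missing), never infinite.  Ambiguous and unclassified cells never enter
    any count.
    """
    from .caa import cells_in_region

    if ratios is None:
        ratios = DEFAULT_RATIOS
    classes: set[str] = set()
    for name, (num, den) in ratios.items():
        classes.add(num)
        classes.update(IMMUNE_CLASSES if den == "immune" else (den,))
        for lab in (num, den):
            if lab in (AMBIGUOUS, UNCLASSIFIED):
                raise ConfigError(f"ratio {name!r} uses excluded class {lab!r}")

    rows = []
    for fov in cells.fov_ids:
        sub = cells.for_fov(fov)
        if region is not None:
            poly = region.get(fov) if isinstance(region, Mapping) else region
            if poly is not None:
                sub = cells_in_region(sub, poly)
        counts = {lab: _count(sub, lab) for lab in classes}
        counts["immune"] = sum(counts.get(lab, _count(sub, lab)) for lab in IMMUNE_CLASSES)
        row: dict = {"fov_id": fov}
        for lab in sorted(classes | {"immune"}):
            row[f"n_{lab}"] = counts[lab]
        for name, (num, den) in ratios.items():
            row[name] = counts[num] / counts[den] if counts[den] > 0 else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("fov_id")


@dataclass
class CorrelogramResult:
    """Pairwise Pearson structure of ratio columns across FOVs.

    ``flag`` is one of ``significant``, ``not_significant`` (p above alpha —
    drawn crossed-out in the field's correlogram figures) or
    ``insufficient_data`` (fewer complete FOVs than ``min_n`` — drawn as a
    question mark).  Flags are exhaustive and mutually exclusive.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    flag: pd.DataFrame
    alpha: float
    min_n: int

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per unordered column pair."""
        cols = list(self.r.columns)
        rows = []
        for i, a in enumerate(cols):
            for b in cols[i:]:
                rows.append({
                    "metric_a": a, "metric_b": b,
                    "r": self.r.loc[a, b], "p": self.p.loc[a, b],
                    "n": self.n.loc[a, b], "flag": self.flag.loc[a, b],
                })
        return pd.DataFrame(rows)


def correlogram(ratios: pd.DataFrame, alpha: float = 0.05, min_n: int = 3) -> CorrelogramResult:
    """Pairwise Pearson r (complete-case) over the ratio columns of a
    per-FOV ratio table, with two-sided p-values and per-pair flags."""
    metric_cols = [c for c in ratios.columns if not c.startswith("n_")]
    if len(metric_cols) < 2:
        raise DataError("need at least 2 ratio columns")
    k = len(metric_cols)
    r = np.full((k, k), np.nan)
    p = np.full((k, k), np.nan)
    n = np.zeros((k, k), dtype=int)
    flag = np.full((k, k), "insufficient_data", dtype=object)
    for i in range(k):
        for j in range(i, k):
            pair = ratios[[metric_cols[i], metric_cols[j]]].dropna() if i != j else ratios[[metric_cols[i]]].dropna()
            n[i, j] = n[j, i] = len(pair)
            if len(pair) < max(min_n, 2):
                continue
            if i == j:
                r[i, i], p[i, i] = 1.0, 0.0
                flag[i, i] = "significant"
                continue
            a = pair.iloc[:, 0].to_numpy()
            b = pair.iloc[:, 1].to_numpy()
            if np.std(a) == 0 or np.std(b) == 0:
                continue  # constant column: correlation undefined
            res = stats.pearsonr(a, b)
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.pvalue
            f = "significant" if res.pvalue <= alpha else "not_significant"
            flag[i, j] = flag[j, i] = f
    idx = pd.Index(metric_cols)
    return CorrelogramResult(
        r=pd.DataFrame(r, idx, idx), p=pd.DataFrame(p, idx, idx),
        n=pd.DataFrame(n, idx, idx), flag=pd.DataFrame(flag, idx, idx),
        alpha=alpha, min_n=min_n,
    )


def coefficient_of_variation(values) -> float:
    """Sample CV: standard deviation (n−1 denominator) over the mean.
    NaN when fewer than 2 non-missing values or the mean is 0."""
    v = pd.Series(values).dropna().to_numpy(dtype=float)
    if v.size < 2:
        return float("nan")
    m = v.mean()
    if m == 0:
        return float("nan")
    return float(v.std(ddof=1) / m)


@dataclass
class CMHResult:
    statistic: float
    pvalue: float
    n_strata: int
    n_dropped: int


def cmh_test(outcome, group, stratum, correction: bool = False) -> CMHResult:
    """Cochran–Mantel–Haenszel chi-square test over stratified 2×2 tables.

    Parameters are per-unit vectors: a binary ``outcome``, a binary
    ``group`` label, and a ``stratum`` label.  Strata where one group is
    entirely absent carry no information and are dropped with a warning.
    Continuity correction is off by default.  With a single stratum the
    statistic reduces to the unstratified score chi-square.
    """
    from statsmodels.stats.contingency_tables import StratifiedTable

    df = pd.DataFrame({"outcome": outcome, "group": group, "stratum": stratum}).dropna()
    if df["outcome"].nunique() > 2 or df["group"].nunique() > 2:
        raise DataError("outcome and group must be binary")
    out_levels = sorted(df["outcome"].unique())
    grp_levels = sorted(df["group"].unique())
    if len(grp_levels) < 2:
        raise DataError("need both groups represented overall")

    tables = []
    dropped = 0
    for _, sub in df.groupby("stratum"):
        tab = np.zeros((2, 2))
        for gi, g in enumerate(grp_levels):
            for oi, o in enumerate(out_levels):
                tab[gi, oi] = ((sub["group"] == g) & (sub["outcome"] == o)).sum()
        if tab.sum(axis=1).min() == 0:  # a group missing from this stratum
            dropped += 1
            continue
        tables.append(tab)
    if dropped:
        warnings.warn(f"dropped {dropped} degenerate strata (a group absent)", stacklevel=2)
    if not tables:
        raise DataError("no informative strata")
    st = StratifiedTable(np.stack(tables, axis=-1))
    res = st.test_null_odds(correction=correction)
    return CMHResult(float(res.statistic), float(res.pvalue), len(tables), dropped)


@dataclass
class WelchResult:
    statistic: float
    df: float
    pvalue: float


def welch_compare(a, b) -> WelchResult:
    """Welch's unequal-variance t test (two-sided, Satterthwaite df).

    Both groups need n ≥ 2.  The degenerate case of zero variance in both
    groups is handled by convention: equal means → t = 0, p = 1; different
    means → infinite t, p = 0.
    """
    a = pd.Series(a).dropna().to_numpy(dtype=float)
    b = pd.Series(b).dropna().to_numpy(dtype=float)
    if a.size < 2 or b.size < 2:
        raise DataError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(a.size + b.size - 2), 1.0)
        return WelchResult(float("inf") if a.mean() > b.mean() else float("-inf"), float(a.size + b.size - 2), 0.0)
    res = stats.ttest_ind(a, b, equal_var=False)
    return WelchResult(float(res.statistic), float(res.df), float(res.pvalue))


def export_heatmap(ratios: pd.DataFrame, out_csv, out_png=None) -> tuple[Path, Path | None]:
    """Write the per-FOV metric matrix as CSV and render it as a heat map.

    Missing values are rendered in a distinct hatch color, never as zero.
    Returns the paths written.  Purely presentational; the CSV round-trips
    to the ratio values exactly (to float precision)."""
    out_csv = Path(out_csv)
    metric_cols = [c for c in ratios.columns if not c.startswith("n_")]
    mat = ratios[metric_cols]
    mat.to_csv(out_csv)

    png = None
    if out_png is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(2 + 0.6 * len(metric_cols), 1 + 0.3 * len(mat)))
        cmap = plt.get_cmap("viridis").copy()
        cmap.set_bad(color="lightgray")
        im = ax.imshow(np.ma.masked_invalid(mat.to_numpy(dtype=float)), aspect="auto", cmap=cmap)
        ax.set_xticks(range(len(metric_cols)), metric_cols, rotation=45, ha="right", fontsize=7)
        ax.set_yticks(range(len(mat)), [str(i) for i in mat.index], fontsize=7)
        fig.colorbar(im, ax=ax, label="ratio")
        fig.tight_layout()
        png = Path(out_png)
        fig.savefig(png, dpi=120)
        plt.close(fig)
    return out_csv, png
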