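"""ROI summaries, two-group comparisons and reliability measures.

Subject-level ROI means are the unit of analysis: for every structure
and every map component (short/long T2, short/long fraction) the two
clinical groups are compared with a pooled-variance two-sample
Student's t-test, Bonferroni-corrected across the four components per
structure (family alpha 0.05 / 4 = 0.0125, with 0.0125 <= p < 0.05
flagged as a trend).  Normality is checked per group with the
Shapiro-Wilk test.  Rater reliability uses intersection-over-union for
repeated segmentations and Cohen's kappa for categorical ratings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.metrics import cohen_kappa_score

__all__ = [
    "COMPONENTS",
    "ROISummary",
    "GroupComparison",
    "roi_summary",
    "average_segmentations",
    "pooled_t_test",
    "bonferroni_alpha",
    "shapiro_wilk",
    "pearson_r",
    "cohens_kappa",
    "intersection_over_union",
    "group_analysis",
]

#: The four map components summarised per structure.
COMPONENTS = ("t2_short", "t2_long", "frac_short", "frac_long")

SIGNIFICANCE_ALPHA = 0.0125  # 0.05 / 4 components
TREND_ALPHA = 0.05


@dataclass
class ROISummary:
    structure: str
    component: str
    mean: float
    sd: float
    n_valid_voxels: int
    empty: bool = False


@dataclass
class GroupComparison:
    structure: str
    component: str
    mean_a: float
    sd_a: float
    n_a: int
    mean_b: float
    sd_b: float
    n_b: int
    t: float
    df: int
    p: float
    significant: bool
    trend: bool
    normality_p_a: float | None = None
    normality_p_b: float | None = None


def roi_summary(map_grid, label_mask, validity, label: int,
                structure: str = "", component: str = "") -> ROISummary:
    """Mean and sample SD of a map over the valid voxels of one ROI.

    Voxels demoted to monoexponential/degenerate (validity False) are
    excluded; they change the voxel count but never contaminate the
    mean.  An empty valid intersection is flagged, not an error.
    """
    grid = np.asarray(map_grid, dtype=float)
    labels = np.asarray(label_mask)
    valid = np.asarray(validity, dtype=bool)
    sel = (labels == label) & valid
    n = int(sel.sum())
    if n == 0:
        return ROISummary(structure, component, np.nan, np.nan, 0, empty=True)
    vals = grid[sel]
    sd = float(vals.std(ddof=1)) if n > 1 else 0.0
    return ROISummary(structure, component, float(vals.mean()), sd, n)


def average_segmentations(mask_a, mask_b, map_grid, validity, label: int = 1,
                          structure: str = "", component: str = "") -> ROISummary:
    """Combine two repeated segmentations of the same structure.

    The ROI summary is computed separately under each mask and the two
    means (and SDs) are averaged — each tracing is one measurement and
    the average of the two measurements enters further analysis.  If
    one tracing has no valid voxels the other is used alone.
    """
    a = roi_summary(map_grid, mask_a, validity, label, structure, component)
    b = roi_summary(map_grid, mask_b, validity, label, structure, component)
    if a.empty and b.empty:
        return a
    if a.empty or b.empty:
        warnings.warn("one segmentation has no valid voxels; "
                      "falling back to the other", stacklevel=2)
        return b if a.empty else a
    return ROISummary(structure, component,
                      0.5 * (a.mean + b.mean), 0.5 * (a.sd + b.sd),
                      a.n_valid_voxels + b.n_valid_voxels)


def pooled_t_test(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                  *, welch: bool = False) -> tuple[float, float, float]:
    """Two-sample t-test from summary statistics: (t, df, two-sided p).

    Classical pooled-variance Student's t by default (df = n_a+n_b-2);
    Welch's unequal-variance form behind the ``welch`` flag.  Zero
    pooled variance degenerates to p=1 for equal means and p=0
    otherwise (limit convention).
    """
    if n_a < 2 or n_b < 2:
        raise ValueError("each group needs n >= 2")
    if sd_a < 0 or sd_b < 0:
        raise ValueError("standard deviations must be non-negative")
    if sd_a == 0 and sd_b == 0:
        df = n_a + n_b - 2
        if mean_a == mean_b:
            return 0.0, float(df), 1.0
        return float(np.inf) * np.sign(mean_a - mean_b), float(df), 0.0
    t, p = sps.ttest_ind_from_stats(mean_a, sd_a, n_a, mean_b, sd_b, n_b,
                                    equal_var=not welch)
    if welch:
        va, vb = sd_a**2 / n_a, sd_b**2 / n_b
        df = (va + vb) ** 2 / (va**2 / (n_a - 1) + vb**2 / (n_b - 1))
    else:
        df = n_a + n_b - 2
    return float(t), float(df), float(p)


def bonferroni_alpha(family_alpha: float, m_comparisons: int) -> float:
    """Per-comparison threshold: family alpha over the number of tests."""
    if not 0 < family_alpha <= 1:
        raise ValueError("family_alpha must lie in (0, 1]")
    if m_comparisons < 1:
        raise ValueError("m_comparisons must be >= 1")
    return family_alpha / m_comparisons


def shapiro_wilk(sample) -> tuple[float, float]:
    """Shapiro-Wilk normality test: (W, p).  Needs 3 <= n <= 5000."""
    x = np.asarray(sample, dtype=float)
    if not 3 <= x.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample: W is undefined")
    res = sps.shapiro(x)
    return float(res.statistic), float(res.pvalue)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation: (r, two-sided p)."""
    r = sps.pearsonr(np.asarray(x, float), np.asarray(y, float))
    return float(r.statistic), float(r.pvalue)


def cohens_kappa(ratings1, ratings2) -> float:
    """Cohen's chance-corrected agreement between two categorical raters."""
    r1, r2 = np.asarray(ratings1), np.asarray(ratings2)
    if r1.shape != r2.shape or r1.ndim != 1 or r1.size == 0:
        raise ValueError("ratings must be two equal-length 1-D vectors")
    if np.array_equal(r1, r2):
        return 1.0  # kappa's 0/0 limit under perfect single-class agreement
    return float(cohen_kappa_score(r1, r2))


def intersection_over_union(mask_a, mask_b) -> float:
    """|A intersect B| / |A union B| for two boolean masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a shape")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise ValueError("both masks are empty: IoU undefined")
    return float(np.logical_and(a, b).sum() / union)


def group_analysis(cohort: pd.DataFrame, *, family_alpha: float = 0.05,
                   m_comparisons: int = 4, welch: bool = False,
                   group_col: str = "group",
                   groups: tuple[str, str] = ("displacement",
                                              "no_displacement"),
                   ) -> pd.DataFrame:
    """Structure-by-component two-group comparison table.

    ``cohort`` is tidy: one row per subject x structure with one column
    per component (see :data:`COMPONENTS`; absent components are
    skipped).  Returns one row per structure x component with group
    means/SDs/ns, t, df, p, the Bonferroni significance flag
    (p < family_alpha/m) and the trend flag (threshold <= p < 0.05),
    plus per-group Shapiro-Wilk normality p-values.
    """
    required = {"structure", group_col}
    if missing := required - set(cohort.columns):
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    threshold = bonferroni_alpha(family_alpha, m_comparisons)
    ga, gb = groups
    rows = []
    for structure, sub in cohort.groupby("structure", sort=False):
        for comp in COMPONENTS:
            if comp not in sub.columns:
                continue
            xa = sub.loc[sub[group_col] == ga, comp].dropna().to_numpy()
            xb = sub.loc[sub[group_col] == gb, comp].dropna().to_numpy()
            if xa.size < 2 or xb.size < 2:
                raise ValueError(
                    f"{structure}/{comp}: each group needs n >= 2")
            t, df, p = pooled_t_test(xa.mean(), xa.std(ddof=1), xa.size,
                                     xb.mean(), xb.std(ddof=1), xb.size,
                                     welch=welch)
            norm_a = norm_b = np.nan
            if xa.size >= 3 and np.ptp(xa) > 0:
                norm_a = shapiro_wilk(xa)[1]
            if xb.size >= 3 and np.ptp(xb) > 0:
                norm_b = shapiro_wilk(xb)[1]
            rows.append({
                "structure": structure,
                "component": comp,
                f"mean_{ga}": xa.mean(),
                f"sd_{ga}": xa.std(ddof=1),
                f"n_{ga}": xa.size,
                f"mean_{gb}": xb.mean(),
                f"sd_{gb}": xb.std(ddof=1),
                f"n_{gb}": xb.size,
                "t": t,
                "df": df,
                "p": p,
                "significant": p < threshold,
                "trend": threshold <= p < TREND_ALPHA,
                f"normality_p_{ga}": norm_a,
                f"normality_p_{gb}": norm_b,
            })
    return pd.DataFrame(rows)
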