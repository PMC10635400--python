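"""Patient-level aggregation of packing scaling D and cohort statistics.

Patients are the unit of analysis: cell-level D values are averaged per
patient (with a >30-cell floor), groups are compared by Welch's t-test with
a pooled-sd Cohen's d, covariates are screened by ordinary least squares,
and group mean D is regressed on modeled 5-year risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests

from .exceptions import CollinearityError, InsufficientDataError

__all__ = [
    "GroupComparison", "RiskRegression",
    "aggregate_patients", "compare_groups", "compare_groups_table",
    "covariate_regression", "regress_d_vs_risk", "lesion_size_report",
]

MIN_CELLS_DEFAULT = 31


@dataclass
class GroupComparison:
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    effect_size: float   # Cohen's d, positive when group_b mean exceeds a
    p_value: float
    test_name: str


@dataclass
class RiskRegression:
    slope: float
    intercept: float
    r_squared: float
    n: int


def aggregate_patients(cell_table: pd.DataFrame, min_cells: int = MIN_CELLS_DEFAULT,
                       patient_table: pd.DataFrame | None = None,
                       include_undersampled: bool = False) -> pd.DataFrame:
    """Per-patient mean D and cell count from a long cell table.

    ``cell_table`` needs columns ``patient_id`` and ``d``.  Patients with
    fewer than ``min_cells`` cells are flagged ``under_sampled`` and dropped
    unless ``include_undersampled``.  Optional per-patient metadata (group,
    label, demographics) is merged on ``patient_id``.
    """
    if len(cell_table) == 0:
        raise InsufficientDataError("empty cell table")
    agg = (cell_table.groupby("patient_id", sort=True)["d"]
           .agg(mean_d="mean", n_cells="count").reset_index())
    agg["under_sampled"] = agg["n_cells"] < min_cells
    if not include_undersampled:
        agg = agg[~agg["under_sampled"]].reset_index(drop=True)
    if patient_table is not None:
        agg = agg.merge(patient_table, on="patient_id", how="left")
    return agg


def _cohens_d(a: np.ndarray, b: np.ndarray, sd_floor: float,
              max_abs: float) -> float:
    na, nb = len(a), len(b)
    pooled_var = (((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                  / (na + nb - 2))
    diff = b.mean() - a.mean()
    if pooled_var <= sd_floor ** 2:
        if diff == 0.0:
            return 0.0
        return float(np.sign(diff) * max_abs)
    d = diff / np.sqrt(pooled_var)
    return float(np.clip(d, -max_abs, max_abs))


def compare_groups(patients: pd.DataFrame, group_a: str, group_b: str,
                   group_col: str = "group", value_col: str = "mean_d",
                   test: str = "welch", sd_floor: float = 1e-12,
                   max_abs_d: float = 20.0) -> GroupComparison:
    """Two-group comparison on patient means.

    Welch's two-sample t-test by default (Mann-Whitney U by
    ``test='mannwhitney'``) with pooled-sd Cohen's d, positive when
    ``group_b`` exceeds ``group_a``.  Identical degenerate groups return
    d = 0, p = 1; a nonzero mean difference atop (near-)zero pooled sd is
    capped at ``max_abs_d``.
    """
    a = patients.loc[patients[group_col] == group_a, value_col].to_numpy(float)
    b = patients.loc[patients[group_col] == group_b, value_col].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise InsufficientDataError(
            f"both groups need >= 2 patients (got {len(a)}, {len(b)})")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        p = 1.0
    elif test == "welch":
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    elif test == "mannwhitney":
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    if not np.isfinite(p):
        p = 1.0
    d = _cohens_d(a, b, sd_floor, max_abs_d)
    return GroupComparison(group_a=group_a, group_b=group_b,
                           n_a=len(a), n_b=len(b), effect_size=d,
                           p_value=p, test_name=test)


def compare_groups_table(patients: pd.DataFrame, pairs,
                         adjust: str = "none", **kw) -> pd.DataFrame:
    """Run :func:`compare_groups` over group pairs; optional Holm adjustment."""
    rows = [compare_groups(patients, a, b, **kw) for a, b in pairs]
    df = pd.DataFrame([r.__dict__ for r in rows])
    if adjust == "holm":
        df["p_adjusted"] = multipletests(df["p_value"], method="holm")[1]
    elif adjust != "none":
        raise ValueError(f"unknown adjustment {adjust!r}")
    return df


def covariate_regression(patients: pd.DataFrame,
                         formula: str = "mean_d ~ label + age + sex + smoking + drinking"
                         ) -> pd.DataFrame:
    """OLS coefficient table (estimate, standard error, p-value per term).

    Raises :class:`CollinearityError` when the design matrix is rank
    deficient (degenerate or redundant covariates).
    """
    if len(patients) < 10:
        raise InsufficientDataError("need >= 10 patients for regression")
    data = patients.copy()
    for col in ("smoking", "drinking"):
        if col in data and data[col].dtype == bool:
            data[col] = data[col].astype(int)
    model = smf.ols(formula, data=data)
    exog = model.exog
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        names = model.exog_names
        degenerate = [n for i, n in enumerate(names)
                      if n != "Intercept" and np.std(exog[:, i]) == 0]
        raise CollinearityError(degenerate or names)
    fit = model.fit()
    return pd.DataFrame({"coef": fit.params, "stderr": fit.bse,
                         "p_value": fit.pvalues})


def regress_d_vs_risk(group_summaries) -> RiskRegression:
    """Least-squares line of group mean D on modeled 5-year risk.

    ``group_summaries``: iterable of ``(five_year_risk, mean_d)`` pairs or a
    DataFrame with columns ``five_year_risk`` and ``mean_d``.
    """
    if isinstance(group_summaries, pd.DataFrame):
        x = group_summaries["five_year_risk"].to_numpy(float)
        y = group_summaries["mean_d"].to_numpy(float)
    else:
        arr = np.asarray(list(group_summaries), float)
        x, y = arr[:, 0], arr[:, 1]
    if len(x) < 3:
        raise InsufficientDataError("need >= 3 groups for the risk regression")
    res = stats.linregress(x, y)
    return RiskRegression(slope=float(res.slope),
                          intercept=float(res.intercept),
                          r_squared=float(res.rvalue ** 2), n=len(x))


def lesion_size_report(counts: dict,
                       small_categories=("<1 cm", "1-1.5 cm")):
    """Subgroup composition report: per-category percentage (one decimal,
    as printed in screening tables) and the combined percentage of lesions
    in the ``small_categories`` (the under-1.5 cm fraction by default).

    Returns ``(DataFrame[category, n, percent], small_pct)``.
    """
    total = sum(counts.values())
    if total <= 0:
        raise ValueError("counts must sum to a positive total")
    df = pd.DataFrame({
        "category": list(counts.keys()),
        "n": list(counts.values()),
    })
    df["percent"] = (100.0 * df["n"] / total).round(1)
    small = sum(counts.get(c, 0) for c in small_categories)
    small_pct = round(100.0 * small / total, 1)
    return df, small_pct
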