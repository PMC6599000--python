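"""Record screening and the adult-vs-cub inferential tests.

Screening: one record per individual adult (earliest capture kept, to
avoid pseudo-replication; a cub later resampled as an adult stays in both
age groups), and removal of subpopulations with too few adults for
meaningful inference (default n < 20).

Inference: the age contrast controlling for subpopulation, as a two-factor
additive model with Type II sums of squares — multivariately on the
isotope matrix via Pillai's trace with its standard approximate-F
transformation, and univariately per isotope via ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .calibration import ISOTOPES


@dataclass(frozen=True)
class CohortTestResult:
    statistic_name: str  # "pillai_V" or "F"
    value: float
    df1: int
    df2: int
    approx_F: float
    p_value: float

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value outside [0, 1]")


def deduplicate(records: pd.DataFrame) -> pd.DataFrame:
    """Keep at most one adult record per id (earliest year); cubs untouched."""
    adults = records[records["age_class"] == "adult"]
    cubs = records[records["age_class"] != "adult"]
    adults = adults.sort_values(["id", "year"], kind="stable").drop_duplicates("id", keep="first")
    out = pd.concat([adults, cubs]).sort_index(kind="stable")
    return out.reset_index(drop=True)


def filter_small_groups(records: pd.DataFrame, min_n: int = 20) -> pd.DataFrame:
    """Drop subpopulations whose *adult* sample size is below ``min_n``."""
    if min_n < 1:
        raise ValueError("min_n must be >= 1")
    adult_n = records[records["age_class"] == "adult"].groupby("subpopulation").size()
    keep = set(adult_n[adult_n >= min_n].index)
    out = records[records["subpopulation"].isin(keep)].reset_index(drop=True)
    if out.empty:
        raise ValueError(f"all subpopulations below the minimum adult sample size {min_n}")
    return out


def _design_matrices(df: pd.DataFrame):
    """Full and reduced (no age term) design matrices of the additive
    age + subpopulation model, treatment-coded."""
    n = len(df)
    intercept = np.ones((n, 1))
    age = (df["age_class"].to_numpy() == "cub").astype(float)[:, None]
    subpop = pd.get_dummies(df["subpopulation"], drop_first=True).to_numpy(dtype=float)
    x_full = np.hstack([intercept, subpop, age])
    x_red = np.hstack([intercept, subpop])
    return x_full, x_red


def _residual_crossproduct(x, y):
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    r = y - x @ beta
    return r.T @ r


def pillai_approx_f(v: float, p: int, q: int, df_error: int):
    """Standard approximate-F transformation of Pillai's trace for a
    hypothesis of rank q on p responses."""
    s = min(p, q)
    m = 0.5 * (abs(p - q) - 1)
    n2 = 0.5 * (df_error - p - 1)
    df1 = int(round(s * (2 * m + s + 1)))
    df2 = int(round(s * (2 * n2 + s + 1)))
    f = (df2 / df1) * v / (s - v)
    return f, df1, df2


def manova_pillai(records: pd.DataFrame, isotopes=ISOTOPES) -> CohortTestResult:
    """Pillai's trace for the age term controlling for subpopulation.

    Complete cases on the requested isotopes; Type II: the hypothesis
    cross-product H is the drop in residual cross-product when age enters
    the additive model, E the full-model residual cross-product;
    V = tr(H (H + E)^-1).
    """
    isotopes = list(isotopes)
    df = records.dropna(subset=isotopes)
    if df["age_class"].nunique() < 2 or df["subpopulation"].nunique() < 2:
        raise ValueError("need at least two levels of both age class and subpopulation")
    y = df[isotopes].to_numpy(dtype=float)
    x_full, x_red = _design_matrices(df)
    p = y.shape[1]
    df_error = len(df) - x_full.shape[1]
    if df_error <= 0 or len(df) <= x_full.shape[1] + p:
        raise ValueError("too few complete cases for the model")
    e = _residual_crossproduct(x_full, y)
    h = _residual_crossproduct(x_red, y) - e
    try:
        v = float(np.trace(np.linalg.solve((h + e).T, h.T).T))
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular H + E cross-product matrix") from exc
    f, df1, df2 = pillai_approx_f(v, p=p, q=1, df_error=df_error)
    pval = float(stats.f.sf(f, df1, df2))
    return CohortTestResult("pillai_V", v, df1, df2, f, pval)


def anova_adjusted(records: pd.DataFrame, isotope: str) -> CohortTestResult:
    """Type II F for the age term in the additive age + subpopulation
    model, on the single requested isotope."""
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    df = records.dropna(subset=[isotope]).rename(columns={isotope: "value"})
    if df["age_class"].nunique() < 2 or df["subpopulation"].nunique() < 2:
        raise ValueError("need at least two levels of both age class and subpopulation")
    model = smf.ols("value ~ C(age_class) + C(subpopulation)", data=df).fit()
    if model.df_resid <= 0 or model.ssr <= 0:
        raise ValueError("zero residual variance")
    table = anova_lm(model, typ=2)
    row = table.loc["C(age_class)"]
    df1 = int(row["df"])
    df2 = int(table.loc["Residual", "df"])
    return CohortTestResult("F", float(row["F"]), df1, df2, float(row["F"]),
                            float(row["PR(>F)"]))


def cohort_report(records: pd.DataFrame, isotopes=ISOTOPES) -> pd.DataFrame:
    """MANOVA plus per-isotope ANOVAs as one tidy table."""
    rows = []
    res = manova_pillai(records, isotopes)
    rows.append({"term": "age|subpopulation", "statistic": "pillai_V", "value": res.value,
                 "approx_F": res.approx_F, "df1": res.df1, "df2": res.df2, "p": res.p_value})
    for iso in isotopes:
        res = anova_adjusted(records, iso)
        rows.append({"term": f"age|subpopulation ({iso})", "statistic": "F", "value": res.value,
                     "approx_F": res.approx_F, "df1": res.df1, "df2": res.df2, "p": res.p_value})
    return pd.DataFrame(rows)
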