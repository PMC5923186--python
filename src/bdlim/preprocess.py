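"""Deterministic data preparation.

Four stages sit between raw inputs and the lag models:

* aggregation of daily PM2.5 predictions to gestational-week means,
* regression-based spirometry z-scores (residuals of an OLS fit on age,
  sex, height and race/ethnicity, scaled to unit variance),
* per-site %5mC from pyrosequencing counts and the 17-site GSTP1 summary,
* a-priori dichotomization of mean %5mC at the sample's fourth quartile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import (
    CollinearityError,
    DegenerateDistributionError,
    DegenerateOutcomeError,
    EmptyInputError,
    MissingDataError,
    UndefinedSiteError,
    ValidationError,
)

SPIROMETRY_OUTCOMES = ("fev1", "fvc", "fev1_fvc", "fef2575")
ZSCORE_COVARIATES = ("child_age", "sex", "height", "race_ethnicity")

#: numpy quantile method used for the quartile split ("type 7": linear
#: interpolation between order statistics), declared in output metadata.
QUANTILE_METHOD = "linear"


# ---------------------------------------------------------------------------
# daily -> weekly exposure aggregation
# ---------------------------------------------------------------------------

def daily_to_weekly(daily_series, T: int | None = None) -> np.ndarray:
    """Average daily concentrations over each gestational week.

    Week t is the mean of days 7(t-1)+1 .. 7t (day 1 = first day
    post-conception).  A trailing partial week with at least one day is
    averaged over the available days; weeks with no days are NaN.

    Parameters
    ----------
    daily_series : array-like
        Daily concentrations (ug/m3) indexed from conception day 1.
    T : int, optional
        Number of weeks to return; defaults to ceil(len/7).
    """
    daily = np.asarray(daily_series, dtype=float)
    if daily.size == 0:
        raise EmptyInputError("daily series is empty")
    if np.any(daily < 0):
        raise ValidationError("negative concentrations in daily series")
    if T is None:
        T = int(np.ceil(daily.size / 7))
    weekly = np.full(T, np.nan)
    for t in range(T):
        chunk = daily[7 * t : 7 * (t + 1)]
        if chunk.size:
            weekly[t] = chunk.mean()
    return weekly


def daily_table_to_weekly(daily: pd.DataFrame, T: int) -> pd.DataFrame:
    """Long-format (child_id, gestational_day, pm25) -> wide weekly matrix."""
    out = {}
    for cid, grp in daily.groupby("child_id"):
        series = grp.sort_values("gestational_day")["pm25"].to_numpy()
        out[cid] = daily_to_weekly(series, T)
    mat = pd.DataFrame.from_dict(out, orient="index")
    mat.columns = [f"pm25_wk{t:02d}" for t in range(1, T + 1)]
    mat.index.name = "child_id"
    return mat.sort_index()


# ---------------------------------------------------------------------------
# lung-function z-scores
# ---------------------------------------------------------------------------

@dataclass
class ZScorePanel:
    """Standardized spirometry outcomes plus the fitted coefficients.

    ``zscores`` holds one ``z_<outcome>`` column per raw outcome, each with
    sample mean 0 and SD 1; ``coefficients``/``residual_sd`` retain the OLS
    standardization fit so new children can be scored consistently.
    """

    zscores: pd.DataFrame
    coefficients: dict[str, pd.Series]
    residual_sd: dict[str, float]

    def coefficient_table(self) -> pd.DataFrame:
        tab = pd.DataFrame(self.coefficients)
        tab.loc["residual_sd"] = pd.Series(self.residual_sd)
        return tab


def _zscore_design(df: pd.DataFrame) -> pd.DataFrame:
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["child_age"] = df["child_age"].astype(float)
    X["height"] = df["height"].astype(float)
    X["sex[boy]"] = (df["sex"] == "boy").astype(float)
    X["race[Hispanic]"] = (df["race_ethnicity"] == "Hispanic").astype(float)
    X["race[White/Other]"] = (df["race_ethnicity"] == "White/Other").astype(float)
    return X


def compute_lung_zscores(
    df: pd.DataFrame, outcomes=SPIROMETRY_OUTCOMES
) -> ZScorePanel:
    """Regression z-scores: residuals of raw spirometry on age, sex, height
    and race/ethnicity, divided by their sample standard deviation."""
    needed = list(ZSCORE_COVARIATES) + list(outcomes)
    sub = df[needed]
    if sub.isna().any().any():
        bad = sub.columns[sub.isna().any()].tolist()
        raise ValidationError(f"missing values in {bad}")
    X = _zscore_design(df)
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # identify offending columns: those whose removal restores full rank
        r_full = np.linalg.matrix_rank(X.to_numpy())
        bad = [
            c
            for c in X.columns
            if np.linalg.matrix_rank(X.drop(columns=c).to_numpy()) == r_full
        ]
        raise CollinearityError(
            f"standardization design is rank deficient (columns {bad})", columns=bad
        )
    if len(df) <= X.shape[1]:
        raise ValidationError("fewer rows than regression coefficients")

    z = pd.DataFrame(index=df.index)
    coefs, rsds = {}, {}
    for out in outcomes:
        fit = sm.OLS(df[out].astype(float), X).fit()
        resid = fit.resid.to_numpy()
        sd = resid.std(ddof=0)
        scale = max(1.0, float(np.std(df[out].to_numpy(dtype=float))))
        if not np.isfinite(sd) or sd <= 1e-10 * scale:
            raise DegenerateOutcomeError(
                f"{out} has zero residual variance; cannot standardize"
            )
        z[f"z_{out}"] = resid / sd
        coefs[out] = fit.params
        rsds[out] = float(sd)
    return ZScorePanel(zscores=z, coefficients=coefs, residual_sd=rsds)


# ---------------------------------------------------------------------------
# GSTP1 methylation
# ---------------------------------------------------------------------------

def percent_methylation(methylated_count, unmethylated_count):
    """%5mC = 100 * methylated / (methylated + unmethylated), elementwise."""
    m = np.asarray(methylated_count, dtype=float)
    u = np.asarray(unmethylated_count, dtype=float)
    if np.any(m < 0) or np.any(u < 0):
        raise ValidationError("read counts must be >= 0")
    total = m + u
    if np.any(total == 0):
        raise UndefinedSiteError("site with zero total reads has no defined %5mC")
    return 100.0 * m / total


def summarize_gstp1(site_values) -> tuple[float, int]:
    """Mean %5mC across non-missing CpG sites, with the missing-site count."""
    v = np.asarray(site_values, dtype=float)
    missing = int(np.isnan(v).sum())
    if missing == v.size:
        raise MissingDataError("all CpG sites missing")
    return float(np.nanmean(v)), missing


@dataclass
class MethylationSummary:
    """Child-level mean %5mC with the fourth-quartile dichotomization."""

    mean_5mc: pd.Series
    high_methylation: pd.Series
    threshold: float
    n_high: int
    n_low: int
    quantile_method: str = QUANTILE_METHOD


def dichotomize_top_quartile(values: pd.Series) -> MethylationSummary:
    """High methylation = mean %5mC at or above the sample's 75th percentile
    (linear-interpolation quantile rule)."""
    v = pd.Series(values).astype(float)
    if len(v) < 4:
        raise ValidationError("need at least 4 children for a quartile split")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite methylation values")
    if v.nunique() == 1:
        raise DegenerateDistributionError("all values identical; no quartile split")
    threshold = float(np.quantile(v.to_numpy(), 0.75, method=QUANTILE_METHOD))
    high = v >= threshold
    return MethylationSummary(
        mean_5mc=v,
        high_methylation=high,
        threshold=threshold,
        n_high=int(high.sum()),
        n_low=int((~high).sum()),
    )


def add_methylation_summary(df: pd.DataFrame, site_columns=None) -> pd.DataFrame:
    """Append ``gstp1_mean`` and ``gstp1_high`` columns from the site panel."""
    if site_columns is None:
        site_columns = [c for c in df.columns if c.startswith("gstp1_site")]
    if not site_columns:
        raise MissingDataError("no GSTP1 site columns found")
    out = df.copy()
    out["gstp1_mean"] = df[site_columns].mean(axis=1, skipna=True)
    summary = dichotomize_top_quartile(out["gstp1_mean"])
    out["gstp1_high"] = summary.high_methylation
    out.attrs["gstp1_threshold"] = summary.threshold
    out.attrs["gstp1_quantile_method"] = summary.quantile_method
    return out
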