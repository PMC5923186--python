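"""Linear models of lung-function z-scores on high GSTP1 methylation.

The epigenetic arm of the analysis: high (fourth-quartile) versus low
mean GSTP1 %5mC as a binary predictor of spirometry z-scores, in a
ladder of adjustment sets, plus sex-stratified fits and a product-term
interaction test.

Model ladder (complete cases, classical standard errors):

* ``univariate`` — high-methylation indicator only,
* ``M1`` — + maternal age and education (the main model),
* ``M2`` — M1 + child asthma (sensitivity),
* ``M3`` — M2 + pre/postnatal tobacco-smoke category (sensitivity).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import CollinearityError, NoContrastError
from .model import build_covariate_design

MODEL_COVARIATES = {
    "univariate": (),
    "M1": ("maternal_age", "maternal_education"),
    "M2": ("maternal_age", "maternal_education", "asthma"),
    "M3": ("maternal_age", "maternal_education", "asthma", "smoking"),
}

HIGH_TERM = "gstp1_high"


def _design(df: pd.DataFrame, model_id: str) -> pd.DataFrame:
    if model_id not in MODEL_COVARIATES:
        raise KeyError(f"unknown model_id {model_id!r}; use {list(MODEL_COVARIATES)}")
    Z = build_covariate_design(df, MODEL_COVARIATES[model_id])
    Z[HIGH_TERM] = df[HIGH_TERM].astype(float)
    return Z


def fit_adjusted_lm(
    df: pd.DataFrame, outcome: str, model_id: str, stratum: str = "all"
) -> pd.DataFrame:
    """OLS of a z-score outcome on the high-methylation indicator.

    Returns EffectTable rows: one per model term plus a ``Ref`` row for
    the low-methylation group, with estimate, classical SE, two-sided
    t-test p-value and the fitted n.
    """
    data = df.dropna(subset=[outcome, HIGH_TERM])
    if data[HIGH_TERM].nunique() < 2:
        raise NoContrastError(
            f"high-methylation indicator constant in stratum {stratum!r}"
        )
    Z = _design(data, model_id)
    if np.linalg.matrix_rank(Z.to_numpy()) < Z.shape[1]:
        raise CollinearityError(f"rank-deficient design for model {model_id}")
    fit = sm.OLS(data[outcome].astype(float), Z).fit()
    rows = [
        {
            "outcome": outcome,
            "model_id": model_id,
            "stratum": stratum,
            "term": "gstp1_low",
            "estimate": 0.0,
            "se": np.nan,
            "p": np.nan,
            "n": int(fit.nobs),
            "ref": True,
        }
    ]
    for term in Z.columns:
        if term == "const":
            continue
        rows.append(
            {
                "outcome": outcome,
                "model_id": model_id,
                "stratum": stratum,
                "term": term,
                "estimate": float(fit.params[term]),
                "se": float(fit.bse[term]),
                "p": float(fit.pvalues[term]),
                "n": int(fit.nobs),
                "ref": False,
            }
        )
    return pd.DataFrame(rows)


def effect_table(df: pd.DataFrame, outcomes, model_ids=tuple(MODEL_COVARIATES)) -> pd.DataFrame:
    """Table-3-shaped grid: every (outcome, model) high-methylation row."""
    pieces = [
        fit_adjusted_lm(df, out, mid) for out in outcomes for mid in model_ids
    ]
    return pd.concat(pieces, ignore_index=True)


def stratified_and_interaction(df: pd.DataFrame, outcome: str) -> pd.DataFrame:
    """Sex-stratified M1 fits plus the pooled sex x methylation interaction.

    The interaction p-value is the two-sided Wald test of the
    boy x high-methylation product term in a pooled model with the M1
    covariates plus sex main effect.
    """
    rows = []
    for sex in ("girl", "boy"):
        stratum = df[df["sex"] == sex]
        if stratum.empty or stratum[HIGH_TERM].nunique() < 2:
            raise NoContrastError(f"stratum {sex!r} lacks methylation contrast")
        stratum_rows = fit_adjusted_lm(
            stratum, outcome, "M1", stratum=f"{sex}s"
        )
        rows.append(stratum_rows)

    pooled = df.dropna(subset=[outcome, HIGH_TERM])
    Z = _design(pooled, "M1")
    Z["sex[boy]"] = (pooled["sex"] == "boy").astype(float)
    Z["sex[boy]:gstp1_high"] = Z["sex[boy]"] * Z[HIGH_TERM]
    fit = sm.OLS(pooled[outcome].astype(float), Z).fit()
    inter = pd.DataFrame(
        [
            {
                "outcome": outcome,
                "model_id": "M1",
                "stratum": "all",
                "term": "sex[boy]:gstp1_high",
                "estimate": float(fit.params["sex[boy]:gstp1_high"]),
                "se": float(fit.bse["sex[boy]:gstp1_high"]),
                "p": np.nan,
                "n": int(fit.nobs),
                "ref": False,
                "p_interaction": float(fit.pvalues["sex[boy]:gstp1_high"]),
            }
        ]
    )
    return pd.concat(rows + [inter], ignore_index=True)


def sex_stratified_table(df: pd.DataFrame, outcomes) -> pd.DataFrame:
    """Table-4-shaped export: per-sex M1 estimates and p-interaction."""
    return pd.concat(
        [stratified_and_interaction(df, out) for out in outcomes],
        ignore_index=True,
    )
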