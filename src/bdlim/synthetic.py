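"""Synthetic pregnancy-cohort generator.

Emulates an urban birth cohort in which each child carries weekly mean
PM2.5 exposure over 40 gestational weeks, demographic and household
covariates, raw spirometry at about age 7, and nasal-epithelium GSTP1
promoter methylation (17 CpG sites, %5mC).  The marginal calibration
targets the descriptives of the motivating cohort: pregnancy-average
PM2.5 median ~10.9 (IQR 10.2-11.7) ug/m3, raw FEV1 1.44 (0.25) L, and a
right-skewed methylation distribution with median 2.26 (IQR 1.56-3.02).

True distributed-lag effects are part of the specification
(:class:`TruthSpec`), so parameter-recovery experiments know the truth
they are trying to recover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import AlignmentError, InvalidSpecError, ShapeError

N_GSTP1_SITES = 17
WEEKS_PER_YEAR = 52.0

SEXES = ("girl", "boy")
RACE_LEVELS = ("Black", "Hispanic", "White/Other")
EDUCATION_LEVELS = ("<=12y", ">12y")
SMOKING_LEVELS = ("never", "prenatal_only", "postnatal_only", "both")

#: outcomes with a direct lag-effect injection slot (raw units per ug/m3)
LAG_OUTCOMES = ("fev1", "fvc", "fef2575", "gstp1")

_DEFAULT_PREVALENCES = {
    "sex": {"girl": 0.479, "boy": 0.521},
    "race_ethnicity": {"Black": 0.228, "Hispanic": 0.655, "White/Other": 0.117},
    "maternal_education": {"<=12y": 0.667, ">12y": 0.333},
    "smoking": {
        "never": 0.714,
        "prenatal_only": 0.082,
        "postnatal_only": 0.140,
        "both": 0.064,
    },
    "asthma": {"no": 0.842, "yes": 0.158},
}

# Raw-unit covariate coefficients for the outcome linear predictors.
# Continuous covariates enter centred at their population means, so each
# target_mean below is the marginal mean of the outcome.
_DEFAULT_COEFFICIENTS = {
    "fev1": {
        "target_mean": 1.44,
        "height": 0.020,       # L per cm
        "child_age": 0.030,    # L per yr beyond the height pathway
        "sex[boy]": 0.05,
        "race[Black]": -0.03,
        "race[White/Other]": 0.02,
        "asthma[yes]": -0.05,
    },
    # FVC is FEV1 plus a strictly positive gap; coefficients below model the gap
    "fvc_gap": {
        "target_mean": 0.14,
        "height": 0.002,
        "sex[boy]": -0.01,
    },
    "fef2575": {
        "target_mean": 1.87,
        "height": 0.025,
        "child_age": 0.020,
        "asthma[yes]": -0.15,
    },
}

_DEFAULT_RESIDUAL_SD = {"fev1": 0.20, "fvc_gap": 0.08, "fef2575": 0.40}


def _lognormal_from_quartiles(median: float, q1: float, q3: float) -> tuple[float, float]:
    """Location/scale of a lognormal matching a printed median and IQR width.

    A two-parameter lognormal cannot match three quantiles exactly; the
    location is pinned to the median and the scale solved so the IQR width
    equals ``q3 - q1`` (the printed quartiles are nearly log-symmetric).
    """
    z75 = 1.3489795003921634 / 2.0  # 75th-percentile standard-normal quantile
    location = math.log(median)
    # IQR = median * (exp(z75*sigma) - exp(-z75*sigma)) = 2*median*sinh(z75*sigma)
    scale = math.asinh((q3 - q1) / (2.0 * median)) / z75
    return location, scale


_METH_LOCATION, _METH_SCALE = _lognormal_from_quartiles(2.26, 1.56, 3.02)


def _zero_lags(T: int) -> dict[str, dict[str, np.ndarray]]:
    return {
        out: {sex: np.zeros(T) for sex in SEXES} for out in LAG_OUTCOMES
    }


@dataclass
class TruthSpec:
    """Complete description of a synthetic cohort, including its truth.

    Parameters
    ----------
    n_children
        Cohort size (default matches the analytic sample size of 171).
    T
        Number of gestational weeks of exposure (week 1 = first week
        post-conception).
    exposure_mean, seasonal_amplitude, ar1_rho, innovation_sd
        Weekly PM2.5 process: mean level plus a 52-week sinusoid with a
        random conception phase per subject plus AR(1) noise, truncated
        at zero (ug/m3).
    covariate_prevalences
        Category -> probability maps for each categorical block.
    true_lag_effects
        ``{outcome: {sex: length-T vector}}`` of raw-outcome-units-per-
        ug/m3 week-specific effects.  Outcomes: fev1, fvc, fef2575,
        gstp1 (the ratio FEV1/FVC is derived, not directly injectable).
    covariate_coefficients
        Raw-unit linear-predictor coefficients per outcome.
    residual_sd
        Raw-unit residual standard deviations per outcome channel.
    methylation_location, methylation_scale
        Lognormal parameters of the child-level mean %5mC (defaults
        solved from median 2.26, IQR 1.56-3.02).
    methylation_site_sd
        Log-scale site-to-site noise around the child mean.
    seed
        Base seed; every generator is a pure function of (spec, seed).
    """

    n_children: int = 171
    T: int = 40
    exposure_mean: float = 10.9
    seasonal_amplitude: float = 3.0
    ar1_rho: float = 0.6
    innovation_sd: float = 2.2
    covariate_prevalences: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_PREVALENCES.items()}
    )
    true_lag_effects: dict = None
    covariate_coefficients: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in _DEFAULT_COEFFICIENTS.items()}
    )
    residual_sd: dict = field(default_factory=lambda: dict(_DEFAULT_RESIDUAL_SD))
    maternal_age_mean: float = 27.2
    maternal_age_sd: float = 5.7
    child_age_mean: float = 6.9
    child_age_sd: float = 0.8
    height_intercept: float = 80.0   # cm at age 0 on the cohort's linear growth line
    height_slope: float = 6.0        # cm per year
    height_sd: float = 5.0
    methylation_location: float = _METH_LOCATION
    methylation_scale: float = _METH_SCALE
    methylation_site_sd: float = 0.30
    seed: int = 0

    def __post_init__(self):
        if self.true_lag_effects is None:
            self.true_lag_effects = _zero_lags(self.T)
        else:
            self.true_lag_effects = {
                out: {sex: np.asarray(v, dtype=float) for sex, v in per_sex.items()}
                for out, per_sex in self.true_lag_effects.items()
            }
        self.validate()

    def validate(self) -> None:
        if not isinstance(self.T, (int, np.integer)) or self.T < 1:
            raise InvalidSpecError(f"T must be an integer >= 1, got {self.T!r}")
        if self.n_children < 1:
            raise InvalidSpecError("n_children must be >= 1")
        for name in ("exposure_mean", "seasonal_amplitude", "innovation_sd"):
            val = getattr(self, name)
            if not np.isfinite(val):
                raise InvalidSpecError(f"{name} must be finite, got {val!r}")
        if not np.isfinite(self.ar1_rho) or abs(self.ar1_rho) >= 1:
            raise InvalidSpecError(f"|ar1_rho| must be < 1, got {self.ar1_rho!r}")
        for block, probs in self.covariate_prevalences.items():
            p = np.array(list(probs.values()), dtype=float)
            if np.any(p < 0) or np.any(p > 1):
                raise InvalidSpecError(f"prevalences for {block!r} outside [0, 1]")
            if abs(p.sum() - 1.0) > 1e-8:
                raise InvalidSpecError(
                    f"prevalences for {block!r} sum to {p.sum():.6f}, expected 1"
                )
        for out, sd in self.residual_sd.items():
            if sd < 0:
                raise InvalidSpecError(f"residual_sd[{out!r}] must be >= 0")
        for out, per_sex in self.true_lag_effects.items():
            if out not in LAG_OUTCOMES:
                raise InvalidSpecError(f"unknown lag-effect outcome {out!r}")
            for sex, vec in per_sex.items():
                if sex not in SEXES:
                    raise InvalidSpecError(f"unknown sex label {sex!r}")
                if np.asarray(vec).shape != (self.T,):
                    raise ShapeError(
                        f"true_lag_effects[{out!r}][{sex!r}] must have length T={self.T}"
                    )

    def rng(self, stage: str) -> np.random.Generator:
        """Independent, reproducible substream for a named pipeline stage."""
        stage_key = int.from_bytes(stage.encode(), "little") % (2**32)
        return np.random.default_rng(np.random.SeedSequence((self.seed, stage_key)))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_lag_effects"] = {
            out: {sex: np.asarray(v).tolist() for sex, v in per_sex.items()}
            for out, per_sex in self.true_lag_effects.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TruthSpec":
        return cls(**d)


def lag_effects_for_zscore_ce(
    spec: TruthSpec, outcome: str, ce: float, window: tuple[int, int]
) -> np.ndarray:
    """Raw-unit per-week lag vector realising a z-score-scale cumulative effect.

    Spreads ``ce`` (z-score units per ug/m3, e.g. -0.10) uniformly over the
    closed week range ``window`` and converts to raw outcome units using the
    outcome's residual standard deviation — the scale the z-scoring stage
    divides by.  The conversion is exact up to the small variance the lag
    term itself adds to the standardization residual (a few percent).
    """
    lo, hi = window
    if not (1 <= lo <= hi <= spec.T):
        raise InvalidSpecError(f"window {window} outside weeks 1..{spec.T}")
    if outcome == "gstp1":
        raw_sd = 1.0  # methylation is analysed on its raw %5mC scale
    elif outcome == "fvc":
        # fvc residual combines the fev1 and gap channels
        raw_sd = math.hypot(spec.residual_sd["fev1"], spec.residual_sd["fvc_gap"])
    else:
        raw_sd = spec.residual_sd[outcome]
    vec = np.zeros(spec.T)
    vec[lo - 1 : hi] = ce * raw_sd / (hi - lo + 1)
    return vec


# ---------------------------------------------------------------------------
# exposures
# ---------------------------------------------------------------------------

def generate_exposures(spec: TruthSpec) -> pd.DataFrame:
    """Weekly mean PM2.5 (ug/m3) for each child over gestational weeks 1..T.

    Process per subject: overall mean + 52-week seasonal sinusoid with a
    uniformly random conception phase + stationary AR(1) noise; truncated
    at zero.  Columns are ``pm25_wk01 .. pm25_wkTT``, index is child_id.
    """
    spec.validate()
    rng = spec.rng("exposures")
    n, T = spec.n_children, spec.T
    weeks = np.arange(1, T + 1)

    phase = rng.uniform(0.0, WEEKS_PER_YEAR, size=n)
    seasonal = spec.seasonal_amplitude * np.sin(
        2.0 * np.pi * (weeks[None, :] + phase[:, None]) / WEEKS_PER_YEAR
    )

    rho, sd = spec.ar1_rho, spec.innovation_sd
    noise = np.empty((n, T))
    stationary_sd = sd / math.sqrt(1.0 - rho**2) if sd > 0 else 0.0
    noise[:, 0] = rng.normal(0.0, 1.0, size=n) * stationary_sd
    shocks = rng.normal(0.0, 1.0, size=(n, T)) * sd
    for t in range(1, T):
        noise[:, t] = rho * noise[:, t - 1] + shocks[:, t]

    x = np.clip(spec.exposure_mean + seasonal + noise, 0.0, None)
    cols = [f"pm25_wk{t:02d}" for t in weeks]
    return pd.DataFrame(x, columns=cols, index=pd.RangeIndex(n, name="child_id"))


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def _draw_categorical(rng, levels, probs, n):
    p = np.array([probs[lv] for lv in levels], dtype=float)
    return rng.choice(np.asarray(levels, dtype=object), size=n, p=p)


def generate_covariates(spec: TruthSpec) -> pd.DataFrame:
    """Child and maternal covariates (no outcomes) for the cohort."""
    spec.validate()
    rng = spec.rng("covariates")
    n = spec.n_children
    prev = spec.covariate_prevalences

    df = pd.DataFrame(index=pd.RangeIndex(n, name="child_id"))
    df["sex"] = _draw_categorical(rng, SEXES, prev["sex"], n)
    df["race_ethnicity"] = _draw_categorical(rng, RACE_LEVELS, prev["race_ethnicity"], n)
    df["maternal_education"] = _draw_categorical(
        rng, EDUCATION_LEVELS, prev["maternal_education"], n
    )
    df["smoking"] = _draw_categorical(rng, SMOKING_LEVELS, prev["smoking"], n)
    df["asthma"] = _draw_categorical(rng, ("no", "yes"), prev["asthma"], n) == "yes"
    df["maternal_age"] = rng.normal(spec.maternal_age_mean, spec.maternal_age_sd, n)
    df["child_age"] = rng.normal(spec.child_age_mean, spec.child_age_sd, n)
    df["height"] = (
        spec.height_intercept
        + spec.height_slope * df["child_age"].to_numpy()
        + rng.normal(0.0, spec.height_sd, n)
    )
    # full-term analysis sample: completed weeks uniform on 37..41
    df["gestational_age"] = rng.integers(37, 42, size=n)
    return df


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------

def _covariate_lp(cov: pd.DataFrame, spec: TruthSpec, outcome: str) -> np.ndarray:
    """Raw-unit linear predictor with continuous covariates centred at their
    population means so the configured target_mean is the marginal mean."""
    coef = spec.covariate_coefficients[outcome]
    mean_height = (
        spec.height_intercept + spec.height_slope * spec.child_age_mean
    )
    lp = np.full(len(cov), coef["target_mean"], dtype=float)
    if "height" in coef:
        lp += coef["height"] * (cov["height"].to_numpy() - mean_height)
    if "child_age" in coef:
        lp += coef["child_age"] * (cov["child_age"].to_numpy() - spec.child_age_mean)
    if "sex[boy]" in coef:
        lp += coef["sex[boy]"] * (cov["sex"].to_numpy() == "boy")
    if "race[Black]" in coef:
        lp += coef["race[Black]"] * (cov["race_ethnicity"].to_numpy() == "Black")
    if "race[White/Other]" in coef:
        lp += coef["race[White/Other]"] * (
            cov["race_ethnicity"].to_numpy() == "White/Other"
        )
    if "asthma[yes]" in coef:
        lp += coef["asthma[yes]"] * cov["asthma"].to_numpy()
    return lp


def _lag_term(spec: TruthSpec, outcome: str, sex: np.ndarray, x: np.ndarray) -> np.ndarray:
    per_sex = spec.true_lag_effects.get(outcome)
    if per_sex is None:
        return np.zeros(len(sex))
    out = np.zeros(len(sex))
    for g in SEXES:
        mask = sex == g
        if mask.any():
            out[mask] = x[mask] @ np.asarray(per_sex[g], dtype=float)
    return out


def generate_outcomes(
    covariates: pd.DataFrame, exposures: pd.DataFrame, spec: TruthSpec
) -> pd.DataFrame:
    """Fill raw spirometry and GSTP1 methylation columns.

    Spirometry: each outcome is its covariate linear predictor plus the
    sex-specific distributed-lag term plus Gaussian noise.  FVC is built
    as FEV1 plus a strictly positive gap so FEV1 <= FVC holds exactly and
    fev1_fvc = fev1/fvc by construction; the configured fvc lag effect is
    realised by injecting (delta_fvc - delta_fev1) into the gap channel.

    Methylation: a child-level mean %5mC from the calibrated lognormal,
    plus the methylation lag term, spread over 17 CpG sites with
    multiplicative log-normal site noise, clipped to [0, 100].
    """
    spec.validate()
    if not covariates.index.equals(exposures.index):
        raise AlignmentError("covariates and exposures must share identical child_ids")
    x = exposures.to_numpy(dtype=float)
    if x.shape[1] != spec.T:
        raise ShapeError(
            f"exposure matrix has {x.shape[1]} weeks, spec.T is {spec.T}"
        )
    rng = spec.rng("outcomes")
    sex = covariates["sex"].to_numpy()
    n = len(covariates)
    df = covariates.copy()

    fev1 = (
        _covariate_lp(covariates, spec, "fev1")
        + _lag_term(spec, "fev1", sex, x)
        + rng.normal(0.0, spec.residual_sd["fev1"], n)
    )
    gap_lag = _lag_term(spec, "fvc", sex, x) - _lag_term(spec, "fev1", sex, x)
    gap = (
        _covariate_lp(covariates, spec, "fvc_gap")
        + gap_lag
        + rng.normal(0.0, spec.residual_sd["fvc_gap"], n)
    )
    gap = np.clip(gap, 0.01, None)
    fvc = fev1 + gap
    fef = (
        _covariate_lp(covariates, spec, "fef2575")
        + _lag_term(spec, "fef2575", sex, x)
        + rng.normal(0.0, spec.residual_sd["fef2575"], n)
    )

    df["fev1"] = fev1
    df["fvc"] = fvc
    df["fev1_fvc"] = fev1 / fvc
    df["fef2575"] = fef

    child_mean = rng.lognormal(spec.methylation_location, spec.methylation_scale, n)
    child_mean = child_mean + _lag_term(spec, "gstp1", sex, x)
    child_mean = np.clip(child_mean, 0.0, 100.0)
    tau = spec.methylation_site_sd
    site_noise = np.exp(
        rng.normal(0.0, 1.0, size=(n, N_GSTP1_SITES)) * tau - 0.5 * tau**2
    )
    sites = np.clip(child_mean[:, None] * site_noise, 0.0, 100.0)
    for j in range(N_GSTP1_SITES):
        df[f"gstp1_site{j + 1:02d}"] = sites[:, j]
    return df


def generate_cohort(spec: TruthSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience wrapper: covariates + outcomes table and exposure matrix."""
    exposures = generate_exposures(spec)
    covariates = generate_covariates(spec)
    cohort = generate_outcomes(covariates, exposures, spec)
    return cohort, exposures


def gstp1_site_columns(df: pd.DataFrame) -> list[str]:
    return [c for c in df.columns if c.startswith("gstp1_site")]
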