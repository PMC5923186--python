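"""Bayesian distributed lag interaction model (BDLIM).

The model relates an outcome y_i to a T-week exposure history x_i and
covariates z_i, allowing a binary modifier g(i) (here child sex) to alter
the *timing* and/or the *magnitude* of the exposure effect:

    y_i = z_i' gamma + beta_{g(i)} * sum_t w_{g(i),t} x_{i,t} + eps_i,
    eps_i ~ Normal(0, sigma^2),   sum_t w_{g,t}^2 = 1.

The distributed lag function delta_{g,t} = beta_g * w_{g,t} is factored
into a unit-L2-norm weight function w_g (which weeks matter) and a scalar
within-window effect beta_g (how much).  Four interaction patterns are
fit: "n" (shared weights and effect), "b" (shared weights, sex-specific
effects), "w" (sex-specific weights, shared effect) and "bw" (both
sex-specific).  Weights live in the span of a natural cubic spline basis
over the week index, normalized to the unit sphere.

Estimation is Metropolis-within-Gibbs: conjugate normal updates for
(gamma, beta) given the weights, a conjugate inverse-gamma update for
sigma^2, and an adaptive random-walk Metropolis step for the spline
coefficients behind each weight function.  The deviance information
criterion (DIC) selects the basis dimension and the interaction pattern.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

with warnings.catch_warnings():
    warnings.simplefilter("ignore", FutureWarning)
    import arviz as az

from .exceptions import (
    CollinearityError,
    ComparabilityError,
    IdentifiabilityError,
    IncompleteFitError,
    InvalidSpecError,
    ShapeError,
    UnidentifiableExposureError,
)

PATTERNS = ("n", "b", "w", "bw")

#: minimum effective sample size of a beta chain before a fit is flagged
MIN_EFFECTIVE_SAMPLE = 100


# ---------------------------------------------------------------------------
# weight basis
# ---------------------------------------------------------------------------

def build_weight_basis(T: int, K: int) -> np.ndarray:
    """Natural cubic spline basis over gestational weeks 1..T.

    Returns a T x K full-rank matrix.  Knots are evenly spaced over
    [1, T]; the basis is {1, t, N_1..N_{K-2}} with the truncated-cubic
    construction whose members are linear beyond the boundary knots.
    """
    if K < 2:
        raise IdentifiabilityError(f"need K >= 2 basis columns, got {K}")
    if K >= T:
        raise IdentifiabilityError(
            f"K={K} weight basis columns with only T={T} weeks is unidentifiable"
        )
    t = np.arange(1, T + 1, dtype=float)
    B = np.empty((T, K))
    B[:, 0] = 1.0
    B[:, 1] = t
    if K > 2:
        knots = np.linspace(1.0, float(T), K)

        def d(k):
            num = np.clip(t - knots[k], 0.0, None) ** 3 - np.clip(
                t - knots[-1], 0.0, None
            ) ** 3
            return num / (knots[-1] - knots[k])

        d_last = d(K - 2)
        for k in range(K - 2):
            B[:, k + 2] = d(k) - d_last
    if np.linalg.matrix_rank(B) < K:  # pragma: no cover - defensive
        raise IdentifiabilityError("weight basis is rank deficient")
    return B


def _normalize(B: np.ndarray, xi: np.ndarray) -> np.ndarray:
    v = B @ xi
    nrm = np.linalg.norm(v)
    if nrm == 0.0:
        raise FloatingPointError("degenerate weight vector")
    return v / nrm


# ---------------------------------------------------------------------------
# specification and fit containers
# ---------------------------------------------------------------------------

@dataclass
class BDLIMSpec:
    """Pattern, weight basis dimension, priors and MCMC settings.

    Priors: gamma and beta ~ Normal(0, c^2) with ``prior_effect_var`` c^2
    (default 100, weakly informative on standardized outcomes); sigma^2 ~
    Inverse-Gamma(``prior_sigma_shape``, ``prior_sigma_scale``).
    """

    pattern: str = "bw"
    weight_df: int = 4
    prior_effect_var: float = 100.0
    prior_sigma_shape: float = 0.01
    prior_sigma_scale: float = 0.01
    n_iter: int = 10_000
    burn_in: int = 5_000
    thin: int = 5
    proposal_scale: float = 0.25
    seed: int = 0

    def validate(self, T: int | None = None) -> None:
        if self.pattern not in PATTERNS:
            raise InvalidSpecError(f"pattern must be one of {PATTERNS}")
        if self.weight_df < 2:
            raise InvalidSpecError("weight_df must be >= 2")
        if T is not None and self.weight_df >= T:
            raise IdentifiabilityError("weight_df must be < number of weeks")
        if not (self.n_iter > self.burn_in >= 0):
            raise InvalidSpecError("need n_iter > burn_in >= 0")
        if self.thin < 1:
            raise InvalidSpecError("thin must be >= 1")
        for name in ("prior_effect_var", "prior_sigma_shape", "prior_sigma_scale"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0")


@dataclass
class BDLIMFit:
    """Posterior draws and bookkeeping for one fitted pattern.

    ``weights[g]`` is draws x T (unit L2 norm per draw, sum >= 0 under the
    sign convention where identified); ``beta[g]`` is draws; shared
    components are the same ndarray object for both group labels.
    """

    spec: BDLIMSpec
    groups: tuple[str, ...]
    weights: dict[str, np.ndarray]
    beta: dict[str, np.ndarray]
    gamma: np.ndarray
    gamma_names: tuple[str, ...]
    sigma2: np.ndarray
    log_likelihood: np.ndarray
    acceptance_rate: dict[str, float]
    ess_beta: dict[str, float]
    converged: bool
    basis: np.ndarray
    # data references retained for plug-in deviance / DIC
    y: np.ndarray
    X: np.ndarray
    Z: np.ndarray
    group_labels: np.ndarray
    dic: dict | None = field(default=None)

    @property
    def n_draws(self) -> int:
        return len(self.sigma2)


# ---------------------------------------------------------------------------
# design helpers
# ---------------------------------------------------------------------------

_TERM_BUILDERS = {
    "maternal_age": lambda df: {"maternal_age": df["maternal_age"].astype(float)},
    "child_age": lambda df: {"child_age": df["child_age"].astype(float)},
    "height": lambda df: {"height": df["height"].astype(float)},
    "sex": lambda df: {"sex[boy]": (df["sex"] == "boy").astype(float)},
    "maternal_education": lambda df: {
        "maternal_education[>12y]": (df["maternal_education"] == ">12y").astype(float)
    },
    "race_ethnicity": lambda df: {
        "race[Hispanic]": (df["race_ethnicity"] == "Hispanic").astype(float),
        "race[White/Other]": (df["race_ethnicity"] == "White/Other").astype(float),
    },
    "asthma": lambda df: {"asthma[yes]": df["asthma"].astype(float)},
    "smoking": lambda df: {
        f"smoking[{lv}]": (df["smoking"] == lv).astype(float)
        for lv in ("prenatal_only", "postnatal_only", "both")
    },
}

#: covariates for spirometry-outcome lag models (z-scores already absorb
#: age, sex, height and race/ethnicity)
SPIROMETRY_ADJUSTMENT = ("maternal_age", "maternal_education")
#: covariates for the methylation-outcome lag model
METHYLATION_ADJUSTMENT = (
    "child_age",
    "sex",
    "race_ethnicity",
    "maternal_age",
    "maternal_education",
)


def build_covariate_design(df: pd.DataFrame, terms) -> pd.DataFrame:
    """Intercept + indicator-coded covariate design for the named terms."""
    Z = {"const": pd.Series(1.0, index=df.index)}
    for term in terms:
        if term not in _TERM_BUILDERS:
            raise InvalidSpecError(f"unknown covariate term {term!r}")
        Z.update(_TERM_BUILDERS[term](df))
    return pd.DataFrame(Z)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

def fit_bdlim(
    y,
    X,
    Z,
    group,
    spec: BDLIMSpec,
    fixed_weights: dict | None = None,
) -> BDLIMFit:
    """Fit the BDLIM for one interaction pattern by MCMC.

    Parameters
    ----------
    y : (n,) outcome vector (typically a spirometry z-score or raw %5mC).
    X : (n, T) weekly exposure matrix (DataFrame or ndarray).
    Z : (n, p) covariate design including an intercept column.
    group : (n,) modifier labels (two levels); may be None for pattern "n".
    spec : BDLIMSpec.
    fixed_weights : optional {group_or_"shared": (T,) unit vector}.
        Diagnostic mode: holds the weight functions fixed (no Metropolis
        step), leaving a purely conjugate linear model in (gamma, beta,
        sigma^2).
    """
    y = np.asarray(y, dtype=float).ravel()
    Xdf = X if isinstance(X, pd.DataFrame) else None
    X = np.asarray(X, dtype=float)
    Zdf = Z if isinstance(Z, pd.DataFrame) else None
    gamma_names = tuple(Zdf.columns) if Zdf is not None else tuple(
        f"z{j}" for j in range(np.asarray(Z).shape[1])
    )
    Z = np.asarray(Z, dtype=float)
    n, T = X.shape
    spec.validate(T=T)
    if len(y) != n or Z.shape[0] != n:
        raise ShapeError("y, X and Z must have matching row counts")
    if not np.any(X.var(axis=0) > 0):
        raise UnidentifiableExposureError(
            "every exposure week has zero between-subject variance"
        )
    if np.linalg.matrix_rank(Z) < Z.shape[1]:
        raise CollinearityError("covariate design Z is rank deficient")

    if group is None:
        if spec.pattern != "n":
            raise InvalidSpecError("group labels required unless pattern is 'n'")
        group = np.zeros(n, dtype=int)
    group = np.asarray(group)
    levels = tuple(sorted(pd.unique(group).tolist(), key=str))
    if spec.pattern != "n":
        if len(levels) != 2:
            raise InvalidSpecError(
                f"patterns b/w/bw need exactly 2 non-empty groups, got {levels}"
            )
    groups = tuple(levels)

    # Always include the modifier's main effect: the weighted-exposure
    # column of each group carries a near-constant level component
    # (mean exposure times the weight sum), which is confounded with a
    # group mean shift unless the main effect is in the design.
    if len(groups) == 2:
        main = (group == groups[1]).astype(float)
        Z_aug = np.column_stack([Z, main])
        if np.linalg.matrix_rank(Z_aug) == Z.shape[1] + 1:
            Z = Z_aug
            gamma_names = gamma_names + (f"group[{groups[1]}]",)

    share_w = spec.pattern in ("n", "b")
    share_b = spec.pattern in ("n", "w")
    weight_keys = ("shared",) if share_w else groups
    effect_keys = ("shared",) if share_b else groups

    rng = np.random.default_rng(spec.seed)
    K = spec.weight_df
    B = build_weight_basis(T, K)

    # row membership per weight function and per effect column
    def rows_for(key):
        return np.ones(n, dtype=bool) if key == "shared" else group == key

    w_rows = {k: rows_for(k) for k in weight_keys}
    e_rows = {k: rows_for(k) for k in effect_keys}

    def weight_key_of(effect_or_row_group):
        return "shared" if share_w else effect_or_row_group

    # state
    if fixed_weights is not None:
        w_state = {
            k: np.asarray(fixed_weights[k], dtype=float) / np.linalg.norm(fixed_weights[k])
            for k in weight_keys
        }
        xi_state = {k: np.linalg.lstsq(B, w_state[k], rcond=None)[0] for k in weight_keys}
    else:
        flat = np.full(T, 1.0 / np.sqrt(T))
        xi0 = np.linalg.lstsq(B, flat, rcond=None)[0]
        xi_state = {
            k: xi0 + 0.05 * rng.standard_normal(K) for k in weight_keys
        }
        w_state = {k: _normalize(B, xi_state[k]) for k in weight_keys}

    # per-row weighted exposure u_i = x_i . w_{wg(i)}
    def weighted_exposure(w_dict):
        u = np.empty(n)
        for k in weight_keys:
            u[w_rows[k]] = X[w_rows[k]] @ w_dict[k]
        return u

    u = weighted_exposure(w_state)

    p = Z.shape[1]
    q = len(effect_keys)
    c2 = spec.prior_effect_var
    a0, b0 = spec.prior_sigma_shape, spec.prior_sigma_scale

    def design(u_vec):
        D = np.empty((n, p + q))
        D[:, :p] = Z
        for j, k in enumerate(effect_keys):
            col = np.zeros(n)
            col[e_rows[k]] = u_vec[e_rows[k]]
            D[:, p + j] = col
        return D

    # init theta, sigma2 from a ridge solve
    D = design(u)
    theta = np.linalg.solve(D.T @ D + np.eye(p + q) / c2, D.T @ y)
    resid = y - D @ theta
    sigma2 = max(float(resid @ resid) / max(n - p - q, 1), 1e-8)

    scales = {k: spec.proposal_scale for k in weight_keys}
    accept = {k: 0 for k in weight_keys}
    prop_count = {k: 0 for k in weight_keys}
    batch_accept = {k: 0 for k in weight_keys}
    batch_count = {k: 0 for k in weight_keys}

    n_keep = (spec.n_iter - spec.burn_in + spec.thin - 1) // spec.thin
    store_w = {k: np.empty((n_keep, T)) for k in weight_keys}
    store_beta = {k: np.empty(n_keep) for k in effect_keys}
    store_gamma = np.empty((n_keep, p))
    store_sigma2 = np.empty(n_keep)
    store_ll = np.empty(n_keep)

    log2pi = np.log(2.0 * np.pi)
    betas = theta[p:]
    kept = 0

    for it in range(spec.n_iter):
        # --- Metropolis update of each weight function (unless fixed) ---
        if fixed_weights is None:
            for k in weight_keys:
                rows = w_rows[k]
                xi_prop = xi_state[k] + scales[k] * rng.standard_normal(K)
                try:
                    w_prop = _normalize(B, xi_prop)
                except FloatingPointError:
                    continue
                u_prop_rows = X[rows] @ w_prop
                # residuals over affected rows only
                lin = Z[rows] @ theta[:p]
                beta_row = np.zeros(rows.sum())
                for j, ek in enumerate(effect_keys):
                    sub = e_rows[ek][rows]
                    beta_row[sub] = betas[j]
                r_cur = y[rows] - lin - beta_row * u[rows]
                r_new = y[rows] - lin - beta_row * u_prop_rows
                ll_diff = (r_cur @ r_cur - r_new @ r_new) / (2.0 * sigma2)
                prior_diff = 0.5 * (xi_state[k] @ xi_state[k] - xi_prop @ xi_prop)
                prop_count[k] += 1
                batch_count[k] += 1
                if np.log(rng.uniform()) < ll_diff + prior_diff:
                    xi_state[k] = xi_prop
                    w_state[k] = w_prop
                    u[rows] = u_prop_rows
                    accept[k] += 1
                    batch_accept[k] += 1
                # adapt toward 20-40% acceptance during burn-in
                if it < spec.burn_in and batch_count[k] == 100:
                    rate = batch_accept[k] / 100.0
                    if rate < 0.2:
                        scales[k] *= 0.8
                    elif rate > 0.4:
                        scales[k] *= 1.25
                    batch_accept[k] = 0
                    batch_count[k] = 0

        # --- conjugate (gamma, beta) update ---
        D = design(u)
        prec = D.T @ D / sigma2 + np.eye(p + q) / c2
        chol = np.linalg.cholesky(prec)
        mean = np.linalg.solve(prec, D.T @ y / sigma2)
        theta = mean + np.linalg.solve(chol.T, rng.standard_normal(p + q))
        betas = theta[p:]

        # --- sigma^2 update ---
        resid = y - D @ theta
        rss = float(resid @ resid)
        sigma2 = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * rss))

        # --- store ---
        if it >= spec.burn_in and (it - spec.burn_in) % spec.thin == 0:
            ll = -0.5 * n * (log2pi + np.log(sigma2)) - rss / (2.0 * sigma2)
            w_out = {k: w_state[k].copy() for k in weight_keys}
            beta_out = {k: float(betas[j]) for j, k in enumerate(effect_keys)}
            _apply_sign_convention(spec.pattern, w_out, beta_out, weight_keys, effect_keys)
            for k in weight_keys:
                store_w[k][kept] = w_out[k]
            for k in effect_keys:
                store_beta[k][kept] = beta_out[k]
            store_gamma[kept] = theta[:p]
            store_sigma2[kept] = sigma2
            store_ll[kept] = ll
            kept += 1

    acc_rate = {
        k: (accept[k] / prop_count[k] if prop_count[k] else float("nan"))
        for k in weight_keys
    }

    # expand shared components to both group labels (same object)
    weights = {g: store_w["shared" if share_w else g] for g in groups}
    beta = {g: store_beta["shared" if share_b else g] for g in groups}

    ess = {}
    for g in groups:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ess[g] = float(az.ess(np.asarray(beta[g])))
    converged = all(e >= MIN_EFFECTIVE_SAMPLE for e in ess.values())
    if not converged:
        warnings.warn(
            f"effective sample size of beta below {MIN_EFFECTIVE_SAMPLE}: {ess}",
            RuntimeWarning,
            stacklevel=2,
        )

    return BDLIMFit(
        spec=spec,
        groups=groups,
        weights=weights,
        beta=beta,
        gamma=store_gamma,
        gamma_names=gamma_names,
        sigma2=store_sigma2,
        log_likelihood=store_ll,
        acceptance_rate=acc_rate,
        ess_beta=ess,
        converged=converged,
        basis=B,
        y=y,
        X=X,
        Z=Z,
        group_labels=group,
    )


def _apply_sign_convention(pattern, w_out, beta_out, weight_keys, effect_keys):
    """Flip (beta, w) blocks jointly so the identified weight sums are >= 0.

    The likelihood is invariant to a joint sign flip of a (beta, w) pair.
    Where a component is shared the flip is applied to the whole invariant
    block: pattern "b" flips the shared w with both betas; pattern "w"
    flips the shared beta with both weight functions, keyed on the first
    group's weight sum.
    """
    if pattern in ("n", "bw"):
        # independent (beta_g, w_g) pairs (one pair for "n")
        for wk, ek in zip(weight_keys, effect_keys):
            if w_out[wk].sum() < 0:
                w_out[wk] = -w_out[wk]
                beta_out[ek] = -beta_out[ek]
    elif pattern == "b":
        if w_out["shared"].sum() < 0:
            w_out["shared"] = -w_out["shared"]
            for ek in effect_keys:
                beta_out[ek] = -beta_out[ek]
    else:  # pattern "w"
        if w_out[weight_keys[0]].sum() < 0:
            beta_out["shared"] = -beta_out["shared"]
            for wk in weight_keys:
                w_out[wk] = -w_out[wk]


# ---------------------------------------------------------------------------
# DIC and model comparison
# ---------------------------------------------------------------------------

def _plugin_log_likelihood(fit: BDLIMFit) -> float:
    """Gaussian log-likelihood at posterior means (weights mean-renormalized)."""
    n = len(fit.y)
    # plug-in weights per group: average draws then renormalize
    w_bar = {}
    for g in fit.groups:
        m = fit.weights[g].mean(axis=0)
        w_bar[g] = m / np.linalg.norm(m)
    beta_bar = {g: float(np.mean(fit.beta[g])) for g in fit.groups}
    gamma_bar = fit.gamma.mean(axis=0)
    sigma2_bar = float(np.mean(fit.sigma2))

    lag = np.zeros(n)
    for g in fit.groups:
        mask = (
            np.ones(n, dtype=bool) if len(fit.groups) == 1 else fit.group_labels == g
        )
        lag[mask] = beta_bar[g] * (fit.X[mask] @ w_bar[g])
    resid = fit.y - fit.Z @ gamma_bar - lag
    rss = float(resid @ resid)
    return -0.5 * n * (np.log(2.0 * np.pi) + np.log(sigma2_bar)) - rss / (
        2.0 * sigma2_bar
    )


def compute_dic(fit: BDLIMFit) -> dict:
    """DIC = D_bar + p_D with D_bar the posterior-mean deviance and
    p_D = D_bar - D(posterior means)."""
    if fit.log_likelihood is None or len(fit.log_likelihood) == 0:
        raise IncompleteFitError("fit has no stored log-likelihood trace")
    if len(fit.log_likelihood) < 200:
        raise IncompleteFitError(
            f"need >= 200 retained draws for DIC, have {len(fit.log_likelihood)}"
        )
    d_bar = float(np.mean(-2.0 * fit.log_likelihood))
    d_hat = -2.0 * _plugin_log_likelihood(fit)
    p_d = d_bar - d_hat
    record = {"D_bar": d_bar, "p_D": p_d, "DIC": d_bar + p_d}
    fit.dic = record
    return record


def compare_patterns(fits: dict[str, BDLIMFit]) -> pd.DataFrame:
    """DIC table across interaction patterns with pseudo-probabilities.

    The normalized weight exp(-dDIC/2) / sum exp(-dDIC/2) approximates the
    probability each pattern is the best-fitting form of effect
    modification (flagged as a DIC-based approximation in the metadata).
    """
    sizes = {pat: len(f.y) for pat, f in fits.items()}
    if len(set(sizes.values())) != 1:
        raise ComparabilityError(f"fits are on different sample sizes: {sizes}")
    ys = [f.y for f in fits.values()]
    if any(not np.array_equal(ys[0], yy) for yy in ys[1:]):
        raise ComparabilityError("fits are on different outcome vectors")
    rows = []
    for pat, f in fits.items():
        rec = f.dic if f.dic is not None else compute_dic(f)
        rows.append({"pattern": pat, "DIC": rec["DIC"], "p_D": rec["p_D"]})
    tab = pd.DataFrame(rows)
    tab["delta_DIC"] = tab["DIC"] - tab["DIC"].min()
    raw = np.exp(-0.5 * tab["delta_DIC"].to_numpy())
    tab["weight"] = raw / raw.sum()
    tab["best"] = tab["delta_DIC"] == 0.0
    tab.attrs["weight_method"] = "DIC pseudo-probability exp(-delta/2), normalized"
    return tab


def select_weight_df(y, X, Z, group, K_grid, spec: BDLIMSpec):
    """Fit a grid of weight-basis dimensions; return (best K, DIC trace).

    Ties in DIC break toward the smaller K.
    """
    K_grid = list(K_grid)
    if not K_grid:
        raise InvalidSpecError("empty weight-df grid")
    rows = []
    for K in sorted(K_grid):
        fit = fit_bdlim(y, X, Z, group, replace(spec, weight_df=K))
        rec = compute_dic(fit)
        rows.append({"K": K, "DIC": rec["DIC"], "p_D": rec["p_D"]})
    trace = pd.DataFrame(rows)
    best = int(trace.loc[trace["DIC"].idxmin(), "K"])
    return best, trace
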