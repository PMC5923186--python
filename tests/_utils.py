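"""Shared helpers for simulation-based tests."""

import numpy as np

import bdlim
from bdlim.model import SPIROMETRY_ADJUSTMENT, build_covariate_design


def fit_simulated(
    seed,
    pattern="bw",
    n=1000,
    boy_ce=None,
    girl_ce=None,
    boy_window=(35, 40),
    girl_window=(10, 15),
    K=4,
    n_iter=6000,
    burn_in=3000,
    mcmc_seed_offset=1000,
):
    """Generate a cohort with configured true FEV1 lag effects, z-score it,
    and fit one BDLIM pattern on z_fev1."""
    spec = bdlim.TruthSpec(n_children=n, seed=seed)
    if boy_ce is not None:
        spec.true_lag_effects["fev1"]["boy"] = bdlim.lag_effects_for_zscore_ce(
            spec, "fev1", boy_ce, boy_window
        )
    if girl_ce is not None:
        spec.true_lag_effects["fev1"]["girl"] = bdlim.lag_effects_for_zscore_ce(
            spec, "fev1", girl_ce, girl_window
        )
    cohort, exposures = bdlim.generate_cohort(spec)
    cohort = cohort[cohort.gestational_age >= 37]
    exposures = exposures.loc[cohort.index]
    panel = bdlim.compute_lung_zscores(cohort)
    y = panel.zscores["z_fev1"].to_numpy()
    Z = build_covariate_design(cohort, SPIROMETRY_ADJUSTMENT)
    group = None if pattern == "n" else cohort["sex"].to_numpy()
    mspec = bdlim.BDLIMSpec(
        pattern=pattern,
        weight_df=K,
        n_iter=n_iter,
        burn_in=burn_in,
        thin=5,
        seed=seed + mcmc_seed_offset,
    )
    fit = bdlim.fit_bdlim(y, exposures, Z, group, mspec)
    return spec, fit


def intersects(windows, lo, hi):
    """True if any reported window overlaps the closed range [lo, hi]."""
    return any(not (w_hi < lo or w_lo > hi) for w_lo, w_hi in windows)


def exact_posterior_summaries(y, D, c2, a0, b0, ngrid=400):
    """Numerically exact posterior summaries and DIC for the conjugate
    linear model y = D theta + eps, theta ~ N(0, c2 I), sigma2 ~ IG(a0, b0).

    Marginalizes theta in closed form and integrates sigma2 on a grid
    (1-D quadrature), independent of any MCMC code path.
    """
    y = np.asarray(y, float)
    D = np.asarray(D, float)
    n, p = D.shape
    DtD = D.T @ D
    Dty = D.T @ y
    yty = float(y @ y)
    Ip = np.eye(p)

    def conditional(s2):
        prec = DtD / s2 + Ip / c2
        V = np.linalg.inv(prec)
        m = V @ Dty / s2
        return m, V

    def log_posterior_s2(s2):
        # matrix determinant lemma + Woodbury keep everything p x p
        M = Ip + (c2 / s2) * DtD
        sign, logdet_M = np.linalg.slogdet(M)
        quad = (yty - (c2 / s2) * Dty @ np.linalg.solve(M, Dty)) / s2
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + logdet_M + quad)
        return ll - (a0 + 1) * np.log(s2) - b0 / s2

    theta_ls = np.linalg.lstsq(D, y, rcond=None)[0]
    s2_hat = float(np.sum((y - D @ theta_ls) ** 2)) / max(n - p, 1)
    grid = np.linspace(0.3 * s2_hat, 3.0 * s2_hat, ngrid)
    logw = np.array([log_posterior_s2(s) for s in grid])
    w = np.exp(logw - logw.max())
    w /= w.sum()

    mean_dev = 0.0
    mean_theta = np.zeros(p)
    mean_s2 = 0.0
    for s2, wi in zip(grid, w):
        m, V = conditional(s2)
        e_rss = yty - 2 * m @ Dty + float(np.sum((np.outer(m, m) + V) * DtD))
        mean_dev += wi * (n * np.log(2 * np.pi * s2) + e_rss / s2)
        mean_theta += wi * m
        mean_s2 += wi * s2
    rss_bar = float(np.sum((y - D @ mean_theta) ** 2))
    d_hat = n * np.log(2 * np.pi * mean_s2) + rss_bar / mean_s2
    p_d = mean_dev - d_hat
    return {
        "theta_mean": mean_theta,
        "sigma2_mean": mean_s2,
        "D_bar": mean_dev,
        "p_D": p_d,
        "DIC": mean_dev + p_d,
    }
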