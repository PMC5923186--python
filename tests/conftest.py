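import numpy as np
import pandas as pd
import pytest

import bdlim
from bdlim.model import SPIROMETRY_ADJUSTMENT, build_covariate_design


@pytest.fixture(scope="session")
def small_cohort():
    """Moderate synthetic cohort with a strong boys-only late window."""
    spec = bdlim.TruthSpec(n_children=400, seed=42)
    spec.true_lag_effects["fev1"]["boy"] = bdlim.lag_effects_for_zscore_ce(
        spec, "fev1", -0.5, (35, 40)
    )
    cohort, exposures = bdlim.generate_cohort(spec)
    return spec, cohort, exposures


@pytest.fixture(scope="session")
def zscored(small_cohort):
    spec, cohort, exposures = small_cohort
    panel = bdlim.compute_lung_zscores(cohort)
    df = pd.concat([cohort, panel.zscores], axis=1)
    return spec, df, exposures, panel


@pytest.fixture(scope="session")
def bw_fit(zscored):
    """One pattern-bw fit reused by invariant and summary tests."""
    spec, df, exposures, _ = zscored
    Z = build_covariate_design(df, SPIROMETRY_ADJUSTMENT)
    mspec = bdlim.BDLIMSpec(
        pattern="bw", weight_df=4, n_iter=3000, burn_in=1000, thin=5, seed=7
    )
    fit = bdlim.fit_bdlim(
        df["z_fev1"].to_numpy(), exposures, Z, df["sex"].to_numpy(), mspec
    )
    bdlim.compute_dic(fit)
    return fit


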