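import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import svyscan as sv

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def gen_config():
    return sv.GeneratorConfig(n_subjects=800, seed=20260928)


@pytest.fixture(scope="session")
def cohort(gen_config):
    """A moderately sized synthetic cohort, inclusion criteria applied."""
    raw = sv.generate_cohort(gen_config)
    return sv.apply_inclusion_criteria(raw)


@pytest.fixture(scope="session")
def analysis_frame(cohort, gen_config):
    """Cohort with transformed exposures and coded covariates attached."""
    lods = gen_config.resolve().lods
    z = sv.transform_exposures(cohort, sv.METABOLITES, lods)
    coded = sv.encode_covariates(cohort)
    keep = cohort.drop(columns=coded.columns.intersection(cohort.columns))
    return pd.concat([keep, z, coded], axis=1)


@pytest.fixture(scope="session")
def design(analysis_frame):
    return sv.SurveyDesign.from_frame(analysis_frame)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


# ---------------------------------------------------------------------------
# Small fixed design fixtures for the linearization oracles
# ---------------------------------------------------------------------------

@pytest.fixture(scope="session")
def design_fixture_12():
    """12 rows, 2 strata x 2 PSUs, unequal weights, binary outcome."""
    return pd.DataFrame({
        "stratum": [1, 1, 1, 1, 1, 1, 2, 2, 2, 2, 2, 2],
        "psu":     [1, 1, 1, 2, 2, 2, 1, 1, 1, 2, 2, 2],
        "weight":  [1.5, 2.0, 0.5, 3.0, 1.0, 2.5, 1.0, 4.0, 2.0, 0.8, 1.2, 2.2],
        "y":       [1, 0, 1, 1, 0, 0, 1, 1, 0, 0, 1, 0],
    })


@pytest.fixture(scope="session")
def design_fixture_16():
    """16 rows, 2 strata x 2 PSUs, unequal weights, a continuous predictor."""
    rng = np.random.default_rng(7)
    n = 16
    df = pd.DataFrame({
        "stratum": np.repeat([1, 2], 8),
        "psu": np.tile(np.repeat([1, 2], 4), 2),
        "weight": np.round(rng.uniform(0.5, 4.0, n), 3),
        "x": np.round(rng.normal(0, 1, n), 3),
    })
    df["y"] = (rng.random(n) < 1 / (1 + np.exp(-(-0.3 + 0.8 * df["x"])))).astype(int)
    # make sure both outcome classes appear in every PSU cell's stratum
    df.loc[0, "y"], df.loc[7, "y"], df.loc[8, "y"], df.loc[15, "y"] = 1, 0, 1, 0
    return df
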