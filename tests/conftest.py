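from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import pedbc as pb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

FIXTURE_DIR = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def default_cohort():
    """Full three-wave study-scale cohort with planted clusters."""
    params = pb.CohortParams(seed=1)
    cohort, labels = pb.generate_cohort(params)
    return params, cohort, labels


@pytest.fixture(scope="session")
def planted_cohort():
    """Single-wave n=500 cohort at the planted-recovery condition.

    Centroid separation >= 2 in (FMI, MMI, BNI, TWI) z-space, within-cluster
    SD 0.3, no wave-to-wave jitter.
    """
    params = pb.CohortParams(
        n_subjects=500, waves=1, participation=(1.0,), wave_jitter_sd=0.0, seed=11
    )
    cohort, labels = pb.generate_cohort(params)
    return params, cohort, labels


@pytest.fixture(scope="session")
def planted_zmatrix(planted_cohort):
    """Ground-truth z-score matrix of the planted cohort (cluster features)."""
    params, cohort, labels = planted_cohort
    Z = pb.generating_zscores(params, cohort)
    truth = cohort["subject_id"].map(labels).to_numpy()
    return Z[["z_bmi", "z_fmi", "z_mmi", "z_bni"]], truth


@pytest.fixture(scope="session")
def screening_fixture_path():
    return FIXTURE_DIR / "screening_fixture.csv"


@pytest.fixture()
def screening_fixture(screening_fixture_path):
    return pd.read_csv(screening_fixture_path, parse_dates=["date"])


@pytest.fixture(scope="session")
def fitted_reference(default_cohort):
    _, cohort, _ = default_cohort
    df = pb.add_bci_columns(cohort)
    return df, pb.BCIReferenceModel().fit(df)


def constant_reference_model(mean=5.0, sd=0.5, domain=(7.0, 14.0)):
    """Reference-model fixture with flat mean/SD curves on a given domain."""
    payload = {
        "format": "pedbc-reference",
        "version": 1,
        "degree": 3,
        "sd_floor": 1e-6,
        "coefficient_order": "ascending",
        "curves": [
            {
                "sex": sex,
                "index": index,
                "c_mean": [mean, 0.0, 0.0, 0.0],
                "c_upper": [mean + sd, 0.0, 0.0, 0.0],
                "c_lower": [mean - sd, 0.0, 0.0, 0.0],
                "residual_ss": {"mean": 0.0, "upper": 0.0, "lower": 0.0},
                "age_domain": list(domain),
            }
            for sex in ("male", "female")
            for index in ("fmi",)
        ],
    }
    return pb.BCIReferenceModel.from_dict(payload)
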