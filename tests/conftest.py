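import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import carechoice as cc
from carechoice import choice_sets, quality_linkage

settings.register_profile(
    "ci",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


# Small synthetic market used across the suite.  The seed is chosen so the
# market is identified (hospitals vary in teaching/cicu status and at least
# one surgeon practices at hospitals with differing attributes).
SMALL_CONFIG = cc.MarketConfig(
    n_patients=800,
    n_hospitals=8,
    n_surgeons=12,
    seed=3,
    region_extent_miles=80.0,
    teaching_share=0.5,
    cicu_share=0.5,
    second_affiliation_prob=0.6,
)


@pytest.fixture(scope="session")
def small_study() -> cc.SyntheticStudy:
    study = cc.generate_market(SMALL_CONFIG)
    truth = cc.default_true_parameters(study.surgeons["surgeon_id"], seed=1, fe_sd=0.3)
    return cc.simulate_choices(study, truth, seed=7)


@pytest.fixture(scope="session")
def small_panel(small_study) -> pd.DataFrame:
    return quality_linkage.build_quality_panel(
        small_study.reviews,
        small_study.report_cards,
        small_study.surgeons["surgeon_id"],
        range(small_study.config.study_quarters),
    )


@pytest.fixture(scope="session")
def small_long(small_study, small_panel) -> pd.DataFrame:
    rows, _ = choice_sets.build_choice_rows(
        small_study.discharges, small_study.roster_at, radius=None
    )
    return choice_sets.assemble_long_dataset(rows, small_panel)


@pytest.fixture(scope="session")
def small_data(small_long) -> cc.EstimationData:
    return cc.EstimationData(small_long, cc.ModelSpec())


@pytest.fixture(scope="session")
def small_fit(small_data) -> cc.FitResult:
    """Mixed-logit fit of the small market (shared; treat as read-only)."""
    return cc.fit(small_data, draws=48, method="halton", seed=0, tol=1e-4,
                  hessian_scheme="forward")


def subset_patients(long_df: pd.DataFrame, n: int) -> pd.DataFrame:
    keep = sorted(long_df["patient_id"].unique())[:n]
    return long_df[long_df["patient_id"].isin(keep)].reset_index(drop=True)
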