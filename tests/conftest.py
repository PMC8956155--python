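import datetime as dt

import pytest
from hypothesis import HealthCheck, settings

import labequity as le
from labequity.ingest import ExclusionConfig
from labequity.pipeline import RunConfig, run_pipeline

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture()
def toy_cases() -> list[le.CaseRecord]:
    """Six hand-built cases: 2 pathologists, 2 sites, mixed classes."""

    def rec(i, pid, day, site, org, cls, spec=1, blocks=2):
        return le.CaseRecord(
            case_id=f"T{i}",
            pathologist_id=pid,
            signout_date=day,
            site=site,
            organization=org,
            case_class=cls,
            specimen_count=spec,
            block_count=blocks,
        )

    return [
        rec(1, "A", dt.date(2018, 1, 8), "AH", "alpha_org", "surgical"),
        rec(2, "A", dt.date(2018, 1, 9), "AH", "alpha_org", "surgical", spec=4, blocks=6),
        rec(3, "A", dt.date(2018, 2, 5), "B1H", "beta_org", "cytology", blocks=0),
        rec(4, "B", dt.date(2018, 1, 8), "B1H", "beta_org", "surgical"),
        rec(5, "B", dt.date(2018, 3, 12), "B1H", "beta_org", "review", blocks=1),
        rec(6, "B", dt.date(2018, 3, 13), "B2H", "beta_org", "external_referral", blocks=0),
    ]


@pytest.fixture(scope="session")
def small_scenario() -> le.SyntheticConfig:
    return le.paperlike_small()


@pytest.fixture(scope="session")
def small_lab(small_scenario):
    return le.generate_lab(small_scenario)


@pytest.fixture(scope="session")
def small_bundle(small_scenario):
    cfg = RunConfig(
        scenario=small_scenario,
        exclusions=ExclusionConfig(study_years=small_scenario.years),
    )
    return run_pipeline(cfg)
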