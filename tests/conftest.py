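import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from faersig.ingest import AdverseEventReport, ReportSet
from faersig.synthetic import SyntheticConfig, generate_dataset

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_report(pid, caseid=None, pts=(), socs=(), sex=None, drug=None,
                age=None, reporter=None, country=None, event_dt="", start_dt="",
                drug_entries=None):
    """Hand-built report for small fixtures."""
    return AdverseEventReport(
        primaryid=str(pid), caseid=str(caseid if caseid is not None else pid),
        drug_entries=drug_entries or [],
        pts=set(pts), socs=set(socs), sex=sex, age_years=age,
        reporter_type=reporter, country=country,
        event_dt=event_dt, start_dt=start_dt,
        target_drugs=(drug,) if drug else (),
    )


def make_set(reports, dedup=True):
    return ReportSet(list(reports), dedup_applied=dedup)


@pytest.fixture(scope="session")
def small_config():
    return SyntheticConfig(
        n_cases=3000,
        planted_signals=(
            ("lecanemab", "Amyloid related imaging abnormality-oedema/effusion", 12.0),
            ("aducanumab", "Cerebral microhaemorrhage", 8.0),
        ),
        seed=7,
    )


@pytest.fixture(scope="session")
def small_dataset(small_config):
    return generate_dataset(small_config)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
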