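import numpy as np
import pytest

import glaufuse as gf
from glaufuse.synthetic import PAPER_STUDY, SimConfig


@pytest.fixture(scope="session")
def smap():
    return gf.default_sector_map()


@pytest.fixture(scope="session")
def normative_cohort():
    return gf.generate_normative_cohort(150, PAPER_STUDY, seed=11)


@pytest.fixture(scope="session")
def norm_db(normative_cohort):
    return gf.build_normative_db(normative_cohort)


@pytest.fixture(scope="session")
def small_sim_cfg():
    """Reduced study composition for fast end-to-end tests."""
    return SimConfig(
        n_healthy=30,
        n_glaucoma=30,
        severity_counts={
            gf.Severity.EARLY: 10,
            gf.Severity.MODERATE: 10,
            gf.Severity.ADVANCED: 10,
        },
    )


@pytest.fixture(scope="session")
def small_study(small_sim_cfg):
    return gf.generate_study(small_sim_cfg, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def make_healthy_record(subject_id="S001", seed=0, cfg=PAPER_STUDY):
    from glaufuse.synthetic import generate_healthy_record

    return generate_healthy_record(subject_id, cfg, np.random.default_rng(seed))
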