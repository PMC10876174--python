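import numpy as np
import pytest

from acnscore.cohort import (CaseRecord, MitoticCount, Outcome,
                             ReticulinCategory, ReticulinStatus)
from acnscore.reproduce import build_reference_cohort, load_fixture


@pytest.fixture(scope="session")
def fixture_tables():
    return load_fixture()


@pytest.fixture(scope="session")
def reference_cohort():
    return build_reference_cohort()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240612)


def make_case(case_id="T-1", *, retic=ReticulinCategory.INTACT, c50=0, c20=0,
              necrosis=False, vascular=False, atypical=False, capsular=False,
              extra_adrenal=False, vena_cava=False, weight=50.0, size=5.0,
              ki67=5.0, outcome=Outcome.UNKNOWN, followup=None) -> CaseRecord:
    """Fully specified case with every scoring input present."""
    return CaseRecord(
        case_id=case_id, age_months=60.0, weight_g=weight, size_cm=size,
        mitoses_per_50hpf=MitoticCount(c50, 50),
        mitoses_per_20hpf=MitoticCount(c20, 20),
        atypical_mitoses=atypical, necrosis=necrosis,
        vascular_invasion=vascular, capsular_invasion=capsular,
        extra_adrenal_extension=extra_adrenal, vena_cava_invasion=vena_cava,
        ki67_percent=ki67, reticulin=ReticulinStatus(retic),
        outcome=outcome, followup_months=followup,
    )


def random_case(rng: np.random.Generator, case_id="R-1") -> CaseRecord:
    """Random fully specified case; mitotic counts share a latent rate so
    the two denominators are coherent."""
    lam = float(rng.lognormal(-1.6, 1.9))
    c20 = int(rng.poisson(20 * lam))
    c50 = c20 + int(rng.poisson(30 * lam))
    return make_case(
        case_id,
        retic=list(ReticulinCategory)[rng.integers(4)],
        c50=c50, c20=c20,
        necrosis=bool(rng.random() < 0.5),
        vascular=bool(rng.random() < 0.5),
        atypical=bool(rng.random() < 0.5),
        capsular=bool(rng.random() < 0.5),
        extra_adrenal=bool(rng.random() < 0.3),
        vena_cava=bool(rng.random() < 0.2),
        weight=float(rng.lognormal(np.log(60), 1.4)),
        size=float(rng.lognormal(np.log(6), 0.5)),
        ki67=float(min(rng.lognormal(np.log(6), 1.0), 100.0)),
    )
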