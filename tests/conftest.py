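import numpy as np
import pytest

from tucrmir.io import HairpinRecord, PatientRecord


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def hairpin():
    """An 85-nt hairpin with 5p and 3p mature arms (miRBase-style intervals)."""
    rng = np.random.default_rng(5)
    seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=85)])
    return HairpinRecord(
        "hp-test", "clu-test", seq, [("hp-test-5p", 10, 31), ("hp-test-3p", 48, 69)]
    )


def make_patient(case_id="c1", cohort="LGG", beta=0.5, **kw):
    defaults = dict(idh1="WT", age=50.0, sex="M", os_time=365.0, event=1)
    defaults.update(kw)
    return PatientRecord(case_id=case_id, cohort=cohort, beta=beta, **defaults)


@pytest.fixture
def toy_cohort():
    """Six-case cohort with a hand-checkable survival structure."""
    return [
        make_patient("a", "LGG", 0.8, os_time=100, event=1),
        make_patient("b", "LGG", 0.7, os_time=200, event=0),
        make_patient("c", "LGG", 0.1, os_time=50, event=1),
        make_patient("d", "LGG", 0.2, os_time=150, event=1),
        make_patient("e", "GBM", 0.9, grade="IV", os_time=80, event=1),
        make_patient("f", "GBM", 0.05, grade="IV", os_time=40, event=1),
    ]
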