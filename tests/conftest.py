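import datetime as dt

import numpy as np
import pytest

from egfrkit import Cohort, PatientRecord, Sex


def make_record(i: int, rng: np.random.Generator | None = None,
                **overrides) -> PatientRecord:
    """A physiologically plausible record, optionally randomized."""
    if rng is None:
        kw = dict(age=55.0, sex=Sex.FEMALE if i % 2 else Sex.MALE,
                  scr=1.2, scys=1.3, bmi=24.0, bun=18.0, alb=4.0,
                  ua=6.5, hgb=12.5, mgfr=70.0,
                  visit_date=dt.date(2013, 1, 1) + dt.timedelta(days=30 * i))
    else:
        kw = dict(
            age=float(rng.uniform(18, 90)),
            sex=Sex.MALE if rng.random() < 0.5 else Sex.FEMALE,
            scr=float(rng.lognormal(0.3, 0.5)),
            scys=float(rng.lognormal(0.3, 0.5)),
            bmi=float(rng.normal(24, 3.5)),
            bun=float(rng.lognormal(3.0, 0.4)),
            alb=float(rng.normal(3.9, 0.5)),
            ua=float(rng.normal(6.7, 2.0)),
            hgb=float(rng.normal(12.3, 2.3)),
            mgfr=float(rng.uniform(10, 150)),
            visit_date=dt.date(2013, 1, 1) + dt.timedelta(days=int(rng.integers(0, 1200))))
    kw.update(overrides)
    return PatientRecord(subject_id=f"p{i:03d}", **kw)


@pytest.fixture
def small_cohort() -> Cohort:
    return Cohort([make_record(i) for i in range(6)], label="unit")


@pytest.fixture
def random_cohort() -> Cohort:
    rng = np.random.default_rng(2024)
    return Cohort([make_record(i, rng) for i in range(100)], label="random")
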