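import math

import numpy as np
import pytest

from uopval import PatientCovariates, SyntheticEncounter

#: Reference-cohort median covariates (hematocrit already as a fraction).
MEDIAN_COVARIATES = dict(
    weight_kg=6.1, hct_fraction=0.43, ph=7.32, cpb_minutes=95.0, vis=7.0,
    cvp_mmhg=10.0,
)


def log_domain_volume(w, hct, ph, cpb, vis, cvp):
    """Independent oracle: the prediction formula evaluated as a sum of
    exponent-weighted logarithms, exponentiated once at the end."""
    inner = math.log(4 * w + 7) - math.log(w + 90) + math.log(558) + math.log(1 - hct)
    return math.exp(
        math.log(6.06) + 1.01 * inner + 0.07 * math.log(ph)
        - 0.01 * math.log(cpb) - 0.08 * math.log(vis) - 0.04 * math.log(cvp)
    )


@pytest.fixture
def median_covariates():
    return PatientCovariates(**MEDIAN_COVARIATES)


@pytest.fixture
def make_encounter():
    """Factory for hand-built encounters with sensible defaults."""
    counter = iter(range(10_000))

    def _make(
        encounter_id=None, patient_id=None, observed=2.59, age_days=172.0,
        stat_category=2, flags=None, **cov_overrides,
    ):
        i = next(counter)
        cov = dict(MEDIAN_COVARIATES, **cov_overrides)
        all_flags = dict.fromkeys(
            ("preop_krt", "reop_32h", "ecmo_32h", "krt_32h",
             "catheter_lt_32h", "missing_data"), False,
        )
        all_flags.update(flags or {})
        return SyntheticEncounter(
            encounter_id=encounter_id or f"E{i:04d}",
            patient_id=patient_id or f"P{i:04d}",
            covariates=PatientCovariates(**cov),
            age_days=age_days,
            stat_category=stat_category,
            observed_uop_ml_kg_hr=observed,
            flags=all_flags,
        )

    return _make


def random_valid_covariates(rng: np.random.Generator, n: int):
    """Covariate draws spanning the model's valid domain."""
    return dict(
        weight_kg=rng.uniform(1.5, 80.0, n),
        hct_fraction=rng.uniform(0.1, 0.7, n),
        ph=rng.uniform(6.8, 7.7, n),
        cpb_minutes=rng.uniform(20.0, 400.0, n),
        vis=rng.uniform(0.2, 60.0, n),
        cvp_mmhg=rng.uniform(1.0, 30.0, n),
    )
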