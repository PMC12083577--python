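import numpy as np
import pytest

import movereserve as mr


@pytest.fixture(scope="session")
def small_cohort():
    """A small simulated cohort shared by read-only tests."""
    cfg = mr.SimulationConfig(n_subjects=8, n_days=5, seed=42)
    mats, cov, truth = mr.simulate_cohort(cfg)
    clean, report = mr.preprocess_cohort(mats)
    cov = cov[cov.subject_id.isin([m.subject_id for m in clean])].reset_index(drop=True)
    return {"raw": mats, "clean": clean, "covariates": cov,
            "truth": truth, "report": report, "config": cfg}


@pytest.fixture()
def rng():
    return np.random.default_rng(20260926)


def constant_matrix(value=7.0, n_days=3, subject_id="C0"):
    """A subject whose every minute equals ``value`` (full wear)."""
    counts = np.full((n_days, 1440), float(value))
    days = [f"2023-03-{6 + d:02d}" for d in range(n_days)]
    return mr.SubjectDayMatrix(subject_id=subject_id, days=days, counts=counts)
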