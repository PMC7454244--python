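"""Shared fixtures: the scaled virtual-trial runs used by several tests.

The 400-patient, seed-1 cohort and its three-arm trial are the scaled
study conditions; they are expensive (minutes), so they are computed
once per session and shared between the acceptance tests and the
trajectory-level property tests.
"""

from __future__ import annotations

import pytest

from qspvct.trial_engine import default_arms, run_trial
from qspvct.virtual_cohort import generate_cohort, with_delta_axis

ACCEPT_N = 400
ACCEPT_SEED = 1


@pytest.fixture(scope="session")
def cohort400():
    """400-VP LHS cohort with packaged defaults (seed 1), screened."""
    return generate_cohort(n=ACCEPT_N, seed=ACCEPT_SEED)


@pytest.fixture(scope="session")
def trial400(cohort400):
    """Three-arm trial over the plausible patients of cohort400."""
    return run_trial(cohort400)


@pytest.fixture(scope="session")
def delta_trial400(cohort400):
    """Atezolizumab arm rerun with the delta PD-L2 weight sampled as an
    added LHS axis over the same patients (paired design)."""
    cohort = with_delta_axis(cohort400, seed=ACCEPT_SEED + 1)
    arms = [a for a in default_arms() if a.arm_id == "atezolizumab_mono"]
    return cohort, run_trial(cohort, arms)
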