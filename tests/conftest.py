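"""Shared fixtures: phantoms, dose matrices and solved plans.

Expensive artifacts (full prioritized solves, the two-arm cohort) are
session-scoped so every test that needs a realistic plan reuses the same
computation.  Problem sizes here are the package's desk-scale study
conditions: the default 6 mm planar thorax grid, 15 equi-angular beams
for planning runs and 7 beams for the degraded comparator arm.
"""

from __future__ import annotations

import numpy as np
import pytest

import prioplan as pp

#: solver settings used for the heavier planning fixtures
FAST_OPTS = pp.SolverOptions(tol_rel=1e-3, maxiter=40)

#: phantom constructed so the full wishlist plan is acceptable at 66 Gy
FEASIBLE_66_CONFIG = pp.PhantomConfig()

#: mediastinal tumor abutting the spinal cord: acceptable at 45 Gy only
CORD_LIMITED_CONFIG = pp.PhantomConfig(tumor_radius=14.0, tumor_center=(14.0, -44.0, 0.0))


@pytest.fixture(scope="session")
def default_phantom() -> pp.StructureSet:
    return pp.build_phantom(FEASIBLE_66_CONFIG)


@pytest.fixture(scope="session")
def default_dij(default_phantom):
    bs = pp.make_beamset(default_phantom, n_beams=15)
    return pp.compute_dose_influence(default_phantom, bs)


@pytest.fixture(scope="session")
def wishlist_template() -> pp.Wishlist:
    return pp.nsclc_wishlist()


@pytest.fixture(scope="session")
def solved_default(default_phantom, default_dij, wishlist_template):
    """Full prioritized solve of the default phantom at 66 Gy."""
    rx = pp.ladder_prescription(66.0)
    plan, report = pp.prioritized_optimize(
        default_dij, wishlist_template, default_phantom, rx, FAST_OPTS
    )
    return plan, report, rx


@pytest.fixture(scope="session")
def cohort_members():
    return pp.generate_cohort(pp.CohortSpec(n_patients=10, seed=7))


@pytest.fixture(scope="session")
def cohort_solved(cohort_members, wishlist_template):
    """Both-arm plans for the 10-patient cohort (reused by several tests).

    Returns a list of dicts with the phantom, both metric reports, the
    wishlist-arm plan/acceptability and hard-constraint checks.
    """
    out = []
    for m in cohort_members:
        ss = m.build()
        plan_b, rep_b, acc_b = pp.plan_member(m, "wishlist", n_beams=15, opts=FAST_OPTS)
        _, rep_a, _ = pp.plan_member(m, "baseline", n_beams=7, opts=FAST_OPTS)
        checks = pp.check_hard_constraints(plan_b, pp.nsclc_wishlist(), ss, m.prescription)
        out.append({
            "member": m,
            "phantom": ss,
            "plan": plan_b,
            "baseline_report": rep_a,
            "wishlist_report": rep_b,
            "acceptability": acc_b,
            "hard_checks": checks,
        })
    return out
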