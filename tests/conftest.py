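"""Shared fixtures.

The expensive artifacts — the synthetic five-specimen curve groups, the
sequential calibration over them, and the four dogbone tear-pattern solves —
are session-scoped and shared between the unit tests and the acceptance
suite so each is computed once.
"""

import numpy as np
import pytest

from meniscus_cdm import constitutive as const
from meniscus_cdm import curve_fitting as cf
from meniscus_cdm import fe_model as fem
from meniscus_cdm import synthetic_data as sd

N_PER_GROUP = 5
GROUP_SEED = 7
CURVE_SEED0 = 200


@pytest.fixture(scope="session")
def synthetic_groups():
    """Five seeded model-based curves per orientation, with ground truth."""
    rng = np.random.default_rng(GROUP_SEED)
    curves = {"longitudinal": [], "transverse": []}
    truths = {"longitudinal": [], "transverse": []}
    for orientation in curves:
        for i in range(N_PER_GROUP):
            params, dp = sd.sample_ground_truth(orientation, rng)
            spec = sd.default_spec(orientation, seed=CURVE_SEED0 + i)
            curve, truth = sd.generate_curve_model_based(params, dp, spec)
            curves[orientation].append(curve)
            truths[orientation].append(truth)
    return curves, truths


@pytest.fixture(scope="session")
def elastic_fit(synthetic_groups):
    curves, _ = synthetic_groups
    return cf.fit_elastic(curves)


@pytest.fixture(scope="session")
def damage_fits(synthetic_groups, elastic_fit):
    """Damage fits for every curve under both criteria."""
    curves, _ = synthetic_groups
    out = {}
    for criterion in ("von_mises", "max_normal_strain"):
        for orientation, group in curves.items():
            results = []
            for i, curve in enumerate(group):
                results.append(cf.fit_damage(
                    curve, elastic_fit.params_for(orientation, i), criterion,
                    budget=200))
            out[(orientation, criterion)] = results
    return out


TEAR_RUNS = {
    ("longitudinal", "von_mises"): (1.20, 20),
    ("longitudinal", "max_normal_strain"): (1.20, 20),
    ("transverse", "von_mises"): (1.50, 25),
    ("transverse", "max_normal_strain"): (1.50, 25),
}


@pytest.fixture(scope="session")
def tear_solutions():
    """Dogbone solves with the fitted-average parameters, all four groups."""
    sols = {}
    for (orientation, criterion), (target, steps) in TEAR_RUNS.items():
        mesh = fem.build_dogbone_mesh(fem.default_geometry(orientation),
                                      orientation, (10, 8, 2),
                                      refine_factor=2)
        dp = const.AVERAGE_DAMAGE[(orientation, criterion)]
        sols[(orientation, criterion)] = fem.solve_quasistatic(
            mesh, const.AVERAGE_ELASTIC, dp, target, steps)
    return sols


@pytest.fixture(scope="session")
def small_dogbone_mesh():
    return fem.build_dogbone_mesh(fem.LONGITUDINAL_GEOMETRY, "longitudinal",
                                  (10, 8, 2), refine_factor=1)
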