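"""Shared fixtures: small synthetic patients and a rule-labelled training cohort.

All fixtures are generated programmatically with fixed seeds; the heavier
cohort-level fixtures are session-scoped so the suite builds them once.
"""

import numpy as np
import pytest

from ocugaze.eye_model import (EyeModel, StructureCloud, TumorSpec,
                               build_parametric_eye, place_tumor, synthesize_cohort)
from ocugaze.fixation import clamp_to_disk
from ocugaze.geometry import PLANE_DISTANCE
from ocugaze.ml_gaze import extract_features
from ocugaze.sampler import EvaluationSettings


@pytest.fixture(scope="session")
def small_patient():
    """One synthetic patient at reduced point density."""
    model = build_parametric_eye(globe_radius=12.0, seed=3, density=0.5)
    spec = TumorSpec(height=5.0, base_area=180.0, latitude=-45.0, longitude=120.0)
    return place_tumor(model, spec, n_points=250, seed=4)


@pytest.fixture(scope="session")
def coarse_settings():
    """Evaluation settings on a coarsened dose grid for fast candidate loops."""
    return EvaluationSettings(grid_shape=(40, 40, 40), grid_spacing=0.885)


def rule_label(model: EyeModel) -> np.ndarray:
    """The learnable geometric labelling rule of the training cohort: fixate
    opposite the tumor's transverse position, farther out for anterior targets."""
    base = model.to_base()
    com = base.target_com() - base.globe_centre
    scale = 3.5 * (1.0 + 0.4 * (com[2] / model.globe_radius))
    fx = clamp_to_disk(-scale * com[0], -scale * com[1])
    return np.array([fx.x, fx.y])


@pytest.fixture(scope="session")
def rule_cohort():
    """200-patient cohort with rule-based fixation labels: (features, labels)."""
    cohort = synthesize_cohort(200, seed=42, density=0.3, tumor_points=150)
    X = np.array([extract_features(m).values for m, _ in cohort])
    Y = np.array([rule_label(m) for m, _ in cohort])
    return X, Y


@pytest.fixture(scope="session")
def rule_loo(rule_cohort):
    """Leave-one-out report on the rule-labelled cohort (computed once)."""
    from ocugaze.ml_gaze import loo_evaluate

    X, Y = rule_cohort
    return loo_evaluate(X, Y, seed=5)


@pytest.fixture
def uniform_grid():
    """Dose grid factory: uniform dose at a given level on every OAR mask."""
    from ocugaze.dose import DoseGrid

    def make(level: float, n: int = 12, prescription: float = 60.0) -> DoseGrid:
        rng = np.random.default_rng(0)
        grid = DoseGrid(shape=(n, n, n), spacing=1.0, origin=np.zeros(3),
                        dose=np.full((n, n, n), float(level)),
                        prescription=prescription)
        for oar in ("macula", "optic_disc", "cornea", "retina",
                    "ciliary_body", "lens", "target", "globe"):
            mask = np.zeros((n, n, n), dtype=bool)
            flat = rng.choice(n ** 3, size=30, replace=False)
            mask.ravel()[flat] = True
            grid.masks[oar] = mask
        return grid

    return make
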