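"""Shared fixtures: small, fast synthetic cohorts and fitted models."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import lesionload as ll


def small_config(**overrides) -> ll.SimulationConfig:
    """Minutes-scale grid: 6 tracts of ~96 skeleton voxels each."""
    defaults = dict(
        grid_shape=(24, 24, 12),
        n_tracts=6,
        skeleton_fraction=0.12,
        n_controls=20,
        n_patients=18,
        lesion_specs=[
            ll.LesionSpec(tract=2, direction="low", effect_size=4.0, extent=30),
            ll.LesionSpec(tract=5, direction="high", effect_size=4.0, extent=30),
        ],
        # total designed burden is 8x smaller than the default cohort's,
        # so the outcome slopes scale up by 8 to keep the label split
        tmt_burden_slope=0.16,
        bds_burden_slope=-0.0096,
        seed=0,
    )
    defaults.update(overrides)
    return ll.SimulationConfig(**defaults)


@pytest.fixture(scope="session")
def small_bundle() -> ll.CohortBundle:
    return ll.generate_cohort(small_config())


@pytest.fixture(scope="session")
def small_model(small_bundle):
    """Normative model fitted on the reference half of the small cohort."""
    controls = small_bundle.covariates[small_bundle.covariates.group == "control"]
    ref, normal = ll.split_controls(controls, seed=3)
    model = ll.build_normative_model(
        small_bundle.image_matrix(list(ref.subject_id)), ref, B=50, seed=4
    )
    return model, ref, normal


@pytest.fixture(scope="session")
def separable_features():
    """Linearly separable toy features with a wide margin."""
    rng = np.random.default_rng(7)
    n = 24
    y = np.r_[np.ones(n // 2), -np.ones(n // 2)].astype(int)
    X = pd.DataFrame(
        rng.standard_normal((n, 4)) * 0.3,
        columns=[f"f{i}" for i in range(4)],
        index=[f"s{i:02d}" for i in range(n)],
    )
    X["f0"] += 5.0 * y
    return X, pd.Series(y, index=X.index)
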