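"""Shared fixtures: small designs, spectral models, rendered scenes, tables.

Expensive artefacts (rendered campaigns, trained models) are session-scoped
so independent tests can share them.
"""

from __future__ import annotations

import numpy as np
import pytest

from jamspec import (
    AcquisitionDesign,
    build_feature_tables,
    calibrate_capture,
    default_spectral_model,
    enumerate_design,
    render_scene,
)


@pytest.fixture(scope="session")
def tiny_design() -> AcquisitionDesign:
    """2 cultivars x 3 levels x 1 view at 64x64: a desk-scale campaign."""
    return AcquisitionDesign(
        cultivars=("gala", "aport"),
        sugar_levels=(30.0, 50.0, 70.0),
        views_per_thickness={1.0: 1},
        spatial_size=(64, 64),
    )


@pytest.fixture(scope="session")
def small_design() -> AcquisitionDesign:
    """4 cultivars x 6 levels x 1 view at 48x48 for model-recovery tests."""
    return AcquisitionDesign(
        cultivars=("gala", "aport", "idared", "golden"),
        sugar_levels=(25.0, 35.0, 45.0, 55.0, 65.0, 75.0),
        views_per_thickness={1.0: 1},
        spatial_size=(48, 48),
    )


@pytest.fixture(scope="session")
def noiseless_model(tiny_design):
    return default_spectral_model(
        tiny_design.wavelengths, tiny_design.cultivars, noise_sd=0.0
    )


@pytest.fixture(scope="session")
def noiseless_capture(tiny_design, noiseless_model):
    meta = enumerate_design(tiny_design)[0]
    return render_scene(meta, noiseless_model, tiny_design, rng_seed=42)


@pytest.fixture(scope="session")
def noiseless_cube(noiseless_capture):
    return calibrate_capture(noiseless_capture)


@pytest.fixture(scope="session")
def small_tables(small_design):
    """Noiseless g=1 and g=2 tables over the small campaign (24 scenes)."""
    return build_feature_tables(small_design, grids=(1, 2), seed=5, noise_sd=0.0)


@pytest.fixture(scope="session")
def noisy_tables(small_design):
    """Moderate-noise g=2 table over the small campaign."""
    return build_feature_tables(small_design, grids=(2,), seed=5, noise_sd=0.01)


def holdout_one_each(design: AcquisitionDesign) -> dict:
    """1 test + 1 val concentration per cultivar for small designs."""
    from jamspec import rotating_holdout_map

    return rotating_holdout_map(
        list(design.cultivars),
        list(design.sugar_levels),
        n_test_cells=len(design.cultivars),
        n_val_cells=len(design.cultivars),
    )


@pytest.fixture(scope="session")
def recovery_design() -> AcquisitionDesign:
    """4 cultivars x 11 levels x 2 views at 48x48: dense enough in sugar
    levels that held-out concentrations are bracketed by training ones."""
    return AcquisitionDesign(
        cultivars=("gala", "aport", "idared", "golden"),
        views_per_thickness={1.0: 2},
        spatial_size=(48, 48),
    )


def interior_holdout(design: AcquisitionDesign) -> dict:
    """1 interior test + 1 interior val level per cultivar (staggered)."""
    levels = [float(v) for v in design.sugar_levels]
    return {
        c: {"test": [levels[2 + 2 * i]], "val": [levels[3 + 2 * i]]}
        for i, c in enumerate(sorted(design.cultivars))
    }


@pytest.fixture(scope="session")
def recovery_tables_clean(recovery_design):
    return build_feature_tables(recovery_design, grids=(3,), seed=5, noise_sd=0.0)


@pytest.fixture(scope="session")
def recovery_tables_noisy(recovery_design):
    return build_feature_tables(recovery_design, grids=(3,), seed=5, noise_sd=0.01)


@pytest.fixture(scope="session")
def recovery_split_clean(recovery_design, recovery_tables_clean):
    from jamspec import split_by_concentration

    return split_by_concentration(
        recovery_tables_clean[3], held_out_map=interior_holdout(recovery_design)
    )


@pytest.fixture(scope="session")
def recovery_split_noisy(recovery_design, recovery_tables_noisy):
    from jamspec import split_by_concentration

    return split_by_concentration(
        recovery_tables_noisy[3], held_out_map=interior_holdout(recovery_design)
    )


@pytest.fixture(scope="session")
def small_split(small_design, small_tables):
    from jamspec import split_by_concentration

    return split_by_concentration(
        small_tables[2], held_out_map=holdout_one_each(small_design)
    )
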