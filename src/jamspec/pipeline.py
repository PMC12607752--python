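"""End-to-end driver: design -> rendered scenes -> feature tables.

Scenes are rendered and consumed one at a time (a full campaign of cubes
would not fit in memory); the segmentation products (reference, mask, ROI)
are computed once per scene and shared across grid configurations.

RGB feature tables are derived from the hyperspectral ones: the three
broadband channel means of a unit-norm mean spectrum, re-normalised, equal
the unit-norm channel means of the raw mean spectrum (channel averaging is
linear), so no second pass over the pixels is needed.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .calibrate import calibrate_capture
from .dataset import METADATA_COLUMNS, build_table
from .design import AcquisitionDesign, enumerate_design
from .rgb import rgb_band_means
from .scene import render_scene
from .segment import (
    DEFAULT_MARGIN,
    DEFAULT_MIN_PIXELS,
    DEFAULT_SAM_THRESHOLD,
    apply_margin,
    cell_feature,
    pick_reference,
    roi_from_mask,
    sam_mask,
    subdivide,
)
from .spectra import SpectralModel, default_spectral_model


def build_feature_tables(
    design: AcquisitionDesign,
    model: SpectralModel | None = None,
    grids: tuple[int, ...] = (1, 2, 3, 4, 5),
    seed: int = 0,
    noise_sd: float | None = None,
    sam_threshold: float = DEFAULT_SAM_THRESHOLD,
    margin: float = DEFAULT_MARGIN,
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> dict[int, pd.DataFrame]:
    """Simulate the whole campaign and return one table per grid size."""
    if model is None:
        model = default_spectral_model(
            design.wavelengths,
            design.cultivars,
            noise_sd=0.01 if noise_sd is None else noise_sd,
        )
    elif noise_sd is not None and noise_sd != model.noise_sd:
        raise ValueError("pass noise_sd either via the model or the argument, not both")

    ss = np.random.SeedSequence(seed)
    captures = enumerate_design(design)
    children = ss.spawn(len(captures))
    per_grid: dict[int, list] = {g: [] for g in grids}
    for meta, child in zip(captures, children):
        capture = render_scene(meta, model, design, child)
        cube = calibrate_capture(capture)
        reference = pick_reference(cube)
        mask = sam_mask(cube, reference, sam_threshold)
        roi = apply_margin(roi_from_mask(mask), margin)
        for g in grids:
            cells = subdivide(roi, g)
            feats = []
            for k, cell in enumerate(cells):
                f = cell_feature(
                    cube, mask, cell, g, (k // g, k % g), min_pixels=min_pixels
                )
                if f is not None:
                    feats.append(f)
            per_grid[g].append((meta, feats))
    return {g: build_table(entries) for g, entries in per_grid.items()}


def rgb_table_from_hsi(table: pd.DataFrame, wavelengths: np.ndarray) -> pd.DataFrame:
    """Project a hyperspectral feature table to unit-norm 3-channel features."""
    bands = [c for c in table.columns if c.startswith("band_")]
    if len(bands) != len(wavelengths):
        raise ValueError("table band count does not match wavelength axis")
    spectra = table[bands].to_numpy()
    rgb = rgb_band_means(spectra, wavelengths)
    rgb = rgb / np.linalg.norm(rgb, axis=1, keepdims=True)
    out = pd.DataFrame(rgb, columns=["band_0001", "band_0002", "band_0003"],
                       index=table.index)
    return pd.concat([out, table[METADATA_COLUMNS]], axis=1)
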