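"""Render raw sensor captures of jam-on-dish scenes.

A scene is an ellipse of jam pixels centred (with seeded jitter) on a bright
dish background.  The renderer works backwards from reflectance: it first
draws the per-pixel reflectance cube, then synthesises dark (D) and white (W)
reference frames with smooth spatial structure and converts to raw intensity
via I = D + (W - D) * R, so that the standard white/dark calibration recovers
the underlying reflectance to machine precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import AcquisitionDesign, CaptureMeta
from .spectra import SpectralModel


class GeometryError(ValueError):
    """Frame too small to place a jam region."""


@dataclass
class RawCapture:
    """One raw capture: intensity cube plus its reference frames.

    ``I`` is (height, width, bands) in sensor counts; ``D`` and ``W`` are the
    per-pixel dark and white reference frames with the same shape.  The
    simulator guarantees W > D everywhere.  ``jam_truth`` is the ground-truth
    jam mask (simulation-only, unavailable for real captures).
    """

    I: np.ndarray
    D: np.ndarray
    W: np.ndarray
    meta: CaptureMeta
    wavelengths: np.ndarray
    jam_truth: np.ndarray | None = None


def _halogen_gain(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth positive illumination x sensor gain curve (sensor counts)."""
    lam = np.asarray(wavelengths, dtype=float)
    return 200.0 + 800.0 * np.exp(-(((lam - 780.0) / 260.0) ** 2))


def ellipse_mask(
    shape: tuple[int, int], rng: np.random.Generator
) -> np.ndarray:
    """Seeded jam ellipse covering >= 10% of the frame."""
    h, w = shape
    if h < 8 or w < 8:
        raise GeometryError(f"frame {h}x{w} too small to place a jam region")
    cy = (0.5 + rng.uniform(-0.04, 0.04)) * h
    cx = (0.5 + rng.uniform(-0.04, 0.04)) * w
    ry = (0.32 + rng.uniform(0.0, 0.06)) * h
    rx = (0.34 + rng.uniform(0.0, 0.06)) * w
    yy, xx = np.mgrid[0:h, 0:w]
    mask = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    if mask.mean() < 0.10:  # ellipse parameters above make this unreachable
        raise GeometryError("jam region covers less than 10% of the frame")
    return mask


def render_scene(
    meta: CaptureMeta,
    model: SpectralModel,
    design: AcquisitionDesign,
    rng_seed: int | np.random.SeedSequence,
) -> RawCapture:
    """Render the raw capture for one design entry.

    Jam pixels draw independent noisy spectra from the spectral model;
    background pixels draw around the dish template with the same noise
    scale.  Bit-identical for identical (meta, model, design, seed).
    """
    if meta.cultivar not in design.cultivars:
        raise ValueError(f"capture cultivar {meta.cultivar!r} not in design")
    rng = np.random.default_rng(rng_seed)
    h, w = design.spatial_size
    lam = model.wavelengths
    n_bands = lam.shape[0]

    jam = ellipse_mask((h, w), rng)
    n_jam = int(jam.sum())

    R = np.empty((h, w, n_bands), dtype=np.float64)
    bg = np.asarray(model.background_spectrum, dtype=np.float64)
    clean = model.mean_spectrum(meta.cultivar, meta.sugar_pct)
    if model.noise_sd > 0:
        R[~jam] = np.clip(
            bg + rng.normal(0.0, model.noise_sd, size=(h * w - n_jam, n_bands)),
            0.0,
            1.0,
        )
        R[jam] = np.clip(
            clean + rng.normal(0.0, model.noise_sd, size=(n_jam, n_bands)),
            0.0,
            1.0,
        )
    else:
        R[~jam] = bg
        R[jam] = clean

    # Smooth spatial structure in the references: a gentle plane in the dark
    # frame and a radial vignette in the white frame, so calibration has
    # genuine per-pixel work to do.
    yy, xx = np.mgrid[0:h, 0:w]
    plane = (yy / max(h - 1, 1) + xx / max(w - 1, 1)) / 2.0
    r2 = ((yy - h / 2) / (h / 2)) ** 2 + ((xx - w / 2) / (w / 2)) ** 2
    vignette = 1.0 - 0.08 * r2

    D = 100.0 + 10.0 * plane[:, :, None] + np.zeros((1, 1, n_bands))
    W = D + _halogen_gain(lam)[None, None, :] * vignette[:, :, None]
    I = D + (W - D) * R
    return RawCapture(
        I=I, D=D, W=W, meta=meta, wavelengths=lam.copy(), jam_truth=jam
    )
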