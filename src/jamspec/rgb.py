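"""Broadband RGB rendition of a reflectance cube.

A camera-accurate RGB image is unavailable for simulated scenes, so RGB is
derived from the hyperspectral cube by boxcar means over three broad visible
windows — blue 400-500 nm, green 500-600 nm, red 600-700 nm — mirroring the
three wide visible channels an RGB sensor integrates.  Everything above
700 nm is discarded, which is precisely the information gap the
hyperspectral-vs-RGB comparison probes.
"""

from __future__ import annotations

import numpy as np

RGB_WINDOWS_NM = {"B": (400.0, 500.0), "G": (500.0, 600.0), "R": (600.0, 700.0)}


class CoverageError(ValueError):
    """Wavelength axis does not cover one of the RGB windows."""


def rgb_band_means(spectra: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """Mean reflectance per RGB window along the last axis.

    Works on any (..., bands) array; returns (..., 3) ordered B, G, R.
    """
    lam = np.asarray(wavelengths, dtype=float)
    channels = []
    for name, (lo, hi) in RGB_WINDOWS_NM.items():
        inside = (lam >= lo) & (lam < hi)
        if not inside.any():
            raise CoverageError(
                f"no bands inside the {name} window {lo:g}-{hi:g} nm"
            )
        channels.append(np.asarray(spectra)[..., inside].mean(axis=-1))
    return np.stack(channels, axis=-1)


def render_rgb(cube: np.ndarray, wavelengths: np.ndarray) -> np.ndarray:
    """3-channel (B, G, R) image of a (h, w, bands) reflectance cube."""
    cube = np.asarray(cube)
    if cube.ndim != 3:
        raise ValueError("cube must be (height, width, bands)")
    if len(wavelengths) != cube.shape[-1]:
        raise ValueError("wavelength list length must match band count")
    return rgb_band_means(cube, wavelengths)
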