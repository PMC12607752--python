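"""White/dark reference radiometric calibration.

Raw sensor counts I are converted to unitless reflectance with the standard
two-point correction

    R = (I - D) / (W - D)

where D is the dark frame (shutter closed) and W the white reference (here:
the bare dish).  The correction removes the sensor dark current and the
joint illumination x gain spectrum.  Pixels whose white-dark contrast falls
below ``eps`` cannot be calibrated (an imperfect white reference shows up
exactly here, e.g. overexposure rendering bright areas dark) and are flagged
invalid rather than silently producing garbage.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .design import CaptureMeta
from .scene import RawCapture


@dataclass
class ReflectanceCube:
    """Calibrated reflectance with its wavelength axis and capture metadata.

    ``invalid`` marks pixels where the white-dark contrast was too small for
    a meaningful ratio at one or more bands; downstream segmentation excludes
    them.
    """

    R: np.ndarray
    wavelengths: np.ndarray
    meta: CaptureMeta | None = None
    invalid: np.ndarray | None = None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.R.shape


def calibrate(
    I: np.ndarray,
    D: np.ndarray,
    W: np.ndarray,
    eps: float = 1e-6,
    clip_max: float | None = 2.0,
    wavelengths: np.ndarray | None = None,
    meta: CaptureMeta | None = None,
) -> ReflectanceCube:
    """Apply the white/dark correction to a raw cube.

    ``D`` and ``W`` may be full per-pixel frames or single spectra (length =
    band count) broadcast spatially.  Reflectance is clipped to
    ``[0, clip_max]`` (``clip_max=None`` disables the upper clip; values a
    little above 1 are legitimate where the sample outshines the dish).
    """
    I = np.asarray(I, dtype=np.float64)
    D = np.asarray(D, dtype=np.float64)
    W = np.asarray(W, dtype=np.float64)
    if eps <= 0:
        raise ValueError("eps must be positive")
    for name, ref in (("D", D), ("W", W)):
        if ref.shape != I.shape and ref.shape != I.shape[-1:]:
            raise ValueError(
                f"{name} shape {ref.shape} incompatible with cube {I.shape}"
            )

    denom = W - D
    bad = denom <= eps
    R = (I - D) / np.where(bad, 1.0, denom)
    R = np.where(np.broadcast_to(bad, R.shape), 0.0, R)
    R = np.clip(R, 0.0, clip_max) if clip_max is not None else np.maximum(R, 0.0)

    invalid = np.broadcast_to(bad, I.shape).any(axis=-1) if I.ndim == 3 else None
    return ReflectanceCube(R=R, wavelengths=wavelengths, meta=meta, invalid=invalid)


def calibrate_capture(
    capture: RawCapture, eps: float = 1e-6, clip_max: float | None = 2.0
) -> ReflectanceCube:
    """Calibrate a :class:`RawCapture` using its own reference frames."""
    return calibrate(
        capture.I,
        capture.D,
        capture.W,
        eps=eps,
        clip_max=clip_max,
        wavelengths=capture.wavelengths,
        meta=capture.meta,
    )
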