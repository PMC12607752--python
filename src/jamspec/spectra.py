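"""Parametric reflectance model for simulated jam scenes.

Real apple-jam reflectance in the VNIR range shares a common shape across
cultivars: a pigment-absorption dip in the 400-500 nm window, a rise through
the red edge, and elevated reflectance with broad peaks in the 700-900 nm
plateau.  Cultivars differ in overall brightness and in the depth/height of
those features.  The simulator reproduces exactly that structure:

* a per-cultivar smooth baseline template with one local minimum inside
  400-500 nm and peaks inside 700-900 nm, values in [0, 1];
* an additive, compactly supported, smooth "sugar bump" over a configurable
  NIR window whose amplitude scales linearly with sugar % w/w — the simplest
  strictly monotone, recoverable signal consistent with the shared shapes;
* i.i.d. Gaussian per-band sensor noise of scale ``noise_sd``;
* a bright, nearly flat dish background template.

Dissolved sugar in a real product perturbs many overtone bands nonlinearly;
this model is deliberately the minimal monotone stand-in, not a radiative
transfer model.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np


class UnknownCultivarError(KeyError):
    """Requested cultivar has no template in the spectral model."""


@dataclass(frozen=True)
class SugarEffect:
    """Monotone additive perturbation of reflectance with sugar content.

    The perturbation is ``direction * magnitude * (sugar_pct / 100) * w(λ)``
    with ``w`` a raised-cosine window supported on
    ``(window_nm[0], window_nm[1])`` — smooth, compact, and strictly monotone
    in sugar at every interior band of the window.
    """

    window_nm: tuple[float, float] = (750.0, 900.0)
    magnitude: float = 0.25
    direction: int = +1

    def weights(self, wavelengths: np.ndarray) -> np.ndarray:
        lo, hi = self.window_nm
        w = np.zeros_like(wavelengths, dtype=float)
        inside = (wavelengths > lo) & (wavelengths < hi)
        phase = (wavelengths[inside] - lo) / (hi - lo)
        w[inside] = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
        return w

    def delta(self, wavelengths: np.ndarray, sugar_pct: float) -> np.ndarray:
        return self.direction * self.magnitude * (sugar_pct / 100.0) * self.weights(
            wavelengths
        )


@dataclass(frozen=True)
class SpectralModel:
    """Cultivar reflectance templates plus sugar effect, noise and background."""

    wavelengths: np.ndarray
    cultivar_baselines: dict[str, np.ndarray]
    sugar_effect: SugarEffect = field(default_factory=SugarEffect)
    noise_sd: float = 0.01
    background_spectrum: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.wavelengths)
        for name, tpl in self.cultivar_baselines.items():
            if tpl.shape != (n,):
                raise ValueError(f"baseline for {name!r} has wrong length")
        if self.background_spectrum is None:
            object.__setattr__(
                self, "background_spectrum", dish_background(self.wavelengths)
            )

    def baseline(self, cultivar: str) -> np.ndarray:
        try:
            return self.cultivar_baselines[cultivar]
        except KeyError:
            raise UnknownCultivarError(
                f"cultivar {cultivar!r} not in spectral model "
                f"(known: {sorted(self.cultivar_baselines)})"
            ) from None

    def mean_spectrum(self, cultivar: str, sugar_pct: float) -> np.ndarray:
        """Noise-free jam reflectance for a cultivar at a sugar level."""
        if not 0.0 < sugar_pct < 100.0:
            raise ValueError("sugar_pct must lie in (0, 100)")
        spec = self.baseline(cultivar) + self.sugar_effect.delta(
            self.wavelengths, sugar_pct
        )
        return np.clip(spec, 0.0, 1.0)


def _cultivar_params(name: str) -> np.ndarray:
    """Deterministic per-cultivar shape parameters derived from the name."""
    seed = zlib.crc32(name.encode("utf-8")) & 0x7FFFFFFF
    return np.random.default_rng(seed).uniform(size=6)


def cultivar_baseline(name: str, wavelengths: np.ndarray) -> np.ndarray:
    """Smooth VNIR reflectance template for one cultivar.

    Built from four components: a brightness floor, a sigmoidal red-edge
    rise, a Gaussian absorption dip near 450 nm, and two Gaussian NIR peaks
    near 760 and 870 nm.  Parameter ranges keep every template inside
    [0.02, 0.98] with visible headroom for the sugar bump.
    """
    u = _cultivar_params(name)
    floor = 0.20 + 0.10 * u[0]
    rise = 0.28 + 0.10 * u[1]
    dip_depth = 0.12 + 0.06 * u[2]
    dip_center = 440.0 + 20.0 * u[3]
    p1 = 0.05 + 0.05 * u[4]
    p2 = 0.04 + 0.05 * u[5]

    lam = np.asarray(wavelengths, dtype=float)
    spec = floor + rise / (1.0 + np.exp(-(lam - 560.0) / 35.0))
    spec -= dip_depth * np.exp(-(((lam - dip_center) / 28.0) ** 2))
    spec += p1 * np.exp(-(((lam - 760.0) / 55.0) ** 2))
    spec += p2 * np.exp(-(((lam - 870.0) / 45.0) ** 2))
    return np.clip(spec, 0.02, 0.98)


def dish_background(wavelengths: np.ndarray) -> np.ndarray:
    """Bright, nearly flat reflectance of the white dish."""
    lam = np.asarray(wavelengths, dtype=float)
    tilt = (lam - lam[0]) / (lam[-1] - lam[0])
    return 0.93 - 0.03 * tilt


def default_spectral_model(
    wavelengths: np.ndarray,
    cultivars: tuple[str, ...],
    noise_sd: float = 0.01,
    sugar_effect: SugarEffect | None = None,
) -> SpectralModel:
    """Spectral model with one generated template per cultivar."""
    baselines = {c: cultivar_baseline(c, wavelengths) for c in cultivars}
    return SpectralModel(
        wavelengths=np.asarray(wavelengths, dtype=float),
        cultivar_baselines=baselines,
        sugar_effect=sugar_effect or SugarEffect(),
        noise_sd=noise_sd,
    )


def simulate_spectrum(
    model: SpectralModel,
    cultivar: str,
    sugar_pct: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Draw one noisy jam pixel spectrum.

    Deterministic given the seed/generator state; with ``noise_sd = 0`` it
    equals :meth:`SpectralModel.mean_spectrum` exactly.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    clean = model.mean_spectrum(cultivar, sugar_pct)
    if model.noise_sd == 0:
        return clean
    noisy = clean + rng.normal(0.0, model.noise_sd, size=clean.shape)
    return np.clip(noisy, 0.0, 1.0)
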