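"""Acquisition design: which captures exist.

The study design is a full factorial over cultivar x sugar level x jam-layer
thickness, with a fixed number of camera views per thickness (views bundle the
angle/distance variations).  The default reproduces the published campaign:
8 Central-Asian cultivars, 11 sugar levels from 25% to 75% w/w in 5% steps,
and layer thicknesses 0.5 / 1.0 / 2.0 cm imaged from 6 / 7 / 7 views,
giving 8 x 11 x 20 = 1760 captures.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

DEFAULT_CULTIVARS = (
    "aport",
    "gala",
    "golden",
    "granny",
    "prince",
    "idared",
    "simirenko",
    "starcrimson",
)

DEFAULT_SUGAR_LEVELS = tuple(range(25, 80, 5))

DEFAULT_VIEWS_PER_THICKNESS = {0.5: 6, 1.0: 7, 2.0: 7}

DEFAULT_DISTANCES_CM = (20.0, 30.0, 40.0)


class InvalidDesignError(ValueError):
    """The acquisition design violates its invariants."""


@dataclass(frozen=True)
class CaptureMeta:
    """Identity of one hyperspectral capture."""

    cultivar: str
    sugar_pct: float
    thickness_cm: float
    view: int
    distance_cm: float
    image_index: int


@dataclass(frozen=True)
class AcquisitionDesign:
    """Factorial imaging campaign over cultivars, sugar levels and thicknesses.

    Parameters
    ----------
    cultivars
        Cultivar names; one jam series is prepared per cultivar.
    sugar_levels
        Sugar concentrations in % w/w, strictly increasing, all in (0, 100).
    views_per_thickness
        Mapping layer thickness (cm) -> number of views captured.  Views are
        opaque indices; the camera angle/distance they correspond to is
        carried only as per-view metadata and never drives any downstream
        logic.
    distances
        Camera distances (cm) cycled through as per-view metadata.
    bands, wavelength_range
        Spectral axis of the camera: ``bands`` samples spanning
        ``wavelength_range`` nm inclusive.
    spatial_size
        (height, width) of the simulated frames in pixels.
    """

    cultivars: tuple[str, ...] = DEFAULT_CULTIVARS
    sugar_levels: tuple[float, ...] = DEFAULT_SUGAR_LEVELS
    views_per_thickness: dict[float, int] = field(
        default_factory=lambda: dict(DEFAULT_VIEWS_PER_THICKNESS)
    )
    distances: tuple[float, ...] = DEFAULT_DISTANCES_CM
    bands: int = 204
    wavelength_range: tuple[float, float] = (400.0, 1000.0)
    spatial_size: tuple[int, int] = (64, 64)

    def __post_init__(self) -> None:
        if not self.cultivars:
            raise InvalidDesignError("design needs at least one cultivar")
        if len(set(self.cultivars)) != len(self.cultivars):
            raise InvalidDesignError("duplicate cultivar names")
        if not self.sugar_levels:
            raise InvalidDesignError("design needs at least one sugar level")
        levels = list(self.sugar_levels)
        if any(not 0 < s < 100 for s in levels):
            raise InvalidDesignError("sugar levels must lie in (0, 100) % w/w")
        if any(b <= a for a, b in zip(levels, levels[1:])):
            raise InvalidDesignError("sugar levels must be strictly increasing")
        if not self.views_per_thickness:
            raise InvalidDesignError("at least one thickness is required")
        if any(v < 1 for v in self.views_per_thickness.values()):
            raise InvalidDesignError("view counts must be >= 1")
        if self.bands < 4:
            raise InvalidDesignError("need at least 4 spectral bands")
        lo, hi = self.wavelength_range
        if hi <= lo:
            raise InvalidDesignError("wavelength_range max must exceed min")
        h, w = self.spatial_size
        if h < 8 or w < 8:
            raise InvalidDesignError("spatial_size must be at least 8x8")

    @property
    def wavelengths(self) -> np.ndarray:
        """Band-center wavelengths in nm (evenly spaced, endpoints included)."""
        lo, hi = self.wavelength_range
        return np.linspace(lo, hi, self.bands)

    @property
    def n_views(self) -> int:
        return sum(self.views_per_thickness.values())

    @property
    def n_captures(self) -> int:
        return len(self.cultivars) * len(self.sugar_levels) * self.n_views

    @property
    def n_samples(self) -> int:
        """Number of physical jam samples (cultivar x concentration cells)."""
        return len(self.cultivars) * len(self.sugar_levels)


def enumerate_design(design: AcquisitionDesign) -> list[CaptureMeta]:
    """List every capture of the campaign in a fixed deterministic order.

    One entry per (cultivar, sugar level, thickness, view); ``image_index``
    numbers the captures consecutively from 0 and is stable across calls.
    """
    captures: list[CaptureMeta] = []
    idx = 0
    for cultivar, sugar in itertools.product(design.cultivars, design.sugar_levels):
        for thickness in sorted(design.views_per_thickness):
            n_views = design.views_per_thickness[thickness]
            for view in range(n_views):
                distance = design.distances[view % len(design.distances)]
                captures.append(
                    CaptureMeta(
                        cultivar=cultivar,
                        sugar_pct=float(sugar),
                        thickness_cm=float(thickness),
                        view=view,
                        distance_cm=float(distance),
                        image_index=idx,
                    )
                )
                idx += 1
    return captures
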