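"""Jam segmentation and grid-based spectral feature extraction.

The jam region is isolated with the spectral angle mapper (SAM): a pixel
belongs to the jam when the angle between its spectrum and a reference
spectrum drawn from a homogeneous jam patch is at most 0.2 rad.  The tight
bounding box of the mask is shrunk by a 10% per-side margin to shed dish
edges, then subdivided into a g x g grid (g = 1..5); each cell contributes
one record: the mean spectrum of its masked pixels, normalised to unit
Euclidean length.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .calibrate import ReflectanceCube

DEFAULT_SAM_THRESHOLD = 0.2
DEFAULT_MARGIN = 0.10
DEFAULT_MIN_PIXELS = 5


class UndefinedAngleError(ValueError):
    """Spectral angle requested for a zero vector."""


class EmptyRoiError(ValueError):
    """No pixels to build a region of interest from."""


class DegenerateRoiError(ValueError):
    """Margin or subdivision collapsed the region of interest."""


@dataclass(frozen=True)
class JamMask:
    """SAM jam mask together with the reference spectrum that produced it."""

    mask: np.ndarray
    reference: np.ndarray
    threshold_rad: float

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold_rad < math.pi / 2:
            raise ValueError("threshold must lie in (0, pi/2) radians")


@dataclass(frozen=True)
class RegionOfInterest:
    """Half-open bounding box [row_min, row_max) x [col_min, col_max)."""

    row_min: int
    row_max: int
    col_min: int
    col_max: int

    def __post_init__(self) -> None:
        if self.row_max <= self.row_min or self.col_max <= self.col_min:
            raise DegenerateRoiError(f"empty region of interest: {self}")

    @property
    def height(self) -> int:
        return self.row_max - self.row_min

    @property
    def width(self) -> int:
        return self.col_max - self.col_min


@dataclass(frozen=True)
class GridCellFeature:
    """One grid cell's unit-norm mean spectrum."""

    grid_size: int
    cell: tuple[int, int]
    feature: np.ndarray
    n_pixels: int


def spectral_angle(p: np.ndarray, r: np.ndarray) -> float:
    """Angle in radians between two spectra (scale-invariant, symmetric)."""
    p = np.asarray(p, dtype=float)
    r = np.asarray(r, dtype=float)
    if p.shape != r.shape:
        raise ValueError("spectra must have equal length")
    np_, nr = np.linalg.norm(p), np.linalg.norm(r)
    if np_ == 0 or nr == 0:
        raise UndefinedAngleError("spectral angle undefined for a zero vector")
    cos = np.clip(p @ r / (np_ * nr), -1.0, 1.0)
    return float(np.arccos(cos))


def spectral_angle_image(cube: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per-pixel spectral angle to ``r`` over a (h, w, bands) cube.

    Zero-norm pixels get angle pi (never matched).
    """
    r = np.asarray(r, dtype=float)
    nr = np.linalg.norm(r)
    if nr == 0:
        raise UndefinedAngleError("spectral angle undefined for a zero reference")
    flat = np.asarray(cube, dtype=float)
    norms = np.linalg.norm(flat, axis=-1)
    dots = flat @ r
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.clip(dots / (norms * nr), -1.0, 1.0)
    angles = np.arccos(cos)
    angles[norms == 0] = np.pi
    return angles


def pick_reference(
    cube: ReflectanceCube, seed_region: RegionOfInterest | None = None
) -> np.ndarray:
    """Reference jam spectrum: per-band median over a homogeneous patch.

    The default patch is the central 10% x 10% of the frame — the jam is
    centred in the acquisitions — and the median keeps single outlier pixels
    out of the reference.
    """
    h, w = cube.R.shape[:2]
    if seed_region is None:
        dh, dw = max(1, h // 10), max(1, w // 10)
        r0, c0 = (h - dh) // 2, (w - dw) // 2
        seed_region = RegionOfInterest(r0, r0 + dh, c0, c0 + dw)
    if seed_region.row_max > h or seed_region.col_max > w:
        raise ValueError("seed region exceeds image bounds")
    patch = cube.R[
        seed_region.row_min : seed_region.row_max,
        seed_region.col_min : seed_region.col_max,
    ]
    if patch.size == 0:
        raise EmptyRoiError("empty seed region")
    return np.median(patch.reshape(-1, patch.shape[-1]), axis=0)


def sam_mask(
    cube: ReflectanceCube,
    reference: np.ndarray,
    threshold_rad: float = DEFAULT_SAM_THRESHOLD,
) -> JamMask:
    """Threshold the per-pixel spectral angle (inclusive: angle <= threshold).

    Pixels flagged invalid by calibration are excluded from the mask.
    """
    angles = spectral_angle_image(cube.R, reference)
    mask = angles <= threshold_rad
    if cube.invalid is not None:
        mask &= ~cube.invalid
    return JamMask(mask=mask, reference=np.asarray(reference, dtype=float),
                   threshold_rad=threshold_rad)


def roi_from_mask(mask: np.ndarray | JamMask) -> RegionOfInterest:
    """Tightest half-open box containing every masked pixel."""
    m = mask.mask if isinstance(mask, JamMask) else np.asarray(mask)
    rows = np.flatnonzero(m.any(axis=1))
    cols = np.flatnonzero(m.any(axis=0))
    if rows.size == 0:
        raise EmptyRoiError("mask has no true pixels")
    return RegionOfInterest(
        int(rows[0]), int(rows[-1]) + 1, int(cols[0]), int(cols[-1]) + 1
    )


def apply_margin(
    roi: RegionOfInterest, fraction: float = DEFAULT_MARGIN
) -> RegionOfInterest:
    """Shrink the box inward by floor(fraction * size) pixels per side."""
    if not 0.0 <= fraction < 0.5:
        raise ValueError("margin fraction must lie in [0, 0.5)")
    dr = math.floor(fraction * roi.height)
    dc = math.floor(fraction * roi.width)
    try:
        return RegionOfInterest(
            roi.row_min + dr, roi.row_max - dr, roi.col_min + dc, roi.col_max - dc
        )
    except DegenerateRoiError:
        raise DegenerateRoiError(
            f"margin {fraction} collapses {roi.height}x{roi.width} box"
        ) from None


def subdivide(roi: RegionOfInterest, g: int) -> list[RegionOfInterest]:
    """Partition the box into g x g cells, row-major.

    Cells tile the box exactly; when a dimension is not divisible by g the
    leftover pixels go to the leading rows/columns, so cell sizes differ by
    at most one pixel per axis.
    """
    if not 1 <= g <= 5:
        raise ValueError("grid size must be in 1..5")
    if roi.height < g or roi.width < g:
        raise DegenerateRoiError(
            f"roi {roi.height}x{roi.width} too small for a {g}x{g} grid"
        )

    def edges(start: int, size: int) -> list[int]:
        base, rem = divmod(size, g)
        sizes = [base + 1] * rem + [base] * (g - rem)
        out = [start]
        for s in sizes:
            out.append(out[-1] + s)
        return out

    re_, ce = edges(roi.row_min, roi.height), edges(roi.col_min, roi.width)
    return [
        RegionOfInterest(re_[i], re_[i + 1], ce[j], ce[j + 1])
        for i in range(g)
        for j in range(g)
    ]


def cell_feature(
    cube: ReflectanceCube,
    mask: np.ndarray | JamMask,
    cell: RegionOfInterest,
    grid_size: int,
    cell_index: tuple[int, int],
    min_pixels: int = DEFAULT_MIN_PIXELS,
) -> GridCellFeature | None:
    """Unit-norm mean spectrum of the masked pixels inside one cell.

    Returns ``None`` (dropped) when fewer than ``min_pixels`` masked pixels
    fall in the cell or the mean spectrum has zero norm.
    """
    m = mask.mask if isinstance(mask, JamMask) else np.asarray(mask)
    sub = cube.R[cell.row_min : cell.row_max, cell.col_min : cell.col_max]
    msub = m[cell.row_min : cell.row_max, cell.col_min : cell.col_max]
    n = int(msub.sum())
    if n < min_pixels:
        return None
    mean = sub[msub].mean(axis=0)
    norm = np.linalg.norm(mean)
    if norm == 0:
        return None
    return GridCellFeature(
        grid_size=grid_size, cell=cell_index, feature=mean / norm, n_pixels=n
    )


def extract_features(
    cube: ReflectanceCube,
    grid_size: int,
    threshold_rad: float = DEFAULT_SAM_THRESHOLD,
    margin: float = DEFAULT_MARGIN,
    min_pixels: int = DEFAULT_MIN_PIXELS,
    reference: np.ndarray | None = None,
    seed_region: RegionOfInterest | None = None,
) -> list[GridCellFeature]:
    """Full segmentation chain: reference -> SAM -> ROI -> margin -> grid.

    Returns the surviving cells in row-major order; dropped cells are simply
    absent.
    """
    if reference is None:
        reference = pick_reference(cube, seed_region)
    mask = sam_mask(cube, reference, threshold_rad)
    roi = apply_margin(roi_from_mask(mask), margin)
    cells = subdivide(roi, grid_size)
    out = []
    for k, cell in enumerate(cells):
        feat = cell_feature(
            cube,
            mask,
            cell,
            grid_size,
            (k // grid_size, k % grid_size),
            min_pixels=min_pixels,
        )
        if feat is not None:
            out.append(feat)
    return out
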