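"""Cavalieri stereology: systematic section sampling, point-counting and
2D-nucleator area estimation, and the volume estimator

    V = t * (1/SSF) * sum_i a_i,

with section thickness ``t`` (um), section sampling fraction ``SSF`` and
per-section cross-sectional areas ``a_i`` (mm^2).  Under systematic uniform
random sampling (a random start offset among the 1/SSF possible ones) the
estimator is unbiased for the stack's Riemann volume: averaged over all
offsets every section is counted exactly once.

Sections are binary raster masks; array index (i, j) maps to the in-plane
position ((i+0.5)*p0, (j+0.5)*p1) mm at pixel size (p0, p1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import map_coordinates

__all__ = [
    "SectionStack",
    "CavalieriEstimate",
    "NucleatorResult",
    "systematic_sample",
    "point_count_area",
    "nucleator_area",
    "cavalieri_volume",
    "pixel_area",
]


@dataclass(frozen=True)
class SectionStack:
    """Ordered binary 2D sections with shared pixel geometry."""

    sections: np.ndarray           # (n, h, w) bool
    pixel_size_mm: tuple[float, float]
    thickness_um: float
    spacing_um: float              # center-to-center distance of kept sections

    def __post_init__(self) -> None:
        s = np.asarray(self.sections).astype(bool)
        if s.ndim != 3:
            raise ValueError("sections must be a (n, h, w) array")
        if self.thickness_um <= 0 or self.spacing_um <= 0:
            raise ValueError("thickness and spacing must be positive")
        object.__setattr__(self, "sections", s)

    def __len__(self) -> int:
        return self.sections.shape[0]


@dataclass(frozen=True)
class CavalieriEstimate:
    """Stereological volume with its provenance."""

    volume_cm3: float
    areas_mm2: tuple[float, ...]
    thickness_um: float
    ssf: float
    start: int | None = None


@dataclass(frozen=True)
class NucleatorResult:
    """2D-nucleator area with the star-shape diagnostic.

    ``non_star_shaped`` is True when any ray re-entered the mask beyond its
    first boundary crossing, i.e. the section is not star shaped about the
    reference point and the estimate is biased low.
    """

    area_mm2: float
    ray_lengths_mm: np.ndarray
    non_star_shaped: bool


def _check_ssf(ssf: float) -> int:
    if not 0.0 < ssf <= 1.0:
        raise ValueError("ssf must be in (0, 1]")
    period = 1.0 / ssf
    if abs(period - round(period)) > 1e-9:
        raise ValueError("1/ssf must be an integer")
    return int(round(period))


def systematic_sample(stack: SectionStack, ssf: float, start: int) -> SectionStack:
    """Keep sections start, start + 1/ssf, start + 2/ssf, ..."""
    period = _check_ssf(ssf)
    if not 0 <= start < period:
        raise ValueError(f"start must be in [0, {period}), got {start}")
    kept = stack.sections[start::period]
    return replace(stack, sections=kept, spacing_um=stack.spacing_um * period)


def pixel_area(section: np.ndarray, pixel_size_mm: tuple[float, float]) -> float:
    """Exact raster area: foreground pixel count x pixel area, mm^2."""
    return float(np.count_nonzero(section)) * pixel_size_mm[0] * pixel_size_mm[1]


def point_count_area(
    section: np.ndarray,
    pixel_size_mm: tuple[float, float],
    d_mm: float,
    offset_mm: tuple[float, float] = (0.0, 0.0),
) -> float:
    """Grid point-counting area estimate: (points hitting the mask) * d^2.

    Points lie at offset + k*d along each axis.  A point counts as inside iff
    the pixel containing it (half-open convention, floor(x/p)) is foreground,
    so results are deterministic on raster masks.
    """
    if d_mm <= 0:
        raise ValueError("grid spacing must be positive")
    if not (0.0 <= offset_mm[0] < d_mm and 0.0 <= offset_mm[1] < d_mm):
        raise ValueError("offset must lie in [0, d) per axis")
    section = np.asarray(section).astype(bool)
    h, w = section.shape
    p0, p1 = pixel_size_mm
    xs = np.arange(offset_mm[0], h * p0, d_mm)
    ys = np.arange(offset_mm[1], w * p1, d_mm)
    if xs.size == 0 or ys.size == 0:
        return 0.0
    i = np.floor(xs / p0).astype(int)
    j = np.floor(ys / p1).astype(int)
    i = i[i < h]
    j = j[j < w]
    hits = int(section[np.ix_(i, j)].sum())
    return hits * d_mm * d_mm


def nucleator_area(
    section: np.ndarray,
    pixel_size_mm: tuple[float, float],
    reference_mm: tuple[float, float],
    *,
    n_rays: int = 64,
    seed: int | None = None,
    step_px: float = 0.25,
) -> NucleatorResult:
    """2D-nucleator area: pi * mean over rays of l(theta)^2.

    ``l(theta)`` is the distance from the reference point to the first mask
    boundary crossing along a systematic fan of ``n_rays`` angles rotated by
    a single uniform random angle (seeded).  The mask is sampled bilinearly
    and the crossing located by linear interpolation at the 0.5 level, so a
    disk is recovered to well below 0.1% at 64 rays.  Exact only for sections
    star shaped about the reference; re-entry beyond the first crossing
    raises ``non_star_shaped``.
    """
    section = np.asarray(section).astype(float)
    h, w = section.shape
    p0, p1 = pixel_size_mm
    rx, ry = reference_mm
    i0, j0 = rx / p0 - 0.5, ry / p1 - 0.5  # pixel-index coordinates
    inside = (
        0 <= int(math.floor(rx / p0)) < h
        and 0 <= int(math.floor(ry / p1)) < w
        and section[int(math.floor(rx / p0)), int(math.floor(ry / p1))] > 0
    )
    if not inside:
        raise ValueError("reference point must lie inside the mask")

    rng = np.random.default_rng(seed)
    rot = rng.uniform(0.0, 2.0 * math.pi / n_rays)
    angles = rot + 2.0 * math.pi * np.arange(n_rays) / n_rays

    # March all rays together in physical (mm) space.
    step_mm = step_px * min(p0, p1)
    max_len = math.hypot(h * p0, w * p1)
    n_steps = int(max_len / step_mm) + 2
    t = np.arange(n_steps) * step_mm                      # (s,)
    dx, dy = np.cos(angles), np.sin(angles)               # (r,)
    px = rx + t[None, :] * dx[:, None]                    # (r, s) mm
    py = ry + t[None, :] * dy[:, None]
    vals = map_coordinates(
        section,
        np.stack([px / p0 - 0.5, py / p1 - 0.5]),
        order=1,
        mode="constant",
        cval=0.0,
    )                                                     # (r, s)

    outside = vals < 0.5
    lengths = np.empty(n_rays)
    reentered = False
    for r in range(n_rays):
        out_idx = np.flatnonzero(outside[r])
        if out_idx.size == 0:  # ray never leaves (mask touches border)
            lengths[r] = t[-1]
            continue
        k = out_idx[0]
        if k == 0:
            lengths[r] = 0.0
        else:
            v0, v1 = vals[r, k - 1], vals[r, k]
            frac = (v0 - 0.5) / (v0 - v1)
            lengths[r] = t[k - 1] + frac * step_mm
        if np.any(vals[r, k:] >= 0.5):
            reentered = True

    area = math.pi * float(np.mean(lengths**2))
    return NucleatorResult(area_mm2=area, ray_lengths_mm=lengths, non_star_shaped=reentered)


def cavalieri_volume(
    areas_mm2,
    thickness_um: float,
    ssf: float,
    *,
    start: int | None = None,
) -> CavalieriEstimate:
    """Cavalieri volume V = t * (1/SSF) * sum(a_i), reported in cm^3."""
    areas = tuple(float(a) for a in np.atleast_1d(np.asarray(areas_mm2, float)))
    if len(areas) == 0:
        raise ValueError("need at least one sampled section area")
    if thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    period = _check_ssf(ssf)
    t_mm = thickness_um / 1000.0
    volume_mm3 = t_mm * period * sum(areas)
    return CavalieriEstimate(
        volume_cm3=volume_mm3 / 1000.0,
        areas_mm2=areas,
        thickness_um=thickness_um,
        ssf=ssf,
        start=start,
    )
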