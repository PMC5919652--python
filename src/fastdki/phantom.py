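"""Synthetic stroke-phantom generator.

Builds a two-hemisphere rat-brain phantom in which an MD-hypointense lesion
core (reduced mean diffusivity, as in the acute ischemic core) is nested
inside a larger MKT-hyperintense lesion (elevated kurtosis extending beyond
the core).  The default geometry embeds the study conditions directly:

* brain ellipsoid of 1.433 cm^3 (whole fixed rat brain scale),
* lesion core of 0.232 cm^3 (the MD lesion group mean),
* MKT lesion of 0.304 cm^3 = 1.31 x core (the 31% MKT/MD volume excess),
* 0.25 x 0.25 x 0.5 mm voxels on a 64 x 64 x 30 grid (the dMRI protocol
  geometry; the last axis is the coronal slice axis).

The module also simulates the 19-image 1-9-9 acquisition under Rician noise
and cuts section stacks for the stereology arm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .dki_core import AcquisitionScheme, make_199_scheme
from .stereology import SectionStack

__all__ = [
    "TissueParams",
    "Ellipsoid",
    "PhantomSpec",
    "PhantomTruth",
    "NoisySeries",
    "default_spec",
    "generate_phantom",
    "simulate_acquisition",
    "slice_sections",
]


@dataclass(frozen=True)
class TissueParams:
    """Per-region ground-truth MD (um^2/ms) and MKT (dimensionless)."""

    md: float
    mkt: float

    def __post_init__(self) -> None:
        if self.md <= 0:
            raise ValueError("region MD must be positive")


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid, center and semi-axes in mm (phantom frame)."""

    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]

    def contains(self, x: np.ndarray, y: np.ndarray, z: np.ndarray) -> np.ndarray:
        cx, cy, cz = self.center
        ax, ay, az = self.semi_axes
        if min(ax, ay, az) < 0:
            raise ValueError("semi-axes must be nonnegative")
        if min(ax, ay, az) == 0.0:
            return np.zeros(np.broadcast(x, y, z).shape, dtype=bool)
        return (
            ((x - cx) / ax) ** 2 + ((y - cy) / ay) ** 2 + ((z - cz) / az) ** 2
        ) <= 1.0

    def scaled(self, factor: float) -> "Ellipsoid":
        return Ellipsoid(self.center, tuple(a * factor for a in self.semi_axes))

    @property
    def volume_mm3(self) -> float:
        ax, ay, az = self.semi_axes
        return 4.0 / 3.0 * math.pi * ax * ay * az


# The designed MKT/MD lesion volume excess, 0.304/0.232 rounded as reported.
DESIGNED_EXCESS_PERCENT = 31.0
_RING_SCALE = (1.0 + DESIGNED_EXCESS_PERCENT / 100.0) ** (1.0 / 3.0)

_DEFAULT_REGIONS = {
    "normal": TissueParams(md=0.5, mkt=0.8),
    "lesion_core": TissueParams(md=0.35, mkt=1.3),
    "lesion_ring": TissueParams(md=0.5, mkt=1.3),
}
_DEFAULT_BRAIN = Ellipsoid((0.0, 0.0, 0.0), (6.8, 7.4, 6.8))       # 1.433 cm^3
_DEFAULT_CORE = Ellipsoid((3.2, 0.0, 0.0), (2.4, 5.0, 4.62))       # 0.2322 cm^3


@dataclass(frozen=True)
class PhantomSpec:
    """Full description of a phantom realization.

    Geometry is analytic (ellipsoids in mm, centered on the grid); the MKT
    lesion is the core scaled isotropically by ``ring_scale`` so its volume
    exceeds the core's by the designed percentage.  ``snr`` is the b=0
    tissue signal-to-noise ratio used by the acquisition simulator.
    """

    shape: tuple[int, int, int] = (64, 64, 30)
    voxel_size_mm: tuple[float, float, float] = (0.25, 0.25, 0.5)
    regions: dict = field(default_factory=lambda: dict(_DEFAULT_REGIONS))
    brain: Ellipsoid = _DEFAULT_BRAIN
    lesion_core: Ellipsoid = _DEFAULT_CORE
    ring_scale: float = _RING_SCALE
    snr: float = 50.0
    s0: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.ring_scale < 1.0:
            raise ValueError("ring_scale must be >= 1 (core nested in ring)")
        for name in ("normal", "lesion_core", "lesion_ring"):
            if name not in self.regions:
                raise ValueError(f"missing region parameters for {name!r}")

    @property
    def lesion_ring(self) -> Ellipsoid:
        return self.lesion_core.scaled(self.ring_scale)


def default_spec(**overrides) -> PhantomSpec:
    """The default study phantom; keyword overrides replace fields."""
    return replace(PhantomSpec(), **overrides)


@dataclass(frozen=True)
class PhantomTruth:
    """Ground-truth parameter maps and nested masks for one phantom."""

    md: np.ndarray            # (nx, ny, nz) um^2/ms, 0 outside brain
    mkt: np.ndarray           # (nx, ny, nz) dimensionless, 0 outside brain
    masks: dict[str, np.ndarray]   # brain, left, right, lesion_md, lesion_mkt
    voxel_size_mm: tuple[float, float, float]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.voxel_size_mm))


def _voxel_centers(shape, voxel_size):
    """Voxel-center coordinates in mm, origin at the grid center."""
    coords = [
        (np.arange(n) + 0.5 - n / 2.0) * d for n, d in zip(shape, voxel_size)
    ]
    return np.meshgrid(*coords, indexing="ij")


def generate_phantom(spec: PhantomSpec) -> PhantomTruth:
    """Rasterize the analytic phantom onto the voxel grid.

    Deterministic (no randomness): each voxel center is assigned the
    innermost containing region (core > ring > normal tissue).  Raises if
    the MKT lesion is not strictly inside the brain or crosses into the
    contralateral hemisphere.
    """
    x, y, z = _voxel_centers(spec.shape, spec.voxel_size_mm)
    brain = spec.brain.contains(x, y, z)
    core = spec.lesion_core.contains(x, y, z)
    ring = spec.lesion_ring.contains(x, y, z)
    ring |= core  # nesting by construction; guard against thin shells

    if np.any(ring & ~brain):
        raise ValueError("lesion extends outside the brain mask")

    # Mid-sagittal split along the first (left-right) axis.
    nx = spec.shape[0]
    right_half = np.zeros(spec.shape, dtype=bool)
    right_half[nx // 2 :] = True
    left = brain & ~right_half
    right = brain & right_half
    if np.any(ring & left) and np.any(ring & right):
        raise ValueError("lesion crosses the mid-sagittal plane")

    md = np.zeros(spec.shape)
    mkt = np.zeros(spec.shape)
    for region_mask, name in (
        (brain & ~ring, "normal"),
        (ring & ~core, "lesion_ring"),
        (core, "lesion_core"),
    ):
        params = spec.regions[name]
        md[region_mask] = params.md
        mkt[region_mask] = params.mkt

    return PhantomTruth(
        md=md,
        mkt=mkt,
        masks={
            "brain": brain,
            "left": left,
            "right": right,
            "lesion_md": core,
            "lesion_mkt": ring,
        },
        voxel_size_mm=spec.voxel_size_mm,
    )


@dataclass(frozen=True)
class NoisySeries:
    """A simulated 19-volume acquisition.

    ``data`` has shape (nx, ny, nz, 19) in scheme order (b=0 first); all
    magnitudes are nonnegative under the Rician model.
    """

    data: np.ndarray
    scheme: AcquisitionScheme
    s0: float
    sigma: float
    voxel_size_mm: tuple[float, float, float]


def _axially_symmetric_eigs(md: float, fa: float) -> tuple[float, float]:
    """(lambda_parallel, lambda_perp) for an axially symmetric tensor with
    the requested mean diffusivity and fractional anisotropy."""
    if not 0.0 <= fa < 1.0:
        raise ValueError("fa must be in [0, 1)")
    delta = fa / math.sqrt(3.0 - 2.0 * fa * fa)
    return md * (1.0 + 2.0 * delta), md * (1.0 - delta)


def simulate_acquisition(
    truth: PhantomTruth,
    scheme: AcquisitionScheme | None = None,
    *,
    snr: float = 50.0,
    seed: int = 0,
    s0: float = 1.0,
    noise: str = "rician",
    fa: float = 0.0,
    fiber_axis: tuple[float, float, float] = (0.0, 0.0, 1.0),
) -> NoisySeries:
    """Simulate the 19-image protocol over the truth maps.

    Per-voxel tensors are isotropic by default (D = MD * Id, W = MKT * I);
    ``fa > 0`` switches to axially symmetric diffusion tensors with the given
    fiber axis while preserving each voxel's MD, exercising the estimator's
    direction-averaging.  Noise is Rician, S_noisy = sqrt((S+e1)^2 + e2^2)
    with e ~ Normal(0, s0/snr); ``noise="gaussian"`` adds e1 only (negative
    excursions preserved, for estimator-theory tests), ``noise="none"`` or
    ``snr=inf`` disables corruption.  Reproducible given ``seed``.
    """
    if scheme is None:
        scheme = make_199_scheme(1.0, 2.5)
    if snr <= 0:
        raise ValueError("snr must be positive")
    if noise not in ("rician", "gaussian", "none"):
        raise ValueError(f"unknown noise model {noise!r}")

    md = truth.md
    mkt = truth.mkt
    shape = md.shape
    n_vol = scheme.n_volumes
    clean = np.empty(shape + (n_vol,))
    clean[..., 0] = s0

    bvals = scheme.bvals
    bvecs = scheme.bvecs
    if fa > 0.0:
        u = np.asarray(fiber_axis, float)
        u = u / np.linalg.norm(u)
        # n'Dn = l_perp + (l_par - l_perp)(n.u)^2 with MD preserved.
        delta = fa / math.sqrt(3.0 - 2.0 * fa * fa)
        for v in range(1, n_vol):
            b, n = bvals[v], bvecs[v]
            cos2 = float(n @ u) ** 2
            adc = md * (1.0 - delta) + 3.0 * md * delta * cos2
            clean[..., v] = s0 * np.exp(-b * adc + (b * b / 6.0) * md**2 * mkt)
    else:
        # Isotropic voxels: the decay is direction independent per shell.
        for v in range(1, n_vol):
            b = bvals[v]
            clean[..., v] = s0 * np.exp(-b * md + (b * b / 6.0) * md**2 * mkt)

    clean *= truth.masks["brain"][..., None]  # no signal outside the brain

    sigma = 0.0 if (noise == "none" or math.isinf(snr)) else s0 / snr
    if sigma == 0.0:
        data = clean
    else:
        rng = np.random.default_rng(seed)
        e1 = rng.normal(0.0, sigma, clean.shape)
        if noise == "rician":
            e2 = rng.normal(0.0, sigma, clean.shape)
            data = np.sqrt((clean + e1) ** 2 + e2**2)
        else:
            data = clean + e1
    return NoisySeries(
        data=data,
        scheme=scheme,
        s0=s0,
        sigma=sigma,
        voxel_size_mm=truth.voxel_size_mm,
    )


def slice_sections(
    mask: np.ndarray,
    voxel_size_mm: tuple[float, float, float],
    thickness_um: float,
    *,
    axis: int = 2,
) -> SectionStack:
    """Cut a binary volume into contiguous coronal sections of the given
    thickness, resampling from the voxel grid.

    Each section takes the voxel layer containing its center (nearest
    neighbor along the cutting axis).  A partial terminal section is kept iff
    it spans at least half the nominal thickness (symmetric rounding).
    """
    if thickness_um <= 0:
        raise ValueError("section thickness must be positive")
    mask = np.asarray(mask).astype(bool)
    mask = np.moveaxis(mask, axis, 0)
    n_layers = mask.shape[0]
    dz_um = voxel_size_mm[axis] * 1000.0
    extent_um = n_layers * dz_um

    n_full = int(extent_um // thickness_um)
    remainder = extent_um - n_full * thickness_um
    n_sections = n_full + (1 if remainder >= 0.5 * thickness_um - 1e-9 else 0)
    if n_sections == 0:
        raise ValueError("volume thinner than half a section")

    centers = (np.arange(n_sections) + 0.5) * thickness_um
    layers = np.minimum((centers / dz_um).astype(int), n_layers - 1)
    sections = mask[layers]

    in_plane = tuple(d for i, d in enumerate(voxel_size_mm) if i != axis)
    return SectionStack(
        sections=sections,
        pixel_size_mm=in_plane,
        thickness_um=thickness_um,
        spacing_um=thickness_um,
    )
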