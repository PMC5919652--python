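"""Tensor algebra and closed-form 1-9-9 fast-DKI estimators.

Diffusion kurtosis imaging (DKI) models the log of the diffusion-weighted
signal with a two-term cumulant expansion in the b-value,

    log S(b, n) = -b n_i n_j D_ij + (b^2 / 6) * Dbar^2 * n_i n_j n_k n_l W_ijkl,

where ``D`` is the rank-2 diffusion tensor (um^2/ms), ``W`` the fully
symmetric rank-4 kurtosis tensor (dimensionless), ``Dbar = Tr(D)/3`` the
mean diffusivity (MD), and ``n`` a unit gradient direction.  The mean of the
kurtosis tensor (MKT, ``Wbar``) is the spherical average of the apparent
kurtosis ``W(n)``, which reduces to the trace identity

    Wbar = (1/5) (W_xxxx + W_yyyy + W_zzzz + 2 W_xxyy + 2 W_xxzz + 2 W_yyzz).

The 1-9-9 protocol (1 b=0 image plus 9 directions at each of two shells
b1 < b2) admits closed-form estimators for MD and MKT: the weighted log-sum
over the nine directions collapses the directional model to two scalar
equations in (Dbar, Wbar), which invert exactly for noiseless data.

Units follow the convention b in ms/um^2, MD in um^2/ms, MKT dimensionless.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import numpy.typing as npt

__all__ = [
    "QualityFlag",
    "DiffusionTensor",
    "KurtosisTensorW",
    "AcquisitionScheme",
    "LogSignalAverages",
    "DKIEstimate",
    "ISOTROPIC_W",
    "make_199_scheme",
    "apparent_kurtosis",
    "mkt_trace",
    "predict_signal",
    "log_sum_average",
    "estimate_md_199",
    "estimate_mkt_199",
    "estimate_voxel",
    "estimate_arrays",
]

# Numerical policy (all overridable through function arguments).
SIGNAL_FLOOR_EPS = 1e-6     # clamp S to eps*s0 before taking logs
DEGENERACY_FLOOR = 1e-12    # |A1 b2^2 - A2 b1^2| below this -> degenerate MKT
MD_RANGE = (0.0, 4.0)       # um^2/ms, plausibility interval for fixed tissue
MKT_RANGE = (-1.0, 5.0)     # dimensionless plausibility interval

_UNIT_TOL = 1e-9
_SCHEME_TOL = 1e-10


class QualityFlag(enum.IntFlag):
    """Per-voxel quality markers carried by estimates and flag maps."""

    NONE = 0
    NONPOSITIVE_SIGNAL = 1
    DEGENERATE_DENOMINATOR = 2
    MD_OUT_OF_RANGE = 4
    MKT_OUT_OF_RANGE = 8
    OUTSIDE_MASK = 16


def _as_unit_direction(n: npt.ArrayLike) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.shape != (3,):
        raise ValueError(f"direction must be a 3-vector, got shape {n.shape}")
    if abs(np.linalg.norm(n) - 1.0) > _UNIT_TOL:
        raise ValueError(f"direction must be unit norm, got |n| = {np.linalg.norm(n)!r}")
    return n


@dataclass(frozen=True)
class DiffusionTensor:
    """Symmetric positive-semidefinite rank-2 diffusion tensor, um^2/ms."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("diffusion tensor must be 3x3")
        if not np.array_equal(m, m.T):
            raise ValueError("diffusion tensor must be exactly symmetric")
        if np.linalg.eigvalsh(m).min() < -1e-12:
            raise ValueError("diffusion tensor must be positive semidefinite")
        object.__setattr__(self, "matrix", m)

    @classmethod
    def from_unique(cls, dxx, dyy, dzz, dxy=0.0, dxz=0.0, dyz=0.0) -> "DiffusionTensor":
        return cls(np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]], float))

    @classmethod
    def isotropic(cls, md: float) -> "DiffusionTensor":
        return cls(md * np.eye(3))

    @property
    def md(self) -> float:
        """Mean diffusivity, Tr(D)/3."""
        return float(np.trace(self.matrix)) / 3.0


def _symmetrize_rank4(t: np.ndarray) -> np.ndarray:
    """Average a 3x3x3x3 array over all 24 index permutations."""
    import itertools

    acc = np.zeros_like(t)
    for perm in itertools.permutations(range(4)):
        acc += np.transpose(t, perm)
    return acc / 24.0


@dataclass(frozen=True)
class KurtosisTensorW:
    """Fully symmetric rank-4 kurtosis tensor (15 unique components)."""

    tensor: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.tensor, dtype=float)
        if t.shape != (3, 3, 3, 3):
            raise ValueError("kurtosis tensor must be 3x3x3x3")
        if not np.allclose(t, _symmetrize_rank4(t), atol=1e-12, rtol=0.0):
            raise ValueError("kurtosis tensor must be fully symmetric")
        object.__setattr__(self, "tensor", t)

    @classmethod
    def from_array(cls, t: npt.ArrayLike, symmetrize: bool = False) -> "KurtosisTensorW":
        t = np.asarray(t, dtype=float)
        if symmetrize:
            t = _symmetrize_rank4(t)
        return cls(t)

    @classmethod
    def from_unique(cls, components: dict[str, float]) -> "KurtosisTensorW":
        """Build from unique components keyed like ``"xxxx"`` or ``"xxyz"``.

        Any index order may be used in the keys; unspecified components are 0.
        """
        axis = {"x": 0, "y": 1, "z": 2}
        t = np.zeros((3, 3, 3, 3))
        import itertools

        for key, value in components.items():
            idx = tuple(axis[c] for c in key)
            if len(idx) != 4:
                raise ValueError(f"component key must have four letters, got {key!r}")
            for perm in set(itertools.permutations(idx)):
                t[perm] = value
        return cls(t)

    @classmethod
    def isotropic(cls, mkt: float) -> "KurtosisTensorW":
        """Isotropic tensor ``mkt * I`` whose apparent kurtosis is ``mkt`` in
        every direction (so its MKT is exactly ``mkt``)."""
        return cls(mkt * ISOTROPIC_W_ARRAY)

    @property
    def mkt(self) -> float:
        return mkt_trace(self)


def _isotropic_rank4() -> np.ndarray:
    d = np.eye(3)
    return (
        np.einsum("ij,kl->ijkl", d, d)
        + np.einsum("ik,jl->ijkl", d, d)
        + np.einsum("il,jk->ijkl", d, d)
    ) / 3.0


#: The fully symmetric isotropic rank-4 tensor I with <W, I> = Tr(W) and
#: apparent kurtosis I(n) = 1 for every unit n.
ISOTROPIC_W_ARRAY = _isotropic_rank4()
ISOTROPIC_W = KurtosisTensorW(ISOTROPIC_W_ARRAY)


@dataclass(frozen=True)
class AcquisitionScheme:
    """The 1-9-9 protocol: b = (0, b1, b2) with 3 axis + 6 bisector directions.

    The nine directions are weighted 1/15 (axes) and 2/15 (bisectors); the
    weighted direction average of any symmetric rank-4 form then equals
    (1/5)Tr(W) and of any rank-2 form equals Tr(D)/3.  This cancellation of
    mixed-index cross terms is what makes the closed forms exact, and it is
    certified at construction, so rotated direction sets are accepted too.
    """

    b1: float
    b2: float
    axes: np.ndarray        # (3, 3) unit rows
    bisectors: np.ndarray   # (6, 3) unit rows
    delta_ms: float | None = None   # gradient duration, informational
    Delta_ms: float | None = None   # diffusion time, informational

    AXIS_WEIGHT = 1.0 / 15.0
    BISECTOR_WEIGHT = 2.0 / 15.0

    def __post_init__(self) -> None:
        if not (0.0 < self.b1 < self.b2):
            raise ValueError(f"require 0 < b1 < b2, got b1={self.b1}, b2={self.b2}")
        axes = np.asarray(self.axes, dtype=float)
        bis = np.asarray(self.bisectors, dtype=float)
        if axes.shape != (3, 3) or bis.shape != (6, 3):
            raise ValueError("scheme needs 3 axis and 6 bisector directions")
        for n in np.vstack([axes, bis]):
            _as_unit_direction(n)
        object.__setattr__(self, "axes", axes)
        object.__setattr__(self, "bisectors", bis)
        self._certify()

    def _certify(self) -> None:
        """Exact validity check: direction moments match the isotropic forms.

        sum_d w_d n n^T = Id/3 guarantees the rank-2 log-sum reduces to MD;
        sum_d w_d n(x4) = I/5 guarantees the rank-4 average equals (1/5)Tr(W)
        for every fully symmetric W (Frobenius pairing with a symmetric tensor
        only sees the symmetric part of the moment tensor, which n(x4) is).
        """
        n = self.directions
        w = self.direction_weights
        m2 = np.einsum("d,di,dj->ij", w, n, n)
        m4 = np.einsum("d,di,dj,dk,dl->ijkl", w, n, n, n, n)
        if np.abs(m2 - np.eye(3) / 3.0).max() > _SCHEME_TOL:
            raise ValueError("direction set fails the rank-2 moment condition")
        if np.abs(m4 - ISOTROPIC_W_ARRAY / 5.0).max() > _SCHEME_TOL:
            raise ValueError("direction set fails the rank-4 moment condition")

    @property
    def directions(self) -> np.ndarray:
        """All nine directions, axes first then bisectors, shape (9, 3)."""
        return np.vstack([self.axes, self.bisectors])

    @property
    def direction_weights(self) -> np.ndarray:
        """Weights (1/15 x3, 2/15 x6); they sum to 1."""
        return np.array([self.AXIS_WEIGHT] * 3 + [self.BISECTOR_WEIGHT] * 6)

    @property
    def n_volumes(self) -> int:
        """Total image count: 1 (b=0) + 9 (b1) + 9 (b2)."""
        return 1 + 2 * len(self.directions)

    @property
    def bvals(self) -> np.ndarray:
        """Per-volume b-values in acquisition order (b0, 9x b1, 9x b2)."""
        return np.concatenate([[0.0], np.full(9, self.b1), np.full(9, self.b2)])

    @property
    def bvecs(self) -> np.ndarray:
        """Per-volume unit directions, (19, 3); the b=0 row is zero."""
        return np.vstack([np.zeros(3), self.directions, self.directions])


_DEFAULT_AXES = np.eye(3)
_DEFAULT_BISECTORS = np.array(
    [
        [1, 1, 0], [1, -1, 0],
        [1, 0, 1], [1, 0, -1],
        [0, 1, 1], [0, 1, -1],
    ],
    dtype=float,
) / math.sqrt(2.0)


def make_199_scheme(
    b1: float,
    b2: float,
    *,
    axes: npt.ArrayLike | None = None,
    bisectors: npt.ArrayLike | None = None,
    delta_ms: float | None = None,
    Delta_ms: float | None = None,
) -> AcquisitionScheme:
    """Build a 1-9-9 acquisition scheme (b in ms/um^2).

    Defaults to the coordinate axes plus the six in-plane bisectors
    (1,+-1,0)/sqrt2, (1,0,+-1)/sqrt2, (0,1,+-1)/sqrt2.  Any direction set that
    satisfies the moment conditions (e.g. a global rotation of the default)
    is accepted; anything else raises at construction.
    """
    return AcquisitionScheme(
        b1=float(b1),
        b2=float(b2),
        axes=_DEFAULT_AXES if axes is None else np.asarray(axes, float),
        bisectors=_DEFAULT_BISECTORS if bisectors is None else np.asarray(bisectors, float),
        delta_ms=delta_ms,
        Delta_ms=Delta_ms,
    )


def apparent_kurtosis(W: KurtosisTensorW, n: npt.ArrayLike) -> float:
    """Directional (apparent) kurtosis W(n) = n_i n_j n_k n_l W_ijkl."""
    n = _as_unit_direction(n)
    return float(np.einsum("i,j,k,l,ijkl->", n, n, n, n, W.tensor))


def mkt_trace(W: KurtosisTensorW) -> float:
    """MKT via the trace identity, (1/5)Tr(W).

    Equals the spherical average of the apparent kurtosis for fully
    symmetric W.
    """
    t = W.tensor
    return (
        t[0, 0, 0, 0] + t[1, 1, 1, 1] + t[2, 2, 2, 2]
        + 2.0 * (t[0, 0, 1, 1] + t[0, 0, 2, 2] + t[1, 1, 2, 2])
    ) / 5.0


def predict_signal(
    s0: float,
    b: float,
    n: npt.ArrayLike,
    D: DiffusionTensor,
    W: KurtosisTensorW,
) -> float:
    """Forward two-term cumulant model for one direction and b-value.

    S = s0 * exp(-b n'Dn + (b^2/6) Dbar^2 W(n)), with Dbar = Tr(D)/3 of the
    supplied tensor.  Strictly positive for s0 > 0.
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    if b < 0:
        raise ValueError("b must be nonnegative")
    n = _as_unit_direction(n)
    adc = float(n @ D.matrix @ n)
    log_decay = -b * adc + (b * b / 6.0) * D.md ** 2 * apparent_kurtosis(W, n)
    return s0 * math.exp(log_decay)


@dataclass(frozen=True)
class LogSignalAverages:
    """The two weighted log-sums A1, A2 of the 1-9-9 scheme.

    A_s = (1/15) [sum_axes log(S/s0) + 2 sum_bisectors log(S/s0)] at b_s.
    Under the two-term model A_s = -b_s Dbar + (b_s^2/6) Dbar^2 Wbar.
    """

    A1: float
    A2: float
    b1: float
    b2: float

    def __post_init__(self) -> None:
        if not (0.0 < self.b1 < self.b2):
            raise ValueError("require 0 < b1 < b2")
        if not (np.isfinite(self.A1) and np.isfinite(self.A2)):
            raise ValueError("log-signal averages must be finite")


@dataclass(frozen=True)
class DKIEstimate:
    """Per-voxel estimate: MD (um^2/ms), MKT (dimensionless), quality flags."""

    md: float
    mkt: float
    flags: QualityFlag = QualityFlag.NONE


def log_sum_average(
    signals: npt.ArrayLike,
    s0: float,
    scheme: AcquisitionScheme,
    *,
    floor_eps: float = SIGNAL_FLOOR_EPS,
) -> tuple[float, bool]:
    """Weighted log-sum of the nine shell signals, normalized by s0.

    ``signals`` must be ordered axes-first to match ``scheme.directions``.
    Nonpositive signals are clamped to ``floor_eps * s0`` before the log;
    the second return value reports whether any clamping occurred (callers
    propagate it as NONPOSITIVE_SIGNAL).
    """
    if s0 <= 0:
        raise ValueError("s0 must be positive")
    s = np.asarray(signals, dtype=float)
    if s.shape != (9,):
        raise ValueError("expected 9 shell signals")
    floor = floor_eps * s0
    clamped = bool(np.any(s < floor))
    s = np.maximum(s, floor)
    return float(scheme.direction_weights @ np.log(s / s0)), clamped


def estimate_md_199(A: LogSignalAverages) -> float:
    """Closed-form MD: (b1^2 A2 - b2^2 A1) / (b1 b2^2 - b1^2 b2), um^2/ms."""
    b1, b2 = A.b1, A.b2
    return (b1 * b1 * A.A2 - b2 * b2 * A.A1) / (b1 * b2 * b2 - b1 * b1 * b2)


def estimate_mkt_199(
    A: LogSignalAverages,
    *,
    degeneracy_floor: float = DEGENERACY_FLOOR,
    sentinel: float = math.nan,
) -> tuple[float, bool]:
    """Closed-form MKT: 6 b1 b2 (A1 b2 - A2 b1)(b1 - b2) / (A1 b2^2 - A2 b1^2)^2.

    The denominator vanishes only for zero signal decay (background); such
    voxels get ``sentinel`` and a True degeneracy indicator.
    """
    b1, b2 = A.b1, A.b2
    den = A.A1 * b2 * b2 - A.A2 * b1 * b1
    if abs(den) < degeneracy_floor:
        return sentinel, True
    num = 6.0 * b1 * b2 * (A.A1 * b2 - A.A2 * b1) * (b1 - b2)
    return num / (den * den), False


def estimate_voxel(
    signals: npt.ArrayLike,
    scheme: AcquisitionScheme,
    *,
    floor_eps: float = SIGNAL_FLOOR_EPS,
    degeneracy_floor: float = DEGENERACY_FLOOR,
    md_range: tuple[float, float] = MD_RANGE,
    mkt_range: tuple[float, float] = MKT_RANGE,
) -> DKIEstimate:
    """Estimate (MD, MKT) from one voxel's 19 signals (b=0 first).

    Composes the two log-sum averages with the closed forms and applies the
    plausibility flags.  Never raises on bad signal levels: an s0 at or below
    zero yields an all-flagged estimate with NaN values.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != (19,):
        raise ValueError("expected 19 signals (1 b=0 + 9 + 9)")
    md, mkt, flags = estimate_arrays(
        s.reshape(19, 1),
        scheme,
        floor_eps=floor_eps,
        degeneracy_floor=degeneracy_floor,
        md_range=md_range,
        mkt_range=mkt_range,
    )
    return DKIEstimate(float(md[0]), float(mkt[0]), QualityFlag(int(flags[0])))


def estimate_arrays(
    signals: np.ndarray,
    scheme: AcquisitionScheme,
    *,
    floor_eps: float = SIGNAL_FLOOR_EPS,
    degeneracy_floor: float = DEGENERACY_FLOOR,
    md_range: tuple[float, float] = MD_RANGE,
    mkt_range: tuple[float, float] = MKT_RANGE,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized 1-9-9 inversion over many voxels.

    Parameters
    ----------
    signals : (19, N) array, first row the b=0 signal, rows 1..9 the b1 shell
        and 10..18 the b2 shell, each ordered like ``scheme.directions``.

    Returns ``(md, mkt, flags)``, each shape (N,); flags are QualityFlag
    bitmasks as an integer array.  Voxels with nonpositive s0 come back NaN
    and fully flagged instead of raising.
    """
    s = np.asarray(signals, dtype=float)
    if s.ndim != 2 or s.shape[0] != 19:
        raise ValueError("signals must have shape (19, N)")
    n_vox = s.shape[1]
    flags = np.zeros(n_vox, dtype=np.int64)
    w = scheme.direction_weights

    s0 = s[0]
    bad_s0 = ~(s0 > 0) | ~np.isfinite(s0)
    s0_safe = np.where(bad_s0, 1.0, s0)

    with np.errstate(invalid="ignore", divide="ignore"):
        A = np.empty((2, n_vox))
        for shell, rows in enumerate((slice(1, 10), slice(10, 19))):
            sh = s[rows]
            floor = floor_eps * s0_safe
            clamped = np.any(sh < floor[None, :], axis=0)
            flags[clamped] |= QualityFlag.NONPOSITIVE_SIGNAL
            sh = np.maximum(sh, floor[None, :])
            A[shell] = w @ np.log(sh / s0_safe[None, :])

    b1, b2 = scheme.b1, scheme.b2
    A1, A2 = A
    md = (b1 * b1 * A2 - b2 * b2 * A1) / (b1 * b2 * b2 - b1 * b1 * b2)

    den = A1 * b2 * b2 - A2 * b1 * b1
    degenerate = np.abs(den) < degeneracy_floor
    flags[degenerate] |= QualityFlag.DEGENERATE_DENOMINATOR
    den_safe = np.where(degenerate, 1.0, den)
    mkt = 6.0 * b1 * b2 * (A1 * b2 - A2 * b1) * (b1 - b2) / (den_safe * den_safe)
    mkt[degenerate] = np.nan

    flags[(md < md_range[0]) | (md > md_range[1])] |= QualityFlag.MD_OUT_OF_RANGE
    with np.errstate(invalid="ignore"):
        mkt_bad = (mkt < mkt_range[0]) | (mkt > mkt_range[1])
    flags[mkt_bad] |= QualityFlag.MKT_OUT_OF_RANGE

    md[bad_s0] = np.nan
    mkt[bad_s0] = np.nan
    flags[bad_s0] |= (
        QualityFlag.NONPOSITIVE_SIGNAL | QualityFlag.DEGENERATE_DENOMINATOR
    )
    return md, mkt, flags
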