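import numpy as np
import pytest

from fastdki import (
    DiffusionTensor,
    KurtosisTensorW,
    generate_phantom,
    make_199_scheme,
)
from fastdki.phantom import PhantomSpec, default_spec


@pytest.fixture(scope="session")
def scheme():
    """The study protocol: b = (0, 1, 2.5) ms/um^2 with default directions."""
    return make_199_scheme(1.0, 2.5)


@pytest.fixture(scope="session")
def truth():
    """Default phantom ground truth (shared; treated as read-only)."""
    return generate_phantom(default_spec())


@pytest.fixture(scope="session")
def small_spec():
    """A reduced phantom for Monte Carlo loops: same voxel size and tissue
    parameters, smaller brain and lesion."""
    from fastdki.phantom import Ellipsoid

    return PhantomSpec(
        shape=(32, 32, 16),
        brain=Ellipsoid((0.0, 0.0, 0.0), (3.4, 3.7, 3.4)),
        lesion_core=Ellipsoid((1.6, 0.0, 0.0), (1.2, 2.5, 2.3)),
    )


def random_diffusion_tensor(rng: np.random.Generator) -> DiffusionTensor:
    """Random PSD tensor with MD in the fixed-tissue range (0.2-0.9)."""
    a = rng.normal(size=(3, 3))
    m = a @ a.T
    m *= rng.uniform(0.2, 0.9) / (np.trace(m) / 3.0)
    m = (m + m.T) / 2.0
    return DiffusionTensor(m)


def random_kurtosis_tensor(rng: np.random.Generator, max_mkt: float = 3.0) -> KurtosisTensorW:
    """Random fully symmetric W with |MKT| <= max_mkt.

    Built as an isotropic part (the MKT) plus a bounded traceless anisotropic
    part, keeping directional kurtosis at tissue-like magnitudes so forward
    signals stay clear of the log-clamping floor.
    """
    from fastdki.dki_core import ISOTROPIC_W_ARRAY, _symmetrize_rank4, mkt_trace

    aniso = _symmetrize_rank4(rng.normal(size=(3, 3, 3, 3)))
    aniso -= mkt_trace(KurtosisTensorW(aniso)) * ISOTROPIC_W_ARRAY
    aniso *= 0.25 / np.abs(aniso).max()
    target = rng.uniform(-max_mkt, max_mkt)
    return KurtosisTensorW(target * ISOTROPIC_W_ARRAY + aniso)


def brute_force_apparent_kurtosis(W: KurtosisTensorW, n) -> float:
    """Independent 81-term quadruple-loop oracle for n_i n_j n_k n_l W_ijkl."""
    n = np.asarray(n, float)
    total = 0.0
    for i in range(3):
        for j in range(3):
            for k in range(3):
                for l in range(3):
                    total += n[i] * n[j] * n[k] * n[l] * W.tensor[i, j, k, l]
    return total


def forward_signals(scheme, D, W, s0=1.0):
    """Noiseless 19-signal vector for one voxel via the forward model."""
    from fastdki import predict_signal

    sig = [s0]
    for b, n in zip(scheme.bvals[1:], scheme.bvecs[1:]):
        sig.append(predict_signal(s0, b, n, D, W))
    return np.array(sig)
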