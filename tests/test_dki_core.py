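"""Core tensor algebra, the forward model and the closed-form estimators."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fastdki import (
    DiffusionTensor,
    KurtosisTensorW,
    LogSignalAverages,
    QualityFlag,
    apparent_kurtosis,
    estimate_md_199,
    estimate_mkt_199,
    estimate_voxel,
    log_sum_average,
    make_199_scheme,
    mkt_trace,
    predict_signal,
)
from fastdki.dki_core import ISOTROPIC_W, estimate_arrays

from conftest import (
    brute_force_apparent_kurtosis,
    forward_signals,
    random_diffusion_tensor,
    random_kurtosis_tensor,
)


class TestScheme:
    def test_protocol_volume_count(self, scheme):
        assert scheme.n_volumes == 19
        assert scheme.bvals.shape == (19,)
        assert scheme.bvecs.shape == (19, 3)

    def test_weights_sum_to_one(self, scheme):
        assert scheme.direction_weights.sum() == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize("b1,b2", [(0.0, 1.0), (1.0, 1.0), (2.5, 1.0), (-1.0, 2.0)])
    def test_invalid_b_ordering_rejected(self, b1, b2):
        with pytest.raises(ValueError):
            make_199_scheme(b1, b2)

    def test_rank4_average_equals_fifth_trace(self, scheme):
        """Weighted direction-average of W(n) = (1/5)Tr(W), brute-force oracle."""
        rng = np.random.default_rng(7)
        w = scheme.direction_weights
        for _ in range(100):
            W = random_kurtosis_tensor(rng)
            avg = sum(
                wd * brute_force_apparent_kurtosis(W, n)
                for wd, n in zip(w, scheme.directions)
            )
            assert avg == pytest.approx(mkt_trace(W), abs=1e-10)

    def test_rank2_average_equals_md(self, scheme):
        rng = np.random.default_rng(8)
        w = scheme.direction_weights
        for _ in range(50):
            D = random_diffusion_tensor(rng)
            avg = sum(wd * float(n @ D.matrix @ n) for wd, n in zip(w, scheme.directions))
            assert avg == pytest.approx(D.md, abs=1e-12)

    def test_rotated_direction_set_accepted(self):
        from scipy.spatial.transform import Rotation

        R = Rotation.from_euler("zyx", [31.0, -14.0, 57.0], degrees=True).as_matrix()
        base = make_199_scheme(1.0, 2.5)
        rotated = make_199_scheme(
            1.0, 2.5, axes=base.axes @ R.T, bisectors=base.bisectors @ R.T
        )
        assert rotated.n_volumes == 19

    def test_invalid_direction_set_rejected(self):
        bad = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                        [1, 0, 0], [0, 1, 0], [0, 0, 1]], float)
        with pytest.raises(ValueError):
            make_199_scheme(1.0, 2.5, bisectors=bad)


class TestTensors:
    def test_diffusion_tensor_requires_symmetry_and_psd(self):
        with pytest.raises(ValueError):
            DiffusionTensor(np.array([[1.0, 0.1, 0], [0, 1, 0], [0, 0, 1]]))
        with pytest.raises(ValueError):
            DiffusionTensor(np.diag([1.0, 1.0, -0.5]))

    def test_kurtosis_tensor_full_symmetry(self):
        rng = np.random.default_rng(0)
        raw = rng.normal(size=(3, 3, 3, 3))
        with pytest.raises(ValueError):
            KurtosisTensorW(raw)
        W = KurtosisTensorW.from_array(raw, symmetrize=True)
        assert W.tensor[0, 1, 2, 1] == pytest.approx(W.tensor[1, 2, 1, 0])

    def test_from_unique_populates_all_permutations(self):
        W = KurtosisTensorW.from_unique({"xxyz": 0.7})
        assert W.tensor[0, 0, 1, 2] == 0.7
        assert W.tensor[2, 1, 0, 0] == 0.7
        assert W.tensor[0, 0, 0, 0] == 0.0


class TestApparentKurtosis:
    def test_axis_aligned_component(self):
        W = KurtosisTensorW.from_unique({"xxxx": 2.0})
        assert apparent_kurtosis(W, (1, 0, 0)) == pytest.approx(2.0)
        assert apparent_kurtosis(W, (0, 1, 0)) == pytest.approx(0.0)

    def test_nonunit_direction_rejected(self):
        with pytest.raises(ValueError):
            apparent_kurtosis(ISOTROPIC_W, (1.0, 1.0, 0.0))

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        n = np.array([1.0, 1.0, 0.0]) / math.sqrt(2.0)
        for _ in range(20):
            W = random_kurtosis_tensor(rng)
            assert apparent_kurtosis(W, n) == pytest.approx(
                brute_force_apparent_kurtosis(W, n), rel=1e-12, abs=1e-12
            )


class TestMKTTrace:
    def test_single_component(self):
        assert mkt_trace(KurtosisTensorW.from_unique({"xxxx": 5.0})) == pytest.approx(1.0)

    def test_isotropic_form(self):
        lam = 0.7
        W = KurtosisTensorW.from_unique(
            {"xxxx": 3 * lam, "yyyy": 3 * lam, "zzzz": 3 * lam,
             "xxyy": lam, "xxzz": lam, "yyzz": lam}
        )
        assert mkt_trace(W) == pytest.approx(3 * lam)

    def test_isotropic_tensor_has_unit_trace_and_unit_form(self):
        assert mkt_trace(ISOTROPIC_W) == pytest.approx(1.0)
        rng = np.random.default_rng(1)
        for _ in range(10):
            v = rng.normal(size=3)
            v /= np.linalg.norm(v)
            assert apparent_kurtosis(ISOTROPIC_W, v) == pytest.approx(1.0)

    def test_equals_spherical_quadrature(self):
        """(1/5)Tr(W) equals the dense spherical average of W(n)."""
        rng = np.random.default_rng(11)
        # Fibonacci sphere, >= 10k quasi-uniform points.
        m = 10001
        i = np.arange(m)
        phi = math.pi * (3.0 - math.sqrt(5.0)) * i
        z = 1.0 - 2.0 * (i + 0.5) / m
        r = np.sqrt(1.0 - z * z)
        pts = np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)
        for _ in range(5):
            W = random_kurtosis_tensor(rng)
            vals = np.einsum("pi,pj,pk,pl,ijkl->p", pts, pts, pts, pts, W.tensor)
            assert vals.mean() == pytest.approx(mkt_trace(W), abs=1e-3)


class TestForwardModel:
    def test_b_zero_returns_s0(self):
        D = DiffusionTensor.isotropic(0.5)
        assert predict_signal(3.2, 0.0, (1, 0, 0), D, ISOTROPIC_W) == pytest.approx(3.2)

    def test_pure_gaussian_decay(self):
        D = DiffusionTensor.isotropic(0.5)
        W0 = KurtosisTensorW(np.zeros((3, 3, 3, 3)))
        s = predict_signal(1.0, 2.0, (0, 0, 1), D, W0)
        assert s == pytest.approx(math.exp(-1.0))

    def test_kurtosis_term_value(self):
        # MD = 0.5, MKT = 1, b = 1: log(S/s0) = -0.5 + (1/6)(0.25)(1)
        D = DiffusionTensor.isotropic(0.5)
        W = KurtosisTensorW.isotropic(1.0)
        s = predict_signal(1.0, 1.0, (0, 1, 0), D, W)
        assert math.log(s) == pytest.approx(-0.458333333333, abs=1e-10)

    def test_nonpositive_s0_rejected(self):
        with pytest.raises(ValueError):
            predict_signal(0.0, 1.0, (1, 0, 0), DiffusionTensor.isotropic(0.5), ISOTROPIC_W)


class TestLogSumAverage:
    def test_equal_signals_give_zero(self, scheme):
        a, clamped = log_sum_average(np.full(9, 2.0), 2.0, scheme)
        assert a == pytest.approx(0.0)
        assert not clamped

    def test_isotropic_voxel_reduces_to_scalar_equation(self, scheme):
        D = DiffusionTensor.isotropic(0.5)
        W = KurtosisTensorW.isotropic(1.0)
        sig = forward_signals(scheme, D, W)[1:10]
        a, _ = log_sum_average(sig, 1.0, scheme)
        assert a == pytest.approx(-0.458333333333, abs=1e-12)

    def test_anisotropic_rank2_average_is_trace_third(self, scheme):
        D = DiffusionTensor(np.diag([1.5, 0.3, 0.3]))
        W0 = KurtosisTensorW(np.zeros((3, 3, 3, 3)))
        sig = forward_signals(scheme, D, W0)[1:10]
        a, _ = log_sum_average(sig, 1.0, scheme)
        assert a == pytest.approx(-0.7, abs=1e-12)

    def test_clamping_reported(self, scheme):
        sig = np.full(9, 0.5)
        sig[4] = -1.0
        _, clamped = log_sum_average(sig, 1.0, scheme)
        assert clamped


class TestClosedForms:
    def test_md_from_log_averages(self):
        A = LogSignalAverages(A1=-0.5, A2=-1.25, b1=1.0, b2=2.5)
        assert estimate_md_199(A) == pytest.approx(0.5)

    def test_zero_averages_give_zero_md(self):
        A = LogSignalAverages(A1=0.0, A2=0.0, b1=1.0, b2=2.5)
        assert estimate_md_199(A) == pytest.approx(0.0)

    def test_round_trip_values(self):
        A = LogSignalAverages(A1=-0.458333333333, A2=-0.989583333333, b1=1.0, b2=2.5)
        assert estimate_md_199(A) == pytest.approx(0.5, abs=1e-10)
        mkt, degenerate = estimate_mkt_199(A)
        assert not degenerate
        assert mkt == pytest.approx(1.0, abs=1e-8)

    def test_gaussian_diffusion_has_zero_mkt(self):
        A = LogSignalAverages(A1=-0.5, A2=-1.25, b1=1.0, b2=2.5)
        mkt, degenerate = estimate_mkt_199(A)
        assert not degenerate
        assert mkt == pytest.approx(0.0, abs=1e-12)

    def test_zero_decay_is_degenerate(self):
        A = LogSignalAverages(A1=0.0, A2=0.0, b1=1.0, b2=2.5)
        mkt, degenerate = estimate_mkt_199(A)
        assert degenerate
        assert math.isnan(mkt)


class TestEstimateVoxel:
    def test_noiseless_phantom_voxel(self, scheme):
        D = DiffusionTensor.isotropic(0.5)
        W = KurtosisTensorW.isotropic(1.0)
        est = estimate_voxel(forward_signals(scheme, D, W), scheme)
        assert est.flags == QualityFlag.NONE
        assert est.md == pytest.approx(0.5, abs=1e-12)
        assert est.mkt == pytest.approx(1.0, abs=1e-10)

    def test_flat_signals_flagged_degenerate(self, scheme):
        est = estimate_voxel(np.ones(19), scheme)
        assert est.md == pytest.approx(0.0)
        assert QualityFlag.DEGENERATE_DENOMINATOR in est.flags

    def test_zero_s0_all_flagged_no_exception(self, scheme):
        est = estimate_voxel(np.zeros(19), scheme)
        assert QualityFlag.NONPOSITIVE_SIGNAL in est.flags
        assert QualityFlag.DEGENERATE_DENOMINATOR in est.flags
        assert math.isnan(est.md)

    def test_exact_inversion_random_tensors(self, scheme):
        """Noiseless signals invert exactly: MD to 1e-10, MKT to 1e-8."""
        rng = np.random.default_rng(42)
        for _ in range(300):
            D = random_diffusion_tensor(rng)
            W = random_kurtosis_tensor(rng)
            est = estimate_voxel(forward_signals(scheme, D, W), scheme)
            assert abs(est.md - D.md) < 1e-10
            assert abs(est.mkt - mkt_trace(W)) < 1e-8

    def test_out_of_range_mkt_flagged(self, scheme):
        D = DiffusionTensor.isotropic(0.5)
        W = KurtosisTensorW.isotropic(8.0)  # implausibly high
        est = estimate_voxel(forward_signals(scheme, D, W), scheme)
        assert QualityFlag.MKT_OUT_OF_RANGE in est.flags
        assert est.mkt == pytest.approx(8.0, abs=1e-7)  # flagged, not clipped


class TestProperties:
    @given(
        md=st.floats(0.1, 2.0),
        mkt=st.floats(-0.8, 3.0),
        c=st.floats(0.5, 3.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_b_scaling(self, md, mkt, c):
        """Scaling b by c while preserving log-signal scales MD by 1/c and
        leaves MKT invariant."""
        sch1 = make_199_scheme(1.0, 2.5)
        schc = make_199_scheme(1.0 * c, 2.5 * c)
        D = DiffusionTensor.isotropic(md)
        W = KurtosisTensorW.isotropic(mkt)
        sig = forward_signals(sch1, D, W)
        # Same signals attributed to scaled b-values: D -> D/c preserves bD;
        # the kurtosis term (b Dbar)^2 Wbar is then unchanged.
        est = estimate_voxel(sig, schc)
        assert est.md == pytest.approx(md / c, rel=1e-9)
        assert est.mkt == pytest.approx(mkt, rel=1e-6, abs=1e-7)

    def test_vectorized_matches_scalar(self, scheme):
        rng = np.random.default_rng(5)
        sigs = []
        expected = []
        for _ in range(40):
            D = random_diffusion_tensor(rng)
            W = random_kurtosis_tensor(rng)
            sigs.append(forward_signals(scheme, D, W))
            expected.append((D.md, mkt_trace(W)))
        md, mkt, flags = estimate_arrays(np.array(sigs).T, scheme)
        exp = np.array(expected)
        np.testing.assert_allclose(md, exp[:, 0], atol=1e-10)
        np.testing.assert_allclose(mkt, exp[:, 1], atol=1e-8)
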