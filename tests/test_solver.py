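"""Two-level Bregman solver: shrinkage, x-update, inner sweeps, full runs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddtfmri.frames import FrameCoefficients, analysis, haar_init, synthesis
from ddtfmri.sampling import SamplingMask, fft2c, forward, ifft2c, make_mask
from ddtfmri.solver import (
    BregmanState,
    ReconConfig,
    initialize,
    inner_iteration,
    reconstruct,
    shrink,
    x_update,
)


def random_problem(n=16, seed=0, r=2):
    g = np.random.default_rng(seed)

    def carr():
        return g.standard_normal((n, n)) + 1j * g.standard_normal((n, n))

    mask = make_mask((n, n), "random2d", 2.0, seed=seed).mask
    f = fft2c(carr()) * mask
    c = fft2c(carr()) * mask
    bank = haar_init(r)
    v = FrameCoefficients(
        g.standard_normal((r * r, n, n)) + 1j * g.standard_normal((r * r, n, n))
    )
    b = FrameCoefficients(
        g.standard_normal((r * r, n, n)) + 1j * g.standard_normal((r * r, n, n))
    )
    return f, c, mask, v, b, bank


class TestShrink:
    @pytest.mark.parametrize("z,a,want", [
        (0.5, 1.0, 0.0),
        (-3.0, 0.5, -2.5),
        (3j, 1.0, 2j),
        (3 + 4j, 5.0, 0.0),
        (0.0, 1.0, 0.0),
    ])
    def test_pointwise_examples(self, z, a, want):
        out = shrink(np.array([z], dtype=complex), a)
        assert abs(out[0] - want) < 1e-12

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        x=st.floats(-100, 100, allow_nan=False),
        a=st.floats(0.01, 10, allow_nan=False),
    )
    def test_matches_real_soft_threshold_formula(self, x, a):
        want = np.sign(x) * max(0.0, abs(x) - a)
        got = shrink(np.array([x], dtype=complex), a)[0]
        assert got.imag == 0
        assert abs(got.real - want) < 1e-12

    def test_magnitude_phase_decomposition(self, rng):
        z = rng.standard_normal(100) + 1j * rng.standard_normal(100)
        a = 0.7
        got = shrink(z, a)
        want = np.where(np.abs(z) > a, z / np.abs(z) * (np.abs(z) - a), 0.0)
        assert np.abs(got - want).max() < 1e-12

    def test_frame_coefficients_passthrough(self):
        fc = FrameCoefficients(np.full((4, 4, 4), 3j))
        out = shrink(fc, 1.0)
        assert isinstance(out, FrameCoefficients)
        np.testing.assert_allclose(out.subbands, np.full((4, 4, 4), 2j))

    def test_rejects_nonpositive_threshold(self):
        with pytest.raises(ValueError):
            shrink(np.zeros(3, dtype=complex), 0.0)


class TestXUpdate:
    def test_empty_mask_returns_synthesis(self):
        f, c, _, v, b, bank = random_problem(seed=1)
        mask = np.zeros_like(f, dtype=bool)
        x = x_update(np.zeros_like(f), np.zeros_like(f), mask, v, b, bank, 10, 10)
        diff = FrameCoefficients(v.subbands - b.subbands)
        want = synthesis(bank, diff)
        assert np.abs(x - want).max() < 1e-12

    def test_mu_equals_lam_averages_on_mask(self):
        f, c, mask, v, b, bank = random_problem(seed=2)
        x = x_update(f, c, mask, v, b, bank, mu=7.0, lam=7.0)
        s1 = f - c
        s2 = fft2c(synthesis(bank, FrameCoefficients(v.subbands - b.subbands)))
        khat = fft2c(x)
        np.testing.assert_allclose(khat[mask], ((s1 + s2) / 2)[mask], atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_satisfies_normal_equations(self, seed):
        f, c, mask, v, b, bank = random_problem(seed=seed)
        mu, lam = 10.0, 10.0
        x = x_update(f, c, mask, v, b, bank, mu, lam)
        # (mu F_p^H F_p + lam I) x = mu F_p^H (f - c) + lam W^H (v - b)
        lhs = mu * ifft2c(fft2c(x) * mask) + lam * x
        rhs = mu * ifft2c((f - c) * mask) + lam * synthesis(
            bank, FrameCoefficients(v.subbands - b.subbands)
        )
        assert np.linalg.norm(lhs - rhs) / np.linalg.norm(rhs) < 1e-8

    def test_rejects_bad_parameters(self):
        f, c, mask, v, b, bank = random_problem(seed=3)
        with pytest.raises(ValueError):
            x_update(f, c, mask, v, b, bank, -1.0, 10.0)
        with pytest.raises(ValueError):
            x_update(f, c, mask[:8], v, b, bank, 10.0, 10.0)


class TestInnerIteration:
    def make_state(self, n=32, seed=4, learn=True):
        g = np.random.default_rng(seed)
        x = g.standard_normal((n, n)) + 1j * g.standard_normal((n, n))
        mask = make_mask((n, n), "radial", 3.0, seed=seed).mask
        f = fft2c(x) * mask
        cfg = ReconConfig(r=4, learn_filters=learn)
        from ddtfmri.sampling import KSpaceSample

        sample = KSpaceSample(f, SamplingMask(mask, "radial", 3.0))
        return initialize(sample, cfg), f, mask, cfg

    def test_huge_lambda_passes_coefficients_through(self):
        state, f, mask, _ = self.make_state()
        cfg = ReconConfig(r=4, lam=1e8, learn_filters=False)
        new = inner_iteration(state, f, mask, cfg)
        wx = analysis(new.bank, new.x)
        target = wx.subbands + state.b.subbands
        assert np.abs(new.v.subbands - target).max() < 1e-6

    def test_learn_filters_off_keeps_bank(self):
        state, f, mask, cfg = self.make_state(learn=False)
        cfg = ReconConfig(r=4, learn_filters=False)
        new = inner_iteration(state, f, mask, cfg)
        np.testing.assert_array_equal(new.bank.filters, state.bank.filters)

    def test_dual_update_identity_exact(self):
        state, f, mask, cfg = self.make_state(learn=True)
        new = inner_iteration(state, f, mask, cfg)
        wx = analysis(new.bank, new.x)
        want = state.b.subbands + cfg.delta_b * (wx.subbands - new.v.subbands)
        np.testing.assert_array_equal(new.b.subbands, want)

    def test_counters_advance(self):
        state, f, mask, cfg = self.make_state()
        new = inner_iteration(state, f, mask, cfg)
        assert new.m_inner == state.m_inner + 1


class TestReconstruct:
    def test_fully_sampled_recovers_inverse_fft(self):
        # image-scale data: the shrinkage threshold 1/lam is negligible
        # relative to [0, 255] magnitudes, so the data term dominates
        from ddtfmri.phantoms import shepp_logan

        x_true = shepp_logan(n=32, seed=5).image
        mask = SamplingMask(np.ones((32, 32), dtype=bool), "full", 1.0)
        sample = forward(x_true, mask)
        cfg = ReconConfig(r=4, K=3, M=2)
        x, diag = reconstruct(sample, cfg)
        assert np.linalg.norm(x - x_true) / np.linalg.norm(sample.f) < 1e-3
        # the outer dual can overshoot between consecutive steps (inner
        # problems are solved inexactly); the residual decays in aggregate
        res = [row["residual"] for row in diag["iterations"]]
        assert res[-1] < 0.25 * res[0]

    def test_outer_dual_update_identity(self, complex_image):
        x_true = complex_image((32, 32), seed=6)
        mask = make_mask((32, 32), "radial", 3.0, seed=6)
        sample = forward(x_true, mask)
        cfg = ReconConfig(r=4, K=2, M=1)
        # step manually and verify delta-c after each outer iteration
        state = initialize(sample, cfg)
        c_prev = state.c.copy()
        for _ in range(cfg.M):
            state = inner_iteration(state, sample.f, mask.mask, cfg)
        resid = fft2c(state.x) * mask.mask - sample.f
        c_new = c_prev + cfg.delta_c * resid
        x, diag = reconstruct(sample, ReconConfig(r=4, K=1, M=1))
        np.testing.assert_array_equal(diag["state"].c, c_new)

    def test_bit_identical_reruns(self, complex_image):
        x_true = complex_image((32, 32), seed=7)
        mask = make_mask((32, 32), "radial", 3.0, seed=7)
        sample = forward(x_true, mask)
        cfg = ReconConfig(r=4, K=2, M=2)
        xa, da = reconstruct(sample, cfg)
        xb, db = reconstruct(sample, cfg)
        np.testing.assert_array_equal(xa, xb)
        assert da["iterations"] == db["iterations"]

    def test_diagnostics_include_metrics_with_ground_truth(self, complex_image):
        x_true = complex_image((32, 32), seed=8)
        mask = make_mask((32, 32), "radial", 3.0, seed=8)
        sample = forward(x_true, mask)
        x, diag = reconstruct(sample, ReconConfig(r=4, K=2, M=1), ground_truth=x_true)
        rows = diag["iterations"]
        assert len(rows) == 2
        assert {"k", "residual", "psnr", "hfen", "ssim"} <= set(rows[0])


class TestReconConfig:
    @pytest.mark.parametrize("field,value", [
        ("delta_c", 2.5),
        ("delta_c", 0.0),
        ("delta_b", 0.0),
        ("delta_b", 1.5),
        ("mu", -1.0),
        ("lam", 0.0),
        ("M", 0),
        ("K", 0),
    ])
    def test_bounds_enforced(self, field, value):
        with pytest.raises(ValueError):
            ReconConfig(**{field: value})

    def test_dict_roundtrip(self):
        cfg = ReconConfig(mu=5.0, K=7)
        assert ReconConfig.from_dict(cfg.to_dict()) == cfg

    def test_unknown_field_rejected(self):
        with pytest.raises(ValueError):
            ReconConfig.from_dict({"muu": 1.0})
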