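"""Multiresolution Hermite optical flow: pyramid, warping, solver."""

import numpy as np
import pytest

import hermiteflow as hf
from hermiteflow.flow import (
    ConstraintChannels,
    FlowField,
    _raised_gradients,
    solve_increment,
)
from hermiteflow.hermite import build_filter_bank, forward_transform
from hermiteflow.steering import estimate_orientation, steer

from conftest import make_smooth_volume


class TestPyramid:
    def test_shapes_and_clipping(self, caplog):
        vol = np.zeros((64, 64, 64))
        with caplog.at_level("WARNING", logger="hermiteflow"):
            pyr = hf.build_pyramid(vol, levels=5)
        assert [p.shape[0] for p in pyr] == [64, 32, 16, 8]
        assert "clipped" in caplog.text

    def test_constant_volume_stays_constant(self):
        pyr = hf.build_pyramid(np.full((32, 32, 32), 5.0), levels=3)
        for level in pyr:
            assert np.allclose(level, 5.0)

    def test_no_aliasing_amplification(self):
        vol = make_smooth_volume((48, 48, 48), seed=13, smooth=1.0)
        pyr = hf.build_pyramid(vol, levels=3)
        variances = [np.var(p) for p in pyr]
        assert variances[1] <= variances[0]
        assert variances[2] <= variances[1]


class TestWarp:
    def test_zero_flow_is_identity(self, smooth_volume):
        flow = FlowField.zeros(smooth_volume.shape)
        assert np.array_equal(hf.warp(smooth_volume, flow), smooth_volume)

    def test_integer_shift_matches_roll(self, smooth_volume):
        flow = FlowField(
            (np.ones(smooth_volume.shape), np.zeros(smooth_volume.shape),
             np.zeros(smooth_volume.shape))
        )
        warped = hf.warp(smooth_volume, flow)
        rolled = np.roll(smooth_volume, -1, axis=0)
        assert np.allclose(warped[:-1], rolled[:-1])

    def test_half_voxel_shift_of_ramp_is_exact(self):
        ramp = np.arange(16.0)[:, None, None] * np.ones((16, 16, 16))
        flow = FlowField(
            (np.full(ramp.shape, 0.5), np.zeros(ramp.shape), np.zeros(ramp.shape))
        )
        warped = hf.warp(ramp, flow)
        assert np.allclose(warped[:-1], ramp[:-1] + 0.5)

    def test_shape_mismatch_rejected(self, smooth_volume):
        with pytest.raises(ValueError):
            hf.warp(smooth_volume, FlowField.zeros((4, 4, 4)))


class TestTemporalDifferences:
    def test_identical_volumes_zero_differences(self, smooth_volume):
        bank = build_filter_bank(4, 5, ndim=3)
        c = forward_transform(smooth_volume, bank)
        ch = hf.temporal_differences(c, c, hf.FlowParams())
        for diff in ch.diffs:
            assert np.abs(diff).max() < 1e-12

    def test_constant_offset_hits_only_dc(self, smooth_volume):
        bank = build_filter_bank(4, 5, ndim=3)
        c0 = forward_transform(smooth_volume, bank)
        c1 = forward_transform(smooth_volume + 3.0, bank)
        ch = hf.temporal_differences(c0, c1, hf.FlowParams())
        assert np.allclose(ch.diffs[0], 3.0)  # DC gain is 1
        for diff in ch.diffs[1:]:
            assert np.abs(diff).max() < 1e-9

    def test_channel_count_and_weights(self, smooth_volume):
        bank = build_filter_bank(4, 5, ndim=3)
        c = forward_transform(smooth_volume, bank)
        params = hf.FlowParams(gamma=100.0)
        ch = hf.temporal_differences(c, c, params)
        # DC + orders 1..3: 1 + (3 + 6 + 10)
        assert len(ch.diffs) == 20
        assert ch.weights[0] == 1.0
        assert np.allclose(ch.weights[1:], 100.0 / 19)

    def test_grid_mismatch_rejected(self, smooth_volume):
        bank = build_filter_bank(4, 5, ndim=3)
        c0 = forward_transform(smooth_volume, bank)
        c1 = forward_transform(smooth_volume[:-2], bank)
        with pytest.raises(ValueError):
            hf.temporal_differences(c0, c1, hf.FlowParams())


class TestAssembleSystem:
    @staticmethod
    def _dc_channels(vol_a, vol_b, params):
        bank = build_filter_bank(4, 5, ndim=3)
        ct = forward_transform(vol_a, bank)
        cw = forward_transform(vol_b, bank)
        return ct, cw, hf.temporal_differences(ct, cw, params)

    def test_gamma_zero_matches_horn_schunck_assembly(self, smooth_volume):
        """Independent oracle: structure tensor of the order-0 channel
        plus alpha on the diagonal."""
        params = hf.FlowParams(gamma=0.0, alpha=7.0)
        vol_b = np.roll(smooth_volume, 1, axis=1)
        ct, cw, ch = self._dc_channels(smooth_volume, vol_b, params)
        flow = FlowField.zeros(smooth_volume.shape)
        system = hf.assemble_system(ch, flow, params)

        bank = cw.bank
        r0 = bank.raise_factors[0]
        g = [r0 * cw[idx] for idx in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]]
        it = cw[(0, 0, 0)] - ct[(0, 0, 0)]
        for i in range(3):
            for j in range(3):
                expected = g[i] * g[j] + (7.0 if i == j else 0.0)
                assert np.allclose(system.A[i, j], expected)
            assert np.allclose(system.b_static[i], -it * g[i])

    def test_data_term_symmetric(self, smooth_volume):
        params = hf.FlowParams()
        vol_b = np.roll(smooth_volume, 1, axis=0)
        _, _, ch = self._dc_channels(smooth_volume, vol_b, params)
        system = hf.assemble_system(ch, FlowField.zeros(smooth_volume.shape), params)
        assert np.array_equal(system.A[0, 1], system.A[1, 0])
        assert np.array_equal(system.A[0, 2], system.A[2, 0])
        assert np.array_equal(system.A[1, 2], system.A[2, 1])
        assert (system.A[0, 0] >= 0).all()

    def test_zero_volumes_alpha_diagonal_only(self):
        zeros = np.zeros((10, 10, 10))
        params = hf.FlowParams(alpha=4.0)
        _, _, ch = self._dc_channels(zeros, zeros, params)
        system = hf.assemble_system(ch, FlowField.zeros(zeros.shape), params)
        for i in range(3):
            for j in range(3):
                assert np.allclose(system.A[i, j], 4.0 if i == j else 0.0)
        assert np.abs(system.b_static).max() < 1e-12

    def test_named_entry_accessors(self, smooth_volume):
        params = hf.FlowParams()
        _, _, ch = self._dc_channels(smooth_volume, smooth_volume, params)
        system = hf.assemble_system(ch, FlowField.zeros(smooth_volume.shape), params)
        assert np.array_equal(system.A1, system.A[0, 0])
        assert np.array_equal(system.A9, system.A[2, 2])
        assert np.array_equal(system.b2, system.b_static[1])

    def test_system_invariant_under_explicit_steering(self, smooth_volume):
        """Dual route: assembling from coefficients steered to the first
        volume's orientation gives the same normal equations."""
        params = hf.FlowParams(gamma=100.0, alpha=10.0)
        vol_b = np.roll(smooth_volume, 1, axis=0)
        bank = build_filter_bank(4, 5, ndim=3)
        ct = forward_transform(smooth_volume, bank)
        cw = forward_transform(vol_b, bank)
        flow = FlowField.zeros(smooth_volume.shape)
        system = hf.assemble_system(
            hf.temporal_differences(ct, cw, params), flow, params
        )

        orient = estimate_orientation(ct)
        st_t = steer(ct, orient)
        st_w = steer(cw, orient)
        ch = ConstraintChannels()
        dc = (0, 0, 0)
        r0 = bank.raise_factors[0]
        ch.append(
            cw[dc] - ct[dc],
            tuple(r0 * cw[idx] for idx in [(1, 0, 0), (0, 1, 0), (0, 0, 1)]),
            1.0,
        )
        n_channels = sum(len(ct.order(n)) for n in range(1, 4))
        stacks_by_order = {n: _raised_gradients(cw, n) for n in range(1, 4)}
        for n in range(1, 4):
            # steering the raised derivative stacks with the same frozen
            # angles rotates them exactly like the coefficients
            steered_stacks = [
                steer(
                    hf.HermiteCoefficients(
                        coeffs=dict(stacks_by_order[n][ax]), order_max=n,
                        sigma=ct.sigma, stride=1,
                        source_shape=ct.source_shape, window_size=5,
                    ),
                    orient,
                )
                for ax in range(3)
            ]
            for q in sorted(ct.order(n)):
                ch.append(
                    st_w[q] - st_t[q],
                    tuple(s[q] for s in steered_stacks),
                    100.0 / n_channels,
                )
        system_steered = hf.assemble_system(ch, flow, params)
        scale = np.abs(system.A).max()
        assert np.abs(system.A - system_steered.A).max() < 1e-9 * scale
        bscale = max(np.abs(system.b_static).max(), 1.0)
        assert np.abs(system.b_static - system_steered.b_static).max() < 1e-9 * bscale


class TestSolveIncrement:
    def test_fixed_point_satisfies_global_system(self, smooth_volume):
        params = hf.FlowParams(
            iterations=400, solver_tolerance=1e-13, solver="jacobi"
        )
        vol_b = np.roll(smooth_volume, 1, axis=0)
        bank = build_filter_bank(4, 5, ndim=3)
        ct = forward_transform(smooth_volume, bank)
        cw = forward_transform(vol_b, bank)
        ch = hf.temporal_differences(ct, cw, params)
        system = hf.assemble_system(ch, FlowField.zeros(smooth_volume.shape), params)
        incr = solve_increment(system, params)
        from hermiteflow.flow import _neighbor_average

        for i in range(3):
            lhs = sum(system.A[i, j] * incr[j] for j in range(3))
            rhs = system.b_static[i] + params.alpha * _neighbor_average(incr[i])
            assert np.abs(lhs - rhs).max() < 1e-6

    def test_residual_nonincreasing_over_iterations(self, smooth_volume):
        vol_b = np.roll(smooth_volume, 1, axis=0)
        bank = build_filter_bank(4, 5, ndim=3)
        ct = forward_transform(smooth_volume, bank)
        cw = forward_transform(vol_b, bank)
        base = hf.FlowParams(solver="jacobi")
        ch = hf.temporal_differences(ct, cw, base)
        system = hf.assemble_system(ch, FlowField.zeros(smooth_volume.shape), base)
        from hermiteflow.flow import _neighbor_average

        def residual(incr):
            r = 0.0
            for i in range(3):
                lhs = sum(system.A[i, j] * incr[j] for j in range(3))
                rhs = system.b_static[i] + base.alpha * _neighbor_average(incr[i])
                r += float(np.sum((lhs - rhs) ** 2))
            return np.sqrt(r)

        res = [
            residual(
                solve_increment(
                    system,
                    hf.FlowParams(iterations=k, solver="jacobi", solver_tolerance=0.0),
                )
            )
            for k in (1, 3, 10, 30)
        ]
        assert all(res[i + 1] <= res[i] * (1 + 1e-12) for i in range(len(res) - 1))

    def test_gauss_seidel_converges_to_same_fixed_point(self, smooth_volume):
        vol_b = np.roll(smooth_volume, 1, axis=0)
        bank = build_filter_bank(4, 5, ndim=3)
        ct = forward_transform(smooth_volume, bank)
        cw = forward_transform(vol_b, bank)
        p = hf.FlowParams(iterations=600, solver_tolerance=1e-13)
        ch = hf.temporal_differences(ct, cw, p)
        system = hf.assemble_system(ch, FlowField.zeros(smooth_volume.shape), p)
        gs = solve_increment(system, p)
        jac = solve_increment(
            system, hf.FlowParams(iterations=600, solver="jacobi", solver_tolerance=1e-13)
        )
        assert max(np.abs(g - j).max() for g, j in zip(gs, jac)) < 1e-4


class TestEstimateFlow:
    def test_identical_volumes_give_zero_flow(self):
        vol = make_smooth_volume((24, 24, 24), seed=21)
        flow = hf.estimate_flow(vol, vol, hf.FlowParams(levels=2, iterations=20))
        assert np.abs(flow.magnitude()).max() < 1e-3

    def test_translation_recovered(self):
        spec = hf.PhantomSpec(
            kind="translation", shape=(32, 32, 32), amplitude=1.0,
            phases=2, seed=3,
        )
        (a, b), gts = hf.generate(spec)
        flow = hf.estimate_flow(a, b, hf.FlowParams(levels=3))
        assert hf.endpoint_error(flow, gts[0]) < 0.2
        core = (slice(4, -4),) * 3
        assert abs(flow.u[core].mean() - 1.0) < 0.2
        assert abs(flow.v[core].mean()) < 0.1

    def test_axis_permutation_equivariance(self):
        spec = hf.PhantomSpec(
            kind="translation", shape=(24, 24, 24), amplitude=1.0,
            phases=2, seed=4,
        )
        (a, b), _ = hf.generate(spec)
        p = hf.FlowParams(levels=1, iterations=20, warps_per_level=1)
        f0 = hf.estimate_flow(a, b, p)
        f1 = hf.estimate_flow(a.transpose(2, 0, 1), b.transpose(2, 0, 1), p)
        # axis 0 of the original is axis 1 of the permuted volume
        assert np.allclose(f0.u, f1.components[1].transpose(1, 2, 0), atol=1e-10)

    def test_alpha_increases_smoothness(self):
        spec = hf.PhantomSpec(
            kind="rotation", shape=(24, 24, 24), amplitude=1.5,
            phases=2, seed=6,
        )
        (a, b), _ = hf.generate(spec)

        def tv(flow):
            return sum(
                float(np.sum(np.abs(g)))
                for c in flow.components
                for g in np.gradient(c)
            )

        lo = hf.estimate_flow(a, b, hf.FlowParams(levels=2, alpha=2.0))
        hi = hf.estimate_flow(a, b, hf.FlowParams(levels=2, alpha=50.0))
        assert tv(hi) < tv(lo)

    def test_shape_mismatch_and_bad_dimensionality(self):
        with pytest.raises(ValueError):
            hf.estimate_flow(np.zeros((8, 8, 8)), np.zeros((8, 8, 9)))
        with pytest.raises(ValueError):
            hf.estimate_flow(np.zeros(64), np.zeros(64))

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            hf.FlowParams(alpha=0.0)
        with pytest.raises(ValueError):
            hf.FlowParams(levels=0)
        with pytest.raises(ValueError):
            hf.FlowParams(solver="sor")
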