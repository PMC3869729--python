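"""Mesh construction, likelihood evaluation and MAP fitting."""

import numpy as np
import pytest
from scipy import optimize, stats

from trajmode import (
    ModeSchedule,
    ModelLabel,
    ModelParams,
    PolynomialPotential,
    SimConfig,
    Trajectory,
    build_mesh,
    estimate_D_msd,
    log_likelihood,
    map_fit,
    simulate,
)
from trajmode.models import monomials


def _traj(x, y, dt=0.05):
    x = np.asarray(x, float)
    return Trajectory(np.arange(x.size) * dt, x, np.asarray(y, float))


class TestMesh:
    def test_corner_points_in_corner_bins(self):
        x = [0.0, 1.0, 0.0, 1.0, 0.5]
        y = [0.0, 0.0, 1.0, 1.0, 0.5]
        mesh = build_mesh(_traj(x, y), n_bins=10)
        got = set(zip(mesh.ix.tolist(), mesh.iy.tolist()))
        assert {(0, 0), (9, 0), (0, 9), (9, 9)} <= got

    def test_degenerate_extent_single_bin(self):
        mesh = build_mesh(_traj([0.3] * 5, [0.3] * 5), n_bins=10)
        assert len(set(zip(mesh.ix.tolist(), mesh.iy.tolist()))) == 1
        assert mesh.edges_x[0] < 0.3 < mesh.edges_x[-1]

    def test_occupancy_partitions_steps(self, mixed_trajs):
        for traj in mixed_trajs[:3]:
            mesh = build_mesh(traj)
            assert mesh.occupancy.sum() == traj.n_frames - 1


class TestLogLikelihood:
    def test_two_frames_is_single_step_density(self):
        from trajmode.models import step_log_density

        traj = _traj([0.0, 0.12], [0.0, -0.03])
        params = ModelParams(D=0.1, sigma=0.02)
        ll = log_likelihood(traj, ModelLabel.FREE, params)
        expected = step_log_density((0.12, -0.03), 0.05, 0.1, sigma=0.02)
        assert ll == pytest.approx(expected, rel=1e-12)

    def test_free_equals_bruteforce_gaussian_product(self, free_traj_500):
        traj = free_traj_500.window(0, 50)
        D, sigma = 0.08, 0.02
        ll = log_likelihood(traj, ModelLabel.FREE, ModelParams(D=D, sigma=sigma))
        # independent route: product of per-axis normal densities
        var = 2.0 * (D + sigma**2 / traj.dt) * traj.dt
        dr = traj.displacements
        expected = float(
            stats.norm.logpdf(dr[:, 0], 0.0, np.sqrt(var)).sum()
            + stats.norm.logpdf(dr[:, 1], 0.0, np.sqrt(var)).sum()
        )
        assert ll == pytest.approx(expected, abs=1e-10)

    def test_free_translation_invariance(self, free_traj_500):
        traj = free_traj_500.window(0, 100)
        params = ModelParams(D=0.1)
        a = log_likelihood(traj, ModelLabel.FREE, params)
        b = log_likelihood(traj.translated(12.3, -4.5), ModelLabel.FREE, params)
        assert a == pytest.approx(b, rel=1e-12)


class TestMapFit:
    def test_free_fit_matches_closed_form_mle(self, free_traj_500):
        fit = map_fit(free_traj_500, ModelLabel.FREE, sigma=0.0)
        assert fit.D == pytest.approx(estimate_D_msd(free_traj_500), rel=1e-6)
        assert fit.converged

    def test_parameter_counts(self, spring_traj_long):
        traj = spring_traj_long.window(0, 200)
        ks = [
            map_fit(traj, model).n_params
            for model in (ModelLabel.FREE, ModelLabel.SPRING2, ModelLabel.QUARTIC4)
        ]
        assert ks == [1, 6, 15]

    def test_spring_constant_recovery(self):
        # median recovered k within 20% of truth at N = 2000, at the default
        # study spring constant (0.3 pN/um ~= 70 kBT/um^2).  Much weaker
        # springs (relaxation time approaching the trajectory length) carry
        # the classic upward drift-rate MLE bias; see docs/methods.md.
        from trajmode.defaults import K_KT

        pot = PolynomialPotential.spring(K_KT)
        k_hats = []
        for seed in range(50):
            cfg = SimConfig(D=0.1, dt=0.05, n_frames=2000, sigma=0.0, seed=1000 + seed)
            traj = simulate(cfg, ModeSchedule.confined(2000, pot))
            fit = map_fit(traj, ModelLabel.SPRING2, sigma=0.0)
            c = fit.params.potential.coeffs
            k_hats.append(c[(2, 0)] + c[(0, 2)])
        assert np.median(k_hats) == pytest.approx(K_KT, rel=0.20)

    def test_nested_likelihood_ordering(self, mixed_trajs):
        for traj in mixed_trajs:
            lm = {
                m: map_fit(traj, m, sigma=0.03).log_map
                for m in (ModelLabel.FREE, ModelLabel.SPRING2, ModelLabel.QUARTIC4)
            }
            assert lm[ModelLabel.QUARTIC4] >= lm[ModelLabel.SPRING2] - 1e-6
            assert lm[ModelLabel.SPRING2] >= lm[ModelLabel.FREE] - 1e-6

    def test_frame_offset_invariance(self, spring_traj_long):
        traj = spring_traj_long.window(0, 300)
        shifted = Trajectory(traj.t + 12.0, traj.x, traj.y)
        for model in (ModelLabel.FREE, ModelLabel.SPRING2):
            a = map_fit(traj, model, sigma=0.01)
            b = map_fit(shifted, model, sigma=0.01)
            assert a.log_map == pytest.approx(b.log_map, rel=1e-12)
            assert a.D == pytest.approx(b.D, rel=1e-12)

    def test_reproducibility(self, spring_traj_long):
        a = map_fit(spring_traj_long, ModelLabel.SPRING2, sigma=0.02)
        b = map_fit(spring_traj_long, ModelLabel.SPRING2, sigma=0.02)
        assert a.log_map == b.log_map
        assert a.params.potential.coeffs == b.params.potential.coeffs

    def test_short_trajectory_warns(self):
        traj = _traj(np.linspace(0, 1, 5), np.zeros(5))
        with pytest.warns(UserWarning, match="below 10 frames"):
            map_fit(traj, ModelLabel.FREE)

    def test_closed_form_map_beats_iterative_optimizer(self, spring_traj_long):
        """Independent route: numeric optimization over (log D, coefficients)
        of the same likelihood must not exceed the closed-form MAP, and
        should approach it."""
        traj = spring_traj_long.window(0, 150)
        sigma = 0.0
        fit = map_fit(traj, ModelLabel.SPRING2, sigma=sigma)
        mesh = build_mesh(traj, n_bins=10, sigma=sigma)
        center = tuple(mesh.step_centers.mean(axis=0))
        monos = monomials(2)

        def neg_ll(theta):
            D = np.exp(theta[0])
            coeffs = {m: c for m, c in zip(monos, theta[1:])}
            params = ModelParams(
                D=D,
                potential=PolynomialPotential(order=2, coeffs=coeffs),
                sigma=sigma,
                center=center,
            )
            return -log_likelihood(traj, ModelLabel.SPRING2, params, mesh)

        x0 = np.concatenate([[np.log(max(estimate_D_msd(traj), 1e-6))], np.zeros(5)])
        res = optimize.minimize(neg_ll, x0, method="Nelder-Mead",
                                options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-10})
        res = optimize.minimize(neg_ll, res.x, method="BFGS")
        assert fit.log_map >= -res.fun - 1e-6
        assert fit.log_map == pytest.approx(-res.fun, abs=0.05)

    def test_degenerate_input_clamps_D(self):
        traj = _traj(np.zeros(30), np.zeros(30))
        fit = map_fit(traj, ModelLabel.FREE)
        assert not fit.converged
        assert fit.D <= 1e-12
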