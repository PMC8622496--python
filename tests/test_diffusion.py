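"""Generator matrix, steady states, PDE simulation, convolution, fitting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from swimstack.diffusion import (DetectionKernel, DiffusionModelSpec,
                                 build_generator_matrix, convolve_detection,
                                 detection_matrix, fit_from_observed,
                                 map_alpha_to_m, map_m_to_alpha, simulate_pde,
                                 simulate_to_steady, steady_state_analytic,
                                 steady_state_nullspace)

DILUTE_M = (0.271930, 0.543860)   # dilute suspension fit
DENSE_M = (0.780702, 0.936842)    # dense suspension fit


def boundary_m(m_solid, m_air, J=21):
    m = np.ones(J)
    m[0], m[-1] = m_solid, m_air
    return m


random_m = st.lists(st.floats(0.1, 5.0), min_size=3, max_size=25)


class TestGenerator:
    def test_three_site_rows_match_update_rule(self):
        spec = DiffusionModelSpec(m=np.ones(3), D=1.0, dz=1.0, dt=0.25)
        A = build_generator_matrix(spec)
        expected = np.array([[-1.0, 1.0, 0.0],
                             [1.0, -2.0, 1.0],
                             [0.0, 1.0, -1.0]])
        np.testing.assert_allclose(A, expected)

    @given(random_m)
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_mass_conservation_algebraic(self, m):
        """Column sums of the generator vanish: sum(dc/dt) = 0 for any c."""
        spec = DiffusionModelSpec(m=np.array(m), D=0.001, dz=0.05, dt=0.005)
        A = build_generator_matrix(spec)
        np.testing.assert_allclose(A.sum(axis=0), 0.0, atol=1e-12)

    def test_steady_vector_is_annihilated(self):
        m = boundary_m(*DILUTE_M)
        A = build_generator_matrix(DiffusionModelSpec(m=m))
        np.testing.assert_allclose(A @ steady_state_analytic(m), 0.0, atol=1e-15)

    def test_small_J_rejected(self):
        with pytest.raises(ValueError, match=">= 3"):
            DiffusionModelSpec(m=np.array([1.0, 1.0]))

    def test_stability_guard(self):
        with pytest.raises(ValueError, match="unstable"):
            DiffusionModelSpec(m=np.ones(5), D=1.0, dz=0.05, dt=0.005)


class TestSteadyStates:
    def test_uniform_m_gives_flat_profile(self):
        np.testing.assert_allclose(steady_state_analytic(np.ones(21)), 1 / 21)

    def test_dilute_suspension_boundary_probabilities(self):
        """m = (0.2719, 0.5439) reproduces bottom 0.15 / top 0.075."""
        p = steady_state_analytic(boundary_m(*DILUTE_M))
        assert p[0] == pytest.approx(0.15, abs=5e-4)
        assert p[-1] == pytest.approx(0.075, abs=5e-4)

    def test_dense_suspension_boundary_probabilities(self):
        p = steady_state_analytic(boundary_m(*DENSE_M))
        assert p[0] == pytest.approx(0.060, abs=5e-4)
        assert p[-1] == pytest.approx(0.050, abs=5e-4)

    def test_direct_five_site_example(self):
        p = steady_state_analytic(np.array([0.5, 1, 1, 1, 0.25]))
        np.testing.assert_allclose(p, [2 / 9, 1 / 9, 1 / 9, 1 / 9, 4 / 9])

    @given(random_m)
    @settings(deadline=None, max_examples=60, derandomize=True)
    def test_nullspace_oracle_matches_closed_form(self, m):
        m = np.array(m)
        spec = DiffusionModelSpec(m=m, D=0.001, dz=0.05, dt=0.005)
        p_null = steady_state_nullspace(build_generator_matrix(spec))
        np.testing.assert_allclose(p_null, steady_state_analytic(m), atol=1e-10)

    def test_interior_permutation_irrelevant(self):
        m = boundary_m(0.5, 0.25, J=8)
        p = steady_state_analytic(m)
        assert np.allclose(p[1:-1], p[1])  # interior sites interchangeable

    def test_monotone_link_m_solid_to_bottom_probability(self):
        probs = [steady_state_analytic(boundary_m(ms, 0.5))[0]
                 for ms in (1.0, 0.5, 0.25, 0.125)]
        assert np.all(np.diff(probs) > 0)


class TestSimulation:
    def test_flat_steady_state_from_random_start(self):
        rng = np.random.default_rng(0)
        c0 = rng.uniform(0.5, 1.5, 21)
        spec = DiffusionModelSpec(m=np.ones(21), t_total=2000.0)
        final = simulate_to_steady(spec, c0=c0)
        np.testing.assert_allclose(final / final.sum(), 1 / 21, atol=1e-6)

    def test_reference_run_converges_to_bimodal_steady_state(self):
        """D=0.001, dz=0.05, dt=0.005 from a random start reaches the
        analytic bimodal profile (L1 < 1e-3) at per-step stationarity."""
        m = boundary_m(*DILUTE_M)
        rng = np.random.default_rng(1)
        c0 = rng.uniform(0.2, 1.0, 21)
        c0 /= c0.sum()
        final = simulate_to_steady(DiffusionModelSpec(m=m), c0=c0)
        assert np.abs(final - steady_state_analytic(m)).sum() < 1e-3

    def test_l1_distance_decreases_in_time(self):
        m = boundary_m(*DILUTE_M)
        rng = np.random.default_rng(2)
        c0 = rng.uniform(0.2, 1.0, 21)
        c0 /= c0.sum()
        traj = simulate_pde(c0, DiffusionModelSpec(m=m, t_total=300.0),
                            steady_tol=0.0, save_every=6000)
        steady = steady_state_analytic(m)
        dists = [np.abs(p - steady).sum() for p in traj.profiles]
        assert np.all(np.diff(dists) < 0)

    def test_mass_conserved_over_horizon(self):
        m = boundary_m(0.3, 0.7)
        rng = np.random.default_rng(3)
        c0 = rng.uniform(0.2, 1.0, 21)
        traj = simulate_pde(c0, DiffusionModelSpec(m=m, t_total=300.0),
                            steady_tol=0.0)
        assert abs(traj.final.sum() - c0.sum()) / c0.sum() < 1e-9

    def test_three_routes_to_stationarity_agree(self):
        m = boundary_m(0.4, 0.8, J=15)
        spec = DiffusionModelSpec(m=m)
        closed = steady_state_analytic(m)
        null = steady_state_nullspace(build_generator_matrix(spec))
        sim = simulate_to_steady(spec)
        assert np.abs(closed - null).max() < 1e-6
        assert np.abs(sim / sim.sum() - closed).sum() < 1e-3

    def test_unstable_step_reported(self):
        with pytest.raises(ValueError, match="unstable"):
            DiffusionModelSpec(m=boundary_m(1.0, 1.0), dt=2.0)


class TestAlphaMapping:
    def test_forward_map(self):
        m = map_alpha_to_m(2.0, 4.0, J=21)
        assert (m[0], m[-1]) == (0.5, 0.25)
        assert np.all(m[1:-1] == 1.0)

    def test_round_trip_exact(self):
        a_s, a_a = map_m_to_alpha(map_alpha_to_m(3.7, 1.9, J=9))
        assert a_s == pytest.approx(3.7, rel=1e-15)
        assert a_a == pytest.approx(1.9, rel=1e-15)
        # powers of two invert exactly
        assert map_m_to_alpha(map_alpha_to_m(4.0, 2.0, J=9)) == (4.0, 2.0)

    def test_unit_alphas_give_flat_steady(self):
        p = steady_state_analytic(map_alpha_to_m(1.0, 1.0, J=11))
        np.testing.assert_allclose(p, 1 / 11)

    def test_nonpositive_alpha_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            map_alpha_to_m(0.0, 1.0)


class TestConvolution:
    def test_delta_at_edge_truncated(self):
        out = convolve_detection(np.array([1.0, 0, 0, 0, 0]))
        np.testing.assert_allclose(out, [1, 1, 0, 0, 0])

    def test_flat_profile_edges_doubled(self):
        out = convolve_detection(np.ones(6))
        np.testing.assert_allclose(out, [2, 3, 3, 3, 3, 2])

    def test_apparent_peak_broadened_below_physical_ratio(self):
        p = steady_state_analytic(map_alpha_to_m(4.0, 2.0, J=21))
        apparent = convolve_detection(p, normalize=True)
        physical_ratio = p[0] / p[10]
        apparent_ratio = apparent.max() / apparent[10]
        assert apparent_ratio < physical_ratio

    def test_kernel_longer_than_profile_rejected(self):
        with pytest.raises(ValueError, match="longer"):
            convolve_detection(np.ones(2), DetectionKernel((1, 1, 1)))

    def test_inward_clipped_matrix_columns_sum_to_k(self):
        M = detection_matrix("nearest-3-clipped-inward", 21)
        np.testing.assert_allclose(M.sum(axis=0), 3.0)


class TestFitting:
    def test_noiseless_roundtrip_recovers_m_exactly(self):
        m = boundary_m(0.25, 0.5, J=21)
        apparent = convolve_detection(steady_state_analytic(m), normalize=True)
        fit = fit_from_observed(apparent)
        assert fit.m_lsq[0] == pytest.approx(0.25, abs=1e-6)
        assert fit.m_lsq[1] == pytest.approx(0.5, abs=1e-6)

    def test_flat_profile_degenerate(self):
        fit = fit_from_observed(np.full(21, 1 / 21))
        assert fit.flat
        assert fit.m_lsq == (1.0, 1.0)

    @pytest.mark.parametrize("alpha", [1.5, 4.0, 10.0])
    def test_alpha_roundtrip_through_convolved_profile(self, alpha):
        """alpha -> steady -> detection convolution -> fit recovers 1/m."""
        m = map_alpha_to_m(alpha, alpha / 2, J=21)
        kernel = DetectionKernel(rule="nearest-3-clipped-inward")
        apparent = convolve_detection(steady_state_analytic(m), kernel,
                                      normalize=True)
        fit = fit_from_observed(apparent, kernel=kernel)
        assert fit.alpha_lsq[0] == pytest.approx(alpha, rel=0.03)
        assert fit.alpha_lsq[1] == pytest.approx(alpha / 2, rel=0.03)

    def test_peak_method_reported_alongside(self):
        m = boundary_m(0.25, 0.5, J=21)
        apparent = convolve_detection(steady_state_analytic(m), normalize=True)
        fit = fit_from_observed(apparent)
        assert fit.alpha_peak[0] > fit.alpha_lsq[0]  # spill bias, documented
        assert np.isfinite(fit.discrepancy).all()

    def test_poisson_noised_benchmark_recovery(self, benchmark):
        counts, truth = benchmark
        from swimstack import distributions as dist
        avg = dist.time_average(counts)
        profile = dist.to_probability(avg.mean)
        fit = fit_from_observed(profile,
                                kernel=DetectionKernel(rule="nearest-3-clipped-inward"))
        assert fit.alpha_lsq[0] == pytest.approx(truth["alpha_solid"], rel=0.10)
        assert fit.alpha_lsq[1] == pytest.approx(truth["alpha_air"], rel=0.10)
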