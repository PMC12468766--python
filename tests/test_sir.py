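import numpy as np
import pytest
from scipy.integrate import solve_ivp

from edgeperc import (CFLError, Graph, SIRInit, SIRParams, build_problem,
                      edge_density_to_state, run_sir, step_sir)
from edgeperc.sir import default_road_init, default_road_params


def single_vertex_setup(**param_overrides):
    """One edge (for a valid metric graph) plus an isolated populated vertex."""
    g = Graph([("a", "b")], vertices=["a", "b", "c"], lengths=[1.0])
    init = SIRInit(populated=frozenset({"c"}), seed_vertex="c",
                   seed_infected=1e-6, s0=0.25)
    return g, default_road_params(**param_overrides), init


class TestBuildProblem:
    def test_road_grid_sizes(self, road):
        pr = build_problem(road, default_road_params(), default_road_init())
        # e1 has length 1.44: round(1.44/0.55)+1 = 4 points, spacing 0.48
        assert pr.n_pts[0] == 4
        assert pr.dx_e[0] == pytest.approx(0.48)
        assert np.all(pr.n_pts >= 3)

    def test_road_cfl_accepted(self, road):
        pr = build_problem(road, default_road_params(), default_road_init())
        # nominal grid: 1.5 * 0.02 / 0.55^2 ~ 0.099, all edges stable
        assert np.all(pr.cfl <= 0.5)

    def test_cfl_guard_rejects_large_dt(self, road):
        with pytest.raises(CFLError, match="e"):
            build_problem(road, default_road_params(dt=0.2), default_road_init())

    def test_missing_lengths_rejected(self, p3):
        with pytest.raises(ValueError):
            build_problem(p3, default_road_params(), default_road_init())

    def test_seed_must_be_populated(self, road):
        init = SIRInit(populated=frozenset({"v1"}), seed_vertex="v18")
        with pytest.raises(ValueError):
            build_problem(road, default_road_params(), init)

    def test_initial_state_splits_seed(self, road):
        pr = build_problem(road, default_road_params(), default_road_init())
        st = pr.initial_state()
        i18 = road.vertex_index("v18")
        assert st.S[i18] == pytest.approx(0.249999)
        assert st.I[i18] == pytest.approx(1e-6)
        # border crossings carry no population
        assert st.S[road.vertex_index("v10")] == 0.0


class TestStep:
    def test_zero_state_is_fixed_point(self, road):
        pr = build_problem(road, default_road_params(), default_road_init())
        st = pr.initial_state()
        st.S[:] = 0
        st.I[:] = 0
        st2 = step_sir(st, pr)
        assert np.all(st2.I == 0) and np.all(st2.I_grid == 0)

    def test_isolated_vertex_matches_ode_oracle(self):
        g, params, init = single_vertex_setup(t_end=10.0)
        traj = run_sir(build_problem(g, params, init))

        def rhs(_, y):
            S, I, R = y
            return [-0.45 * S * I, 0.45 * S * I - 0.13 * I, 0.13 * I]

        sol = solve_ivp(rhs, [0, 10], [0.25 - 1e-6, 1e-6, 0.0],
                        rtol=1e-12, atol=1e-14)
        ic = g.vertex_index("c")
        assert abs(traj.S[-1, ic] - sol.y[0, -1]) < 1e-6
        assert abs(traj.I[-1, ic] - sol.y[1, -1]) < 1e-6
        assert abs(traj.R[-1, ic] - sol.y[2, -1]) < 1e-6
        # subcritical: tau*S0/eta < 1, infection decays monotonically
        assert np.all(np.diff(traj.I[:, ic]) <= 0)

    def test_sealed_edge_conserves_mass_per_step(self):
        # no vertex coupling at all: zero-flux diffusion conserves the integral
        g = Graph([("a", "b")], lengths=[2.0])
        init = SIRInit(populated=frozenset({"a", "b"}), seed_vertex="a",
                       seed_infected=0.0, s0=0.0)
        params = default_road_params(lam=0.0, alpha=0.0, nu=0.0)
        pr = build_problem(g, params, init)
        st = pr.initial_state()
        rng = np.random.default_rng(0)
        st.I_grid[:] = rng.uniform(0, 1, pr.n_grid)
        mass = pr.weights @ st.I_grid
        for _ in range(50):
            st = step_sir(st, pr)
            new_mass = pr.weights @ st.I_grid
            assert abs(new_mass - mass) < 1e-10
            mass = new_mass


class TestRun:
    def test_no_infection_means_nothing_happens(self, road):
        init = SIRInit(populated=default_road_init().populated,
                       seed_vertex="v18", seed_infected=0.0)
        traj = run_sir(build_problem(road, default_road_params(t_end=2.0), init))
        assert np.all(traj.I == 0) and np.all(traj.R == 0)
        assert np.allclose(traj.S, traj.S[0], atol=0)

    def test_total_population_conserved(self, road):
        traj = run_sir(build_problem(road, default_road_params(),
                                     default_road_init()))
        drift = np.abs(traj.mass - traj.mass[0]).max() / traj.mass[0]
        assert drift < 1e-6

    def test_positivity(self, road):
        traj = run_sir(build_problem(road, default_road_params(),
                                     default_road_init()))
        assert traj.I.min() > -1e-9
        assert traj.edge_state.min() > -1e-9

    def test_seed_vertex_and_its_edges_peak_first(self, road):
        # v18 and its only edges e20, e21 lead the epidemic
        traj = run_sir(build_problem(road, default_road_params(),
                                     default_road_init()))
        peak_v = traj.I.max(axis=0)
        assert np.argmax(peak_v) == road.vertex_index("v18")
        peak_e = traj.edge_state.max(axis=0)
        assert set(np.argsort(peak_e)[-2:]) == {19, 20}

    def test_symmetric_star_gives_identical_edge_profiles(self):
        g = Graph([("c", "a"), ("c", "b")], lengths=[1.0, 1.0])
        init = SIRInit(populated=frozenset({"a", "b", "c"}), seed_vertex="c",
                       seed_infected=1e-4, s0=0.25)
        pr = build_problem(g, default_road_params(t_end=5.0), init)
        traj = run_sir(pr)
        assert np.allclose(traj.edge_state[:, 0], traj.edge_state[:, 1],
                           atol=1e-14)

    def test_first_order_time_convergence(self, road):
        coarse = run_sir(build_problem(
            road, default_road_params(t_end=4.0), default_road_init()))
        fine = run_sir(build_problem(
            road, default_road_params(t_end=4.0, dt=0.01, sample_every=20),
            default_road_init()))
        # curves at shared sample times agree to well under 1% sup-norm
        scale = np.abs(coarse.I).max()
        assert np.abs(coarse.I - fine.I).max() < 0.01 * scale

    def test_final_size_relation_supercritical(self):
        # isolated vertex with tau*S0/eta > 1: S_inf = S0 exp(-tau R_inf / eta)
        g = Graph([("a", "b")], vertices=["a", "b", "c"], lengths=[1.0])
        init = SIRInit(populated=frozenset({"c"}), seed_vertex="c",
                       seed_infected=0.01, s0=1.0)
        params = default_road_params(tau=1.0, eta=0.3, dt=0.005, t_end=80.0,
                                     sample_every=100)
        traj = run_sir(build_problem(g, params, init))
        ic = g.vertex_index("c")
        S_inf, R_inf = traj.S[-1, ic], traj.R[-1, ic]
        assert traj.I[-1, ic] < 1e-6
        S0 = 1.0 - 0.01  # seed infection is moved out of the S compartment
        assert S_inf == pytest.approx(S0 * np.exp(-1.0 / 0.3 * R_inf), abs=1e-4)


class TestEdgeDensityToState:
    def test_zero_and_constant_profiles(self):
        g = Graph([("a", "b")], lengths=[2.0])
        init = SIRInit(populated=frozenset({"a"}), seed_vertex="a",
                       seed_infected=0.0, s0=0.1)
        pr = build_problem(g, default_road_params(), init)
        st = pr.initial_state()
        assert edge_density_to_state(st, pr).x[0] == 0.0
        st.I_grid[:] = 0.3
        assert edge_density_to_state(st, pr).x[0] == pytest.approx(0.3)

    def test_linear_profile_gives_half(self):
        g = Graph([("a", "b")], lengths=[2.0])
        init = SIRInit(populated=frozenset({"a"}), seed_vertex="a",
                       seed_infected=0.0, s0=0.1)
        pr = build_problem(g, default_road_params(), init)
        st = pr.initial_state()
        st.I_grid[:] = np.linspace(0, 1, pr.n_grid)
        assert edge_density_to_state(st, pr).x[0] == pytest.approx(0.5)

    def test_clipped_to_unit_interval(self, road):
        pr = build_problem(road, default_road_params(), default_road_init())
        st = pr.initial_state()
        st.I_grid[:] = 3.0
        assert np.all(edge_density_to_state(st, pr).x == 1.0)


class TestParamsValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            SIRParams(tau=-1.0)

    def test_unknown_lambda_mode(self):
        with pytest.raises(ValueError):
            SIRParams(lambda_mode="sometimes")

    def test_unknown_border_mode(self):
        with pytest.raises(ValueError):
            SIRParams(border_mode="open")


class TestEPCPipeline:
    def test_corridor_edge_has_top_mean_epc(self, road):
        # the Szczecin-Poznan corridor edge e21 dominates the mean EPC over
        # the run (transcription-dependent; the remaining ordering is not
        # asserted)
        from edgeperc import EdgeStates, epc

        traj = run_sir(build_problem(road, default_road_params(),
                                     default_road_init()))
        vals = [epc(road, EdgeStates(x, t=t)).values
                for t, x in zip(traj.times, traj.edge_state)]
        mean_epc = np.mean(vals, axis=0)
        assert int(np.argmax(mean_epc)) == 20  # e21
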