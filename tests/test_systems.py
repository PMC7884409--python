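"""Bundled simulators and generators: physics and closure checks."""

import numpy as np
import pytest

from eqbalance import (
    TermSpec,
    apply_mask,
    assemble_equation_space,
    brute_force_oracle,
    finite_difference,
    generate_planted_balance,
    magnitude_mask,
    residual_report,
)
from eqbalance.exceptions import IntegrationError
from eqbalance.systems import (
    RDEConfig,
    analytic_boundary_layer_fixture,
    classic_hh_config,
    simulate_hodgkin_huxley,
    simulate_rde_analog,
)
from eqbalance.systems.boundary_layer import INNER, OUTER


# --------------------------------------------------------------------------- #
# conductance-based neuron
# --------------------------------------------------------------------------- #
class TestHodgkinHuxley:
    def test_resting_equilibrium(self):
        cfg = classic_hh_config(i_stim=0.0, t_span=(0, 100), dt=0.1)
        r = simulate_hodgkin_huxley(cfg)
        v = r.states["V"]
        t = r.coords[:, 0]
        assert np.abs(v[t > 20] - v[-1]).max() < 2.0  # no spikes after transient
        assert v.max() < -60.0

    def test_spike_count_matches_independent_rk4(self):
        """Repetitive spiking under sustained drive, spike count cross-checked
        against a self-contained fixed-step RK4 integration of the same
        equations written out longhand."""
        cfg = classic_hh_config(i_stim=10.0, t_span=(0, 100), dt=0.05)
        r = simulate_hodgkin_huxley(cfg)
        v = r.states["V"]
        spikes = int(np.sum((v[1:] > 0) & (v[:-1] <= 0)))
        assert spikes >= 5

        def vtrap(x, y):
            return np.where(np.abs(x / y) < 1e-7, y - x / 2, x / np.expm1(x / y))

        def deriv(y, t):
            v, m, h, n = y
            am, bm = 0.1 * vtrap(-(v + 40), 10.0), 4 * np.exp(-(v + 65) / 18)
            ah, bh = 0.07 * np.exp(-(v + 65) / 20), 1 / (1 + np.exp(-(v + 35) / 10))
            an, bn = 0.01 * vtrap(-(v + 55), 10.0), 0.125 * np.exp(-(v + 65) / 80)
            ina = 120.0 * m**3 * h * (v - 50.0)
            ik = 36.0 * n**4 * (v + 77.0)
            il = 0.3 * (v + 54.387)
            return np.array([
                (-ina - ik - il + 10.0),
                am * (1 - m) - bm * m,
                ah * (1 - h) - bh * h,
                an * (1 - n) - bn * n,
            ])

        dt = 0.01
        y = np.array([cfg.v0, cfg.gate_init["m"], cfg.gate_init["h"], cfg.gate_init["n"]])
        vs = [y[0]]
        for i in range(int(100 / dt)):
            t = i * dt
            k1 = deriv(y, t)
            k2 = deriv(y + dt / 2 * k1, t + dt / 2)
            k3 = deriv(y + dt / 2 * k2, t + dt / 2)
            k4 = deriv(y + dt * k3, t + dt)
            y = y + dt / 6 * (k1 + 2 * k2 + 2 * k3 + k4)
            vs.append(y[0])
        vs = np.asarray(vs)
        ref_spikes = int(np.sum((vs[1:] > 0) & (vs[:-1] <= 0)))
        assert spikes == ref_spikes

    def test_term_arrays_close_implicit_form(self):
        cfg = classic_hh_config(i_stim=10.0, t_span=(0, 50), dt=0.05)
        esf = simulate_hodgkin_huxley(cfg).to_equation_space()
        assert residual_report(esf).max_normalized <= 1e-6

    def test_charge_bookkeeping(self):
        """The capacitive term equals the negated sum of all other signed terms."""
        cfg = classic_hh_config(i_stim=10.0, t_span=(0, 50), dt=0.05)
        r = simulate_hodgkin_huxley(cfg)
        cap, sign_cap, _ = r.term_arrays["dVdt"]
        others = sum(
            sign * arr
            for name, (arr, sign, _) in r.term_arrays.items()
            if name != "dVdt"
        )
        np.testing.assert_allclose(sign_cap * cap, -others, atol=1e-10)

    def test_divergence_detected(self):
        cfg = classic_hh_config(i_stim=1e6, t_span=(0, 100), dt=0.1)
        with pytest.raises(IntegrationError):
            simulate_hodgkin_huxley(cfg)

    def test_bursting_alternates_epochs(self, bursting_sim):
        v = bursting_sim.states["V"]
        t = bursting_sim.coords[:, 0]
        crossings = t[1:][(v[1:] > -20) & (v[:-1] <= -20)]
        assert len(crossings) >= 10  # several spikes
        gaps = np.diff(crossings)
        assert gaps.max() > 3000.0  # a quiescent interval of seconds
        assert np.median(gaps) < 1000.0  # rapid spiking within bursts

    def test_slow_currents_dominate_quiescence(self, bursting_sim):
        r = bursting_sim
        v = r.states["V"]
        dv = r.term_arrays["dVdt"][0]
        quiescent = (v < -45) & (np.abs(dv) < 0.01)
        spiking = v > -35
        assert quiescent.sum() > 100 and spiking.sum() > 100

        def med(name, sel):
            return np.median(np.abs(r.term_arrays[name][0][sel]))

        # quiescence: calcium-linked currents carry the balance
        assert med("I_SI", quiescent) > 10 * med("I_Na", quiescent)
        assert med("I_KCa", quiescent) > 10 * med("I_Na", quiescent)
        # spikes: the fast Na/K cycle dominates the slow inward current
        assert med("I_Na", spiking) > med("I_SI", spiking)
        assert med("I_K", spiking) > med("I_SI", spiking)


# --------------------------------------------------------------------------- #
# detonation analog
# --------------------------------------------------------------------------- #
class TestRDE:
    def test_constant_state_is_equilibrium(self):
        cfg = RDEConfig(q=0.0, epsilon_loss=0.0, M=64, t_span=(0, 5),
                        n_snapshots=6, u0=lambda x: 0.7 * np.ones_like(x))
        r = simulate_rde_analog(cfg)
        np.testing.assert_allclose(r.states["u"], 0.7, atol=1e-13)

    def test_inviscid_burgers_matches_characteristics(self):
        """Pre-shock smooth advection vs the method-of-characteristics solution."""
        from scipy.optimize import brentq

        cfg = RDEConfig(q=0.0, epsilon_loss=0.0, M=1024, t_span=(0, 1.0),
                        n_snapshots=11, u0=lambda x: 0.5 + 0.25 * np.sin(x))
        r = simulate_rde_analog(cfg)
        x, u = r.states["x"], r.states["u"][-1]

        def u0(s):
            return 0.5 + 0.25 * np.sin(s)

        exact = np.array([
            u0(brentq(lambda s: s + u0(s) * 1.0 - xi, xi - 2.0, xi + 1.0))
            for xi in x
        ])
        assert np.abs(u - exact).max() <= 1e-3

    def test_progress_variable_bounds(self, rde_sim):
        lam = rde_sim.states["lambda"]
        assert lam.min() >= 0.0
        assert lam.max() <= 1.0 + 1e-9

    def test_two_persistent_waves(self, rde_sim):
        u, t = rde_sim.states["u"], rde_sim.states["t"]
        for ti in np.flatnonzero(t >= 100)[::20]:
            row = u[ti]
            peaks = np.sum(
                (row > np.roll(row, 1)) & (row >= np.roll(row, -1))
                & (row > 0.5 * row.max()) & (row > 0.3)
            )
            assert peaks == 2

    def test_snapshot_terms_close_implicit_form(self, rde_sim):
        from eqbalance.systems.rde import U_EQUATION_TERMS

        esf = rde_sim.to_equation_space(U_EQUATION_TERMS)
        assert residual_report(esf).max_normalized <= 1e-10
        esf_lam = rde_sim.to_equation_space(["lam_t", "lam_gain", "lam_loss"])
        assert residual_report(esf_lam).max_normalized <= 1e-10

    def test_residual_shrinks_under_refinement(self):
        """Time-differenced u_t vs the advection term: the closure defect is
        discretization-limited and shrinks as grid and sampling refine."""
        maxes = []
        for m, ns in ((128, 101), (256, 201)):
            cfg = RDEConfig(q=0.0, epsilon_loss=0.0, M=m, t_span=(0, 1.0),
                            n_snapshots=ns, u0=lambda x: 0.5 + 0.25 * np.sin(x))
            r = simulate_rde_analog(cfg)
            dt = r.states["t"][1] - r.states["t"][0]
            ut_fd = finite_difference(r.states["u"], axis=0, spacing=dt, order=1)
            esf = assemble_equation_space(
                [ut_fd.ravel(), r.term_arrays["u_ux"][0]],
                [TermSpec("u_t", sign_convention=-1),
                 TermSpec("u_ux", sign_convention=-1)],
                r.coords,
            )
            esf = apply_mask(esf, magnitude_mask(0.1 * np.abs(esf.values).max()))
            maxes.append(residual_report(esf).max_normalized)
        assert maxes[1] < maxes[0]

    def test_invalid_config(self):
        with pytest.raises(Exception):
            RDEConfig(cfl=1.5)
        with pytest.raises(Exception):
            RDEConfig(M=32)


# --------------------------------------------------------------------------- #
# planted generator
# --------------------------------------------------------------------------- #
class TestPlantedGenerator:
    def test_zero_noise_exact_subspace(self):
        f, labels = generate_planted_balance([(0, 1)], 100, K=4, noise_sigma=0.0, seed=0)
        np.testing.assert_allclose(f.values[:, 0] + f.values[:, 1], 0.0, atol=1e-12)
        np.testing.assert_array_equal(f.values[:, 2:], 0.0)
        assert (labels == 0).all()

    def test_determinism(self):
        a, _ = generate_planted_balance([(0, 1), (2, 3)], 200, K=5, noise_sigma=0.01, seed=42)
        b, _ = generate_planted_balance([(0, 1), (2, 3)], 200, K=5, noise_sigma=0.01, seed=42)
        np.testing.assert_array_equal(a.values, b.values)

    def test_negligible_direction_variance_bound(self):
        sigma = 0.02
        f, labels = generate_planted_balance([(0, 1, 2)], 3000, K=6,
                                             noise_sigma=sigma, seed=1)
        cov = np.cov(f.values.T)
        w = np.sort(np.linalg.eigvalsh(cov))
        # the K - p trailing eigenvalues are pure noise
        assert (w[: 6 - 3] <= 2 * sigma**2 + 1e-4).all()

    def test_invalid_pattern_rejected(self):
        with pytest.raises(ValueError):
            generate_planted_balance([(0, 9)], 10, K=4, noise_sigma=0.0, seed=0)
        with pytest.raises(ValueError):
            generate_planted_balance([(2,)], 10, K=4, noise_sigma=0.0, seed=0)


# --------------------------------------------------------------------------- #
# analytic singular-perturbation fixture
# --------------------------------------------------------------------------- #
class TestBoundaryLayerFixture:
    @pytest.mark.parametrize("eps", [1e-2, 1e-3, 5e-2])
    def test_terms_close_exactly(self, eps):
        f, _ = analytic_boundary_layer_fixture(eps, 200)
        assert residual_report(f).max_normalized <= 1e-10

    def test_truth_inner_region_width(self):
        eps = 1e-3
        f, labels = analytic_boundary_layer_fixture(eps, 400)
        x = f.coords[:, 0]
        inner = labels == INNER
        assert inner[0]  # adjacent to x = 0
        assert np.all(np.diff(np.flatnonzero(inner)) == 1)  # contiguous
        width = x[inner].max()
        assert eps <= width <= 10 * eps * np.log(1 / eps)

    def test_outer_points_oracle_pair(self):
        f, labels = analytic_boundary_layer_fixture(1e-3, 400)
        x = f.coords[:, 0]
        far = x > 0.5
        for row in f.values[far][::20]:
            res = brute_force_oracle(row, delta=0.1)
            assert (1, 2) in res.minimal_sets  # {y', constant}
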