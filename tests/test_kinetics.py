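import numpy as np
import pytest
import scipy.linalg

from myokin.kinetics import (PseudoFirstOrderError, RateSystem,
                             build_rate_matrix, default_time_grid,
                             eigen_phases, scheme1_system, scheme2_initial,
                             scheme2_system, simulate_scheme1,
                             simulate_scheme2, simulate_transient)
from myokin.trace import ObservableMap, pyrene_observables, trp_observables


def hyperbolic_fast_rate(params, atp):
    """Hyperbolic fast-phase prediction k2*K1*[T]/(1+K1*[T])."""
    try:
        return params.k_plus2_prime * params.K1_prime * atp / (
            1 + params.K1_prime * atp)
    except AttributeError:
        return params.k_plus2 * params.K1 * atp / (1 + params.K1 * atp)


class TestRateMatrix:
    @pytest.mark.parametrize("atp,adp", [(0.0, 0.0), (250.0, 0.0),
                                         (20.0, 50.0), (3600.0, 0.0)])
    def test_columns_sum_to_zero(self, s1_mut, acto_mut, atp, adp):
        for sys in (build_rate_matrix(s1_mut, atp_um=atp),
                    build_rate_matrix(acto_mut, atp_um=atp, adp_um=adp)):
            assert np.all(np.abs(sys.Q.sum(axis=0)) < 1e-10)
            off = sys.Q - np.diag(np.diag(sys.Q))
            assert np.all(off >= 0)

    def test_no_ligand_means_no_flux_and_flat_trace(self, s1_mut):
        trace = simulate_scheme1(s1_mut, atp_um=0.0,
                                 t_grid=np.linspace(0.002, 5, 200))
        assert np.allclose(trace.signal, trace.signal[0], atol=1e-12)

    def test_fast_eigenvalue_matches_hyperbolic_prediction(self, acto_mut):
        # largest signal-carrying eigenvalue vs the two-step binding
        # hyperbola at 250 uM ATP: coupling to the conformer branch may
        # shift it by a few percent but not more than 5%
        phases = eigen_phases(acto_mut, atp_um=250.0)
        fast = max(r for r, _ in phases)
        assert fast == pytest.approx(hyperbolic_fast_rate(acto_mut, 250.0), rel=0.05)

    def test_pseudo_first_order_violation_names_ligand(self, acto_mut):
        with pytest.raises(PseudoFirstOrderError, match="ADP"):
            scheme2_system(acto_mut, atp_um=2000.0, adp_um=0.5,
                           protein_um=0.1)

    def test_rejects_negative_concentration(self, s1_mut):
        with pytest.raises(ValueError):
            scheme1_system(s1_mut, atp_um=-1.0)


class TestEigenPhases:
    def test_two_state_single_rate_is_exact(self):
        Q = np.array([[-5.0, 0.0], [5.0, 0.0]])
        sys = RateSystem(Q, ("a", "b"))
        phases = eigen_phases(sys, p0=np.array([1.0, 0.0]),
                              observables=ObservableMap({"a": 1.0, "b": 2.0}))
        assert len(phases) == 1
        rate, coeff = phases[0]
        assert rate == pytest.approx(5.0, rel=1e-12)
        assert coeff == pytest.approx(-1.0, rel=1e-12)

    def test_slowest_displacement_phase_is_adp_release(self, acto_wt):
        # pure A.M.D start, saturating ATP, ADP diluted away: the slow
        # signal-carrying phase reports k_minusAD (64 s^-1 input); modes
        # below 5% of the dominant amplitude are sub-resolution
        sys = scheme2_system(acto_wt, atp_um=2000.0, adp_um=0.0)
        p0 = np.zeros(len(sys.states))
        p0[sys.index("A.M.D")] = 1.0
        phases = eigen_phases(sys, p0=p0)
        amax = max(abs(c) for _, c in phases)
        rates = [r for r, c in phases if abs(c) >= 0.05 * amax]
        assert min(rates) == pytest.approx(acto_wt.k_minusAD, rel=0.02)

    def test_matches_matrix_exponential_oracle_on_random_systems(self):
        # brute-force propagator agreement over 100 random reversible
        # 4-state systems (detailed balance, the class our schemes live in)
        rng = np.random.default_rng(4)
        tpts = np.geomspace(0.01, 3.0, 60)
        for _ in range(100):
            pi = rng.dirichlet(np.ones(4))
            S = rng.lognormal(0, 1, (4, 4))
            S = S + S.T
            Q = S * pi[:, None]          # Q[j, i] = S_ij * pi_j -> balance
            np.fill_diagonal(Q, 0.0)
            Q -= np.diag(Q.sum(axis=0))
            sys = RateSystem(Q, ("s0", "s1", "s2", "s3"))
            p0 = rng.dirichlet(np.ones(4))
            yields = ObservableMap(dict(zip(sys.states, rng.uniform(0, 2, 4))))
            analytic = simulate_transient(sys, p0=p0, observables=yields,
                                          t_grid=tpts, method="eigen")
            brute = simulate_transient(sys, p0=p0, observables=yields,
                                       t_grid=tpts, method="expm")
            np.testing.assert_allclose(analytic.signal, brute.signal,
                                       rtol=1e-8, atol=1e-10)


class TestSimulation:
    def test_occupancy_conservation(self, acto_mut):
        sys = scheme2_system(acto_mut, atp_um=250.0, adp_um=10.0)
        p0 = scheme2_initial(acto_mut, sys)
        for t in (1e-3, 0.05, 1.0, 10.0):
            p = scipy.linalg.expm(sys.Q * t) @ p0
            assert abs(p.sum() - 1.0) < 1e-9

    def test_trp_transient_is_biexponential_with_hyperbolic_fast_rate(self):
        # Scheme 1 at 250 uM ATP with plateau 88 and half-saturation 93:
        # the fast phase rate is 88*250/(93+250) = 64.1 s^-1
        from myokin.params import SchemeOneParams
        p = SchemeOneParams(K1=1 / 93.0, k_plus2=88.0, k_plus3=3.2,
                            k_minus3=0.8)
        phases = eigen_phases(p, atp_um=250.0)
        amax = max(abs(c) for _, c in phases)
        resolvable = [(r, c) for r, c in phases if abs(c) >= 0.05 * amax]
        assert len(resolvable) == 2  # product release is sub-resolution
        fast = max(r for r, _ in phases)
        assert fast == pytest.approx(88 * 250 / (93 + 250), rel=1e-9)

    def test_saturating_atp_fast_rate_approaches_k_plus2(self, s1_mut):
        fast = max(r for r, _ in eigen_phases(s1_mut, atp_um=1e7))
        assert fast == pytest.approx(s1_mut.k_plus2, rel=1e-4)

    def test_complete_dissociation_reaches_free_actin_yield(self, acto_mut):
        obs = pyrene_observables(total_change=0.34)
        trace = simulate_scheme2(
            acto_mut.model_copy(update={"k_minus_alpha": 0.0}),
            atp_um=50000.0, t_grid=np.linspace(1e-3, 5, 300),
            observables=obs, protein_um=None)
        assert trace.signal[-1] == pytest.approx(1.34, rel=1e-6)

    def test_eigen_path_matches_propagator_on_shared_grid(self, acto_mut):
        t = default_time_grid(5.0, n_points=60)
        analytic = simulate_scheme2(acto_mut, atp_um=500.0, t_grid=t)
        sys = scheme2_system(acto_mut, atp_um=500.0)
        p0 = scheme2_initial(acto_mut, sys)
        brute = simulate_transient(sys, p0=p0,
                                   observables=pyrene_observables(),
                                   t_grid=t, method="expm")
        np.testing.assert_allclose(analytic.signal, brute.signal, rtol=1e-6)

    def test_rapid_equilibrium_collapse_matches_explicit_binding(self, s1_wt):
        # explicit two-step binding converges to the collapsed-K1 model
        # as the off-rate becomes fast (k_minus1 = 1e4 s^-1): fast-phase
        # rates agree within 2%
        atp = 200.0
        collapsed = max(r for r, _ in eigen_phases(s1_wt, atp_um=atp))
        sys = scheme1_system(s1_wt, atp_um=atp, explicit_binding=True)
        p0 = np.zeros(len(sys.states))
        p0[0] = 1.0
        rates = sorted((r for r, _ in eigen_phases(
            sys, p0=p0, observables=trp_observables())), reverse=True)
        visible = [r for r in rates if r < s1_wt.k_minus1 / 3]
        assert visible[0] == pytest.approx(collapsed, rel=0.02)

    def test_initial_occupancies_must_sum_to_one(self, acto_mut):
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_scheme2(acto_mut, atp_um=100.0,
                             p0=np.array([0.5, 0.1, 0.0, 0.0, 0.0]),
                             t_grid=np.linspace(1e-3, 1, 100))


def test_default_time_grid_spans_dead_time_to_20_over_rate():
    t = default_time_grid(4.0, dead_time=0.0015, n_points=500)
    assert t[0] == pytest.approx(0.0015)
    assert t[-1] == pytest.approx(5.0)
    assert t.size == 500
    assert np.all(np.diff(t) > 0)
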