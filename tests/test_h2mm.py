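"""Photon-by-photon HMM: exhaustive-path oracles, EM properties, model
selection, Viterbi dwells, uncertainties, and rate extraction."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from repstates import burst_core as bc
from repstates import h2mm as h2
from repstates import photon_sim
from repstates.burst_core import CorrectionFactors


def make_data(obs, gaps, bursts=None, n_symbols=2):
    ptr = np.array(bursts if bursts is not None else [0, len(obs)], dtype=np.int64)
    return h2.BurstPhotons(obs=np.asarray(obs, np.uint8),
                           gaps=np.asarray(gaps, np.int64),
                           burst_ptr=ptr, n_symbols=n_symbols)


def brute_force_loglik(model, obs, gaps):
    """Sum over all photon-level hidden paths with A**gap transitions."""
    K = model.K
    A, B, pi = model.trans, model.emission, model.initial
    Apow = {g: np.linalg.matrix_power(A, int(g)) for g in set(gaps[1:])}
    total = 0.0
    best_logp, best_path = -np.inf, None
    for path in itertools.product(range(K), repeat=len(obs)):
        p = pi[path[0]] * B[path[0], obs[0]]
        for n in range(1, len(obs)):
            p *= Apow[gaps[n]][path[n - 1], path[n]] * B[path[n], obs[n]]
        total += p
        logp = np.log(max(p, 1e-300))
        if logp > best_logp:
            best_logp, best_path = logp, path
    return np.log(total), best_path, best_logp


def random_model(rng, K, n_symbols=2):
    A = rng.random((K, K)) * 0.05
    np.fill_diagonal(A, 0)
    np.fill_diagonal(A, 1 - A.sum(axis=1))
    B = rng.random((K, n_symbols)) + 0.05
    B /= B.sum(axis=1, keepdims=True)
    pi = rng.random(K) + 0.1
    pi /= pi.sum()
    return h2.H2MMModel(trans=A, emission=B, initial=pi)


class TestLoglikOracle:
    def test_k1_closed_form(self):
        B = np.array([[0.3, 0.7]])
        m = h2.H2MMModel(trans=np.ones((1, 1)), emission=B,
                         initial=np.array([1.0]))
        obs = np.array([0, 1, 1, 0, 1], dtype=np.uint8)
        d = make_data(obs, [0, 5, 2, 9, 1])
        expect = np.log(B[0, obs]).sum()
        assert h2.h2mm_loglik(m, d) == pytest.approx(expect)

    def test_identity_transitions_reduce_to_state_mixture(self):
        # A = I: the burst likelihood is a pi-weighted mixture of frozen
        # single-state likelihoods.
        rng = np.random.default_rng(3)
        m = random_model(rng, 3)
        m.trans = np.eye(3)
        obs = rng.integers(0, 2, 12).astype(np.uint8)
        gaps = np.concatenate([[0], rng.integers(1, 50, 11)])
        d = make_data(obs, gaps)
        per_state = np.prod(m.emission[:, obs], axis=1)
        expect = np.log(np.dot(m.initial, per_state))
        assert h2.h2mm_loglik(m, d) == pytest.approx(expect)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), K=st.integers(2, 3),
           n=st.integers(2, 8))
    def test_forward_and_viterbi_match_exhaustive_paths(self, seed, K, n):
        rng = np.random.default_rng(seed)
        m = random_model(rng, K)
        obs = rng.integers(0, 2, n).astype(np.uint8)
        gaps = np.concatenate([[0], rng.integers(1, 6, n - 1)])
        d = make_data(obs, gaps)
        logl_bf, path_bf, score_bf = brute_force_loglik(m, obs, gaps)
        assert h2.h2mm_loglik(m, d) == pytest.approx(logl_bf, rel=1e-9)
        vp = h2.viterbi_dwells(m, d)
        assert vp.score == pytest.approx(score_bf, rel=1e-9)
        assert tuple(vp.states.tolist()) == path_bf

    def test_matrix_power_composition(self):
        rng = np.random.default_rng(4)
        A = random_model(rng, 3).trans
        P1 = h2.matrix_power_eig(A, np.array([137]))[0]
        P2 = h2.matrix_power_eig(A, np.array([86]))[0]
        P12 = h2.matrix_power_eig(A, np.array([223]))[0]
        assert np.allclose(P1 @ P2, P12, atol=1e-10)

    def test_non_stochastic_transitions_rejected(self):
        m = h2.H2MMModel(trans=np.array([[0.5, 0.1], [0.2, 0.8]]),
                         emission=np.full((2, 2), 0.5),
                         initial=np.array([0.5, 0.5]))
        with pytest.raises(ValueError):
            h2.h2mm_loglik(m, make_data([0, 1], [0, 1]))


class TestEM:
    def test_single_state_emissions_are_stream_fractions(self):
        rng = np.random.default_rng(5)
        obs = (rng.random(500) < 0.3).astype(np.uint8)
        gaps = np.concatenate([[0], rng.integers(1, 100, 499)])
        d = make_data(obs, gaps)
        m = h2.h2mm_em(d, K=1, max_iter=50)
        assert m.emission[0, 1] == pytest.approx(obs.mean(), abs=1e-6)

    def test_loglik_monotone_over_iterations(self, two_state_fixture):
        s = photon_sim.simulate_burst_stream(two_state_fixture, 120, seed=8)
        bg = bc.estimate_background(s)
        bursts = bc.all_photon_burst_search(s, bg)
        d = h2.burst_photon_data(s, bursts)
        model = h2.default_init(2, d.n_symbols)
        prev = -np.inf
        for _ in range(40):
            A, B, pi, logl = h2._em_step(model, d)
            assert logl >= prev - 1e-7 * max(1.0, abs(prev))
            model.trans, model.emission, model.initial = A, B, pi
            prev = logl

    def test_two_state_recovery(self, two_state_fixture):
        # E 0.2/0.8, k = 500/s both ways: E within 0.05, rates within 25%.
        s = photon_sim.simulate_burst_stream(two_state_fixture, 600, seed=4)
        bg = bc.estimate_background(s)
        bursts = bc.all_photon_burst_search(s, bg)
        bc.apply_corrections(bursts, CorrectionFactors())
        kept = bc.filter_population(bursts)
        d = h2.burst_photon_data(s, kept)
        m = h2.h2mm_em(d, K=2, max_iter=1000)
        e = np.sort(m.state_e_raw())
        assert abs(e[0] - 0.2) < 0.05 and abs(e[1] - 0.8) < 0.05
        rm = h2.rates_and_occupancy(m)
        k12, k21 = rm.rates[0, 1], rm.rates[1, 0]
        if e.tolist() != np.sort(m.state_e_raw()).tolist():
            k12, k21 = k21, k12
        assert abs(k12 - 500) / 500 < 0.25
        assert abs(k21 - 500) / 500 < 0.25


class TestSelection:
    def test_one_state_data_selects_one(self):
        rng = np.random.default_rng(6)
        obs = (rng.random(3000) < 0.4).astype(np.uint8)
        gaps = np.concatenate([[0], rng.integers(1, 2000, 2999)])
        ptr = np.arange(0, 3001, 100)
        d = make_data(obs, gaps, bursts=ptr)
        k, models, info = h2.fit_select(d, k_max=3, max_iter=200)
        assert k == 1

    def test_selection_requires_two_models(self):
        with pytest.raises(ValueError):
            h2.select_states({1: None})

    def test_bic_prime_definition(self):
        assert h2.bic_prime(1000.0, 990.0) == pytest.approx(0.01)


class TestViterbiDwells:
    def test_k1_single_dwell_per_burst(self):
        m = h2.H2MMModel(trans=np.ones((1, 1)),
                         emission=np.array([[0.5, 0.5]]),
                         initial=np.array([1.0]))
        d = make_data([0, 1, 0, 1], [0, 1, 1, 1], bursts=[0, 2, 4])
        vp = h2.viterbi_dwells(m, d)
        assert len(vp.dwells) == 2

    def test_dwells_tile_bursts_and_alternate(self, two_state_fixture):
        s = photon_sim.simulate_burst_stream(two_state_fixture, 80, seed=10)
        bg = bc.estimate_background(s)
        bursts = bc.all_photon_burst_search(s, bg)
        d = h2.burst_photon_data(s, bursts)
        m = h2.h2mm_em(d, K=2, max_iter=300)
        vp = h2.viterbi_dwells(m, d)
        for bi in range(d.n_bursts):
            dw = [x for x in vp.dwells if x[0] == bi]
            assert dw[0][2] == d.burst_ptr[bi]
            assert dw[-1][3] == d.burst_ptr[bi + 1]
            for a, b in zip(dw[:-1], dw[1:]):
                assert a[3] == b[2] and a[1] != b[1]


class TestUncertainty:
    def test_k1_profile_matches_binomial(self):
        # One state: the E profile is an analytic binomial likelihood.
        rng = np.random.default_rng(7)
        n = 4000
        obs = (rng.random(n) < 0.3).astype(np.uint8)
        d = make_data(obs, np.concatenate([[0], np.full(n - 1, 10)]))
        m = h2.h2mm_em(d, K=1, max_iter=50)
        cis = h2.loglik_uncertainty(d, m, which="E")
        lo, hi, bounded = cis["E"][0]
        p_hat = obs.mean()

        def binom_deficit(p):
            ll = obs.sum() * np.log(p) + (n - obs.sum()) * np.log(1 - p)
            ll_max = obs.sum() * np.log(p_hat) + (n - obs.sum()) * np.log(1 - p_hat)
            return ll_max - ll

        assert bounded
        assert binom_deficit(lo) == pytest.approx(0.5, abs=0.02)
        assert binom_deficit(hi) == pytest.approx(0.5, abs=0.02)

    def test_ci_width_shrinks_with_root_n(self):
        widths = []
        for n in (1000, 4000):
            rng = np.random.default_rng(8)
            obs = (rng.random(n) < 0.5).astype(np.uint8)
            d = make_data(obs, np.concatenate([[0], np.full(n - 1, 10)]))
            m = h2.h2mm_em(d, K=1, max_iter=50)
            lo, hi, _ = h2.loglik_uncertainty(d, m, which="E")["E"][0]
            widths.append(hi - lo)
        assert widths[1] == pytest.approx(widths[0] / 2.0, rel=0.15)


class TestRatesAndDark:
    def test_identity_gives_zero_rates(self):
        m = h2.H2MMModel(trans=np.eye(3), emission=np.full((3, 2), 0.5),
                         initial=np.full(3, 1 / 3))
        rm = h2.rates_and_occupancy(m)
        assert np.all(rm.rates == 0.0)

    def test_per_tick_probability_to_rate(self):
        A = np.array([[1 - 1e-5, 1e-5], [2e-5, 1 - 2e-5]])
        m = h2.H2MMModel(trans=A, emission=np.full((2, 2), 0.5),
                         initial=np.array([0.5, 0.5]))
        rm = h2.rates_and_occupancy(m, clock_tick_s=1e-8)
        assert rm.rates[0, 1] == pytest.approx(1000.0)
        assert rm.rates[1, 0] == pytest.approx(2000.0)

    def test_large_probabilities_fall_back_to_logm(self):
        A = np.array([[0.95, 0.05], [0.05, 0.95]])
        m = h2.H2MMModel(trans=A, emission=np.full((2, 2), 0.5),
                         initial=np.array([0.5, 0.5]))
        with pytest.warns(UserWarning, match="matrix-logarithm"):
            rm = h2.rates_and_occupancy(m, clock_tick_s=1e-8)
        assert rm.method == "logm"

    def test_max_resolvable_rate_from_count_budget(self):
        assert h2.max_resolvable_rate(5.0e4, 20.0) == pytest.approx(2.5e3)

    def _model_with_dark(self):
        # 5 states, one sparse low-E acceptor-dark artefact at E = 0.05
        A = np.full((5, 5), 1e-6)
        np.fill_diagonal(A, 0)
        np.fill_diagonal(A, 1 - A.sum(axis=1))
        e = np.array([0.05, 0.27, 0.54, 0.82, 0.96])
        B = np.stack([1 - e, e], axis=1)
        pi = np.array([0.02, 0.2, 0.2, 0.3, 0.28])
        return h2.H2MMModel(trans=A, emission=B, initial=pi)

    def test_dark_state_excluded_and_renormalised(self):
        m = self._model_with_dark()
        # stationary of near-uniform A is uniform; use occupancy threshold 0.3
        rep = h2.exclude_dark_state(m, e_open_pred=0.29, margin=0.05,
                                    occupancy_threshold=0.3)
        assert rep["dark_states"] == [0]
        assert len(rep["kept_states"]) == 4
        assert rep["occupancy"].sum() == pytest.approx(1.0)
        assert rep["rates"].shape == (4, 4)

    def test_no_dark_state_is_noop(self):
        m = self._model_with_dark()
        rep = h2.exclude_dark_state(m, e_open_pred=0.01)
        assert rep["dark_states"] == []
        assert len(rep["kept_states"]) == 5

    def test_all_dark_raises(self):
        m = self._model_with_dark()
        with pytest.raises(ValueError):
            h2.exclude_dark_state(m, e_open_pred=2.0, occupancy_threshold=2.0)
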