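"""HMM unit and oracle tests: transitions, emissions, forward-backward, EM fit."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, pearsonr

import contactzone as cz
from contactzone.hmm import (forward_backward, posterior_mean_admixture,
                             stationary_diploid)


class TestHaploidTransition:
    def test_zero_distance_is_identity(self):
        assert np.allclose(cz.haploid_transition(0.0, 10, 0.3), np.eye(2))

    def test_large_distance_reaches_stationarity(self):
        T = cz.haploid_transition(50.0, 10, 0.2)
        assert np.allclose(T, [[0.2, 0.8], [0.2, 0.8]], atol=1e-12)

    def test_rows_sum_to_one(self):
        for d, t, m in [(0.01, 2, 0.0), (0.3, 100, 0.5), (1e-5, 7, 0.99)]:
            assert np.allclose(cz.haploid_transition(d, t, m).sum(axis=1), 1.0)

    def test_matches_discrete_generation_oracle(self):
        # one generation: switch with prob 1 - e^{-d}, redraw from (m, 1-m)
        d, t, m = 0.01, 10, 0.2
        G = np.exp(-d) * np.eye(2) + (1 - np.exp(-d)) * np.tile([m, 1 - m], (2, 1))
        oracle = np.linalg.matrix_power(G, t)
        assert np.allclose(cz.haploid_transition(d, t, m), oracle, atol=1e-12)

    @pytest.mark.parametrize("bad", [(-0.1, 10, 0.2), (0.1, 0.5, 0.2), (0.1, 10, 1.5)])
    def test_invalid_arguments_raise(self, bad):
        with pytest.raises(ValueError):
            cz.haploid_transition(*bad)

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(d=st.floats(0.0, 5.0), t=st.floats(1.0, 500.0), m=st.floats(0.0, 1.0))
    def test_stochasticity_and_stationarity_properties(self, d, t, m):
        """Rows sum to 1, entries are probabilities, and (m, 1-m) is a fixed point."""
        h = cz.haploid_transition(d, t, m)
        assert np.allclose(h.sum(axis=1), 1.0, atol=1e-12)
        assert (h >= -1e-15).all() and (h <= 1 + 1e-15).all()
        pi = np.array([m, 1.0 - m])
        assert np.allclose(pi @ h, pi, atol=1e-12)
        d3 = cz.diploid_transition(d, t, m)
        assert np.allclose(d3.sum(axis=1), 1.0, atol=1e-12)
        pi3 = np.array([(1 - m) ** 2, 2 * m * (1 - m), m**2])
        assert np.allclose(pi3 @ d3, pi3, atol=1e-12)


class TestDiploidTransition:
    def test_zero_distance_is_identity(self):
        assert np.allclose(cz.diploid_transition(0.0, 5, 0.4), np.eye(3))

    def test_stationary_row_is_hardy_weinberg(self):
        m = 0.3
        T = cz.diploid_transition(100.0, 10, m)
        hw = [(1 - m) ** 2, 2 * m * (1 - m), m**2]
        assert np.allclose(T, np.tile(hw, (3, 1)), atol=1e-12)

    @pytest.mark.parametrize("d,t,m", [(0.005, 2, 0.1), (0.02, 20, 0.5), (0.1, 7, 0.8)])
    def test_matches_ordered_pair_oracle(self, d, t, m):
        # Build the 4-state ordered chain by explicit loops and collapse it.
        h = cz.haploid_transition(d, t, m)
        states = list(itertools.product([0, 1], repeat=2))  # 0=het copy, 1=con copy
        T4 = np.zeros((4, 4))
        for i, (a, b) in enumerate(states):
            for j, (a2, b2) in enumerate(states):
                T4[i, j] = h[a, a2] * h[b, b2]
        k_of = [2 - sum(s) for s in states]  # het copies -> diploid index CC=0..HH=2
        T3 = np.zeros((3, 3))
        for k in range(3):
            reps = [i for i, kk in enumerate(k_of) if kk == k]
            rows = []
            for r in reps:
                row = np.zeros(3)
                for j in range(4):
                    row[k_of[j]] += T4[r, j]
                rows.append(row)
            # lumpability: both ordered representatives must agree
            for row in rows[1:]:
                assert np.allclose(row, rows[0], atol=1e-12)
            T3[k] = rows[0]
        assert np.allclose(cz.diploid_transition(d, t, m), T3, atol=1e-12)


class TestEmission:
    def test_no_reads_is_uninformative(self):
        ll = cz.emission_loglik(np.array([0]), np.array([0]),
                                np.array([0.9]), np.array([0.1]))
        assert np.allclose(ll, ll[0, 0])

    def test_equal_panel_frequencies_are_uninformative(self):
        f = np.array([0.4])
        ll = cz.emission_loglik(np.array([3]), np.array([2]), f, f)
        assert np.allclose(ll[0], ll[0, 0])

    def test_matches_hand_marginalization(self):
        # explicit sum over the diploid genotype, written out independently
        f_con, f_het, eps = 0.9, 0.05, 0.01
        ref, alt = 1, 4
        n = ref + alt
        pg = {0: eps, 1: 0.5, 2: 1 - eps}
        pairs = {0: (f_con, f_con), 1: (f_con, f_het), 2: (f_het, f_het)}
        expected = []
        for state in range(3):
            fa, fb = pairs[state]
            prior = {0: (1 - fa) * (1 - fb), 1: fa * (1 - fb) + fb * (1 - fa), 2: fa * fb}
            expected.append(sum(prior[g] * binom.pmf(alt, n, pg[g]) for g in range(3)))
        got = cz.emission_loglik(np.array([ref]), np.array([alt]),
                                 np.array([f_con]), np.array([f_het]))
        assert np.allclose(np.exp(got[0]), expected, rtol=1e-12)

    def test_error_free_fixed_difference(self):
        # conspecific panel fixed ref, heterospecific fixed alt, 3 alt reads:
        # CC impossible, HC has prob (1/2)^3, HH certain
        got = np.exp(cz.emission_loglik(np.array([0]), np.array([3]),
                                        np.array([0.0]), np.array([1.0]),
                                        error_rate=0.0))[0]
        assert got[0] == 0.0
        assert np.isclose(got[1], 0.5**3)
        assert np.isclose(got[2], 1.0)

    def test_invalid_error_rate_raises(self):
        with pytest.raises(ValueError):
            cz.emission_loglik(np.array([1]), np.array([1]),
                               np.array([0.5]), np.array([0.5]), error_rate=1.5)


def _enumerate_posteriors(ref, alt, panels, conspecific, t, m, eps=0.01):
    """Exhaustive 3^L path enumeration oracle."""
    other = {"outcrosser": "selfer", "selfer": "outcrosser"}[conspecific]
    logE = cz.emission_loglik(ref, alt, panels.freq(conspecific), panels.freq(other), eps)
    E = np.exp(logE)
    L = len(ref)
    morgan = panels.df["morgan"].to_numpy()
    trans = [cz.diploid_transition(morgan[i + 1] - morgan[i], t, m) for i in range(L - 1)]
    pi3 = stationary_diploid(m)
    marg = np.zeros((L, 3))
    total = 0.0
    for path in itertools.product(range(3), repeat=L):
        p = pi3[path[0]] * E[0, path[0]]
        for i in range(1, L):
            p *= trans[i - 1][path[i - 1], path[i]] * E[i, path[i]]
        total += p
        for i, s in enumerate(path):
            marg[i, s] += p
    return marg / total, np.log(total)


class TestForwardBackward:
    def test_single_site_no_reads_gives_stationary(self, tiny_panels):
        panels1 = cz.SnpPanelTable(tiny_panels.df.iloc[:1].copy())
        post, _ = forward_backward(np.array([0]), np.array([0]), panels1,
                                   "outcrosser", t=10, m=0.3)
        assert np.allclose(post[0], stationary_diploid(0.3), atol=1e-12)

    def test_m_zero_collapses_to_conspecific(self, tiny_panels):
        rng = np.random.default_rng(1)
        ref = rng.integers(0, 4, 6)
        alt = rng.integers(0, 4, 6)
        post, _ = forward_backward(ref, alt, tiny_panels, "outcrosser", t=10, m=0.0)
        assert np.allclose(post[:, 0], 1.0)

    @pytest.mark.parametrize("seed,m,t", [(0, 0.2, 5), (1, 0.5, 2), (2, 0.05, 50)])
    def test_matches_path_enumeration(self, tiny_panels, seed, m, t):
        rng = np.random.default_rng(seed)
        ref = rng.integers(0, 5, 6)
        alt = rng.integers(0, 5, 6)
        post, ll = forward_backward(ref, alt, tiny_panels, "outcrosser", t=t, m=m)
        oracle, oracle_ll = _enumerate_posteriors(ref, alt, tiny_panels,
                                                  "outcrosser", t, m)
        assert np.allclose(post, oracle, atol=1e-8)
        assert np.isclose(ll, oracle_ll, atol=1e-8)

    def test_posterior_rows_normalized(self, admixed_cohort):
        *_, fits = admixed_cohort
        for fit in fits.fits[:10]:
            assert np.allclose(fit.posteriors.sum(axis=1), 1.0, atol=1e-9)
            assert (fit.posteriors >= 0).all()

    def test_non_monotone_map_raises(self, tiny_panels):
        df = tiny_panels.df.copy()
        df.loc[3, "morgan"] = 0.0001
        with pytest.raises(ValueError):
            cz.SnpPanelTable(df)


class TestFitIndividual:
    def test_pure_parental_recovers_near_zero(self, tiny_panels):
        cfg = cz.SimConfig(n_sites=500, n_outcrosser=3, n_selfer=0,
                           pedigree_class="old_admixed", alpha_range=(0.0, 0.0),
                           seed=33)
        panels = cz.simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        reads = cz.simulate_reads(truth, panels, cfg)
        for i in range(3):
            fit = cz.fit_individual(reads.ref[i], reads.alt[i], panels, "outcrosser")
            assert fit.alpha < 0.01

    def test_em_convergence_contract(self, admixed_cohort):
        """At termination the re-fed admixture moves by less than the 0.001 rule."""
        cfg, panels, truth, reads, fits = admixed_cohort
        for i, fit in enumerate(fits.fits[:10]):
            if not fit.converged:
                continue
            post, _ = forward_backward(reads.ref[i], reads.alt[i], panels,
                                       "outcrosser", t=fit.t, m=fit.alpha)
            assert abs(posterior_mean_admixture(post) - fit.alpha) < 0.001

    def test_loglik_near_monotone_at_fixed_t(self):
        cfg = cz.SimConfig(n_sites=400, n_outcrosser=4, n_selfer=0,
                           pedigree_class="old_admixed", seed=44)
        panels = cz.simulate_panels(cfg)
        _, truth = cz.simulate_zone(cfg, panels)
        reads = cz.simulate_reads(truth, panels, cfg)
        for i in range(4):
            alpha, lls = 0.05, []
            for _ in range(25):
                post, ll = forward_backward(reads.ref[i], reads.alt[i], panels,
                                            "outcrosser", t=20, m=alpha)
                lls.append(ll)
                nxt = posterior_mean_admixture(post)
                if abs(nxt - alpha) < 1e-4:
                    break
                alpha = nxt
            drops = -np.diff(lls)
            # the alpha feedback is a fixed-point update, not an exact M-step:
            # small terminal decreases occur; they must stay negligible
            assert drops.max(initial=0.0) < 1e-3 * abs(lls[-1])

    def test_alpha_recovery_on_simulated_truth(self, admixed_cohort):
        _, _, truth, _, fits = admixed_cohort
        fitted = np.array([f.alpha for f in fits.fits])
        r, _ = pearsonr(fitted, truth.true_alpha)
        assert r >= 0.98
        assert np.abs(fitted - truth.true_alpha).mean() < 0.02

    def test_bad_arguments_raise(self, tiny_panels):
        r = np.zeros(6, int)
        with pytest.raises(ValueError):
            cz.fit_individual(r, r, tiny_panels, "outcrosser", tol=0.0)
        with pytest.raises(ValueError):
            cz.fit_individual(r, r, tiny_panels, "outcrosser", t_grid=[])
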