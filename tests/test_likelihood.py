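"""Likelihood tests: closed forms at nu=1 (Poisson), high-precision series
oracles, quadrature and simulation cross-checks, and agreement between the
exact scipy path and the compiled fast path."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import special
from scipy.integrate import quad

import gammaxo as gx
from gammaxo import _kernels as K
from gammaxo.celldata import CellwiseData
from gammaxo.errors import SeriesConvergenceError

# Values computed with a 40-digit sympy oracle summing 120 series terms
# (geometric tail closed analytically); see test_stahl_matches_live_sympy
# for the oracle itself run in-session on one point.
ORACLE_LOG_F = -0.44881079050605227  # log f*(0.3; nu=11.2, lam=1)
ORACLE_CDF = 0.0352551490758113  # F*(0.3; nu=11.2, lam=1)
ORACLE_LOG_G = -0.027371207630186814  # log g*(0.1; nu=18.6, lam=0.973)
ORACLE_LOG_P0 = -1.0310599851392765  # log P0(L=0.8; nu=10, lam=1)
ORACLE_PATHWAY_1XO = -0.4502536853459621  # log lik([0.45]; L=0.9, nu=11.2, lam=1)
ORACLE_STAHL_3XO = -0.9599844451967041  # log lik([.2,.5,.8]; L=1, nu=11.2, p=0.0094)


class TestPoissonCollapse:
    """At nu = 1 the thinned process is homogeneous Poisson with rate lam."""

    @pytest.mark.parametrize("lam", [1.0, 0.7])
    def test_interarrival_is_exponential(self, lam):
        logf, cdf = gx.thinned_interarrival(0.5, nu=1.0, lam=lam)
        assert logf == pytest.approx(math.log(lam) - lam * 0.5, abs=1e-10)
        assert cdf == pytest.approx(1.0 - math.exp(-lam * 0.5), abs=1e-12)

    def test_first_point_density(self):
        assert gx.stationary_first_point_logdensity(0.2, 1.0, 1.0) == pytest.approx(
            -0.2, abs=1e-12
        )

    def test_zero_probability(self):
        assert gx.prob_zero_observed(1.0, 1.0, 1.0) == pytest.approx(
            math.exp(-1.0), abs=1e-12
        )

    @pytest.mark.parametrize("positions", [[], [0.3, 0.7], [0.1, 0.4, 0.9]])
    def test_pathway_loglik_is_poisson(self, positions):
        ll = gx.gamma_pathway_loglik(positions, 1.0, nu=1.0, lam=1.0)
        assert ll == pytest.approx(-1.0, abs=1e-8)


class TestSeriesOracles:
    def test_thinned_interarrival_matches_oracle(self):
        logf, cdf = gx.thinned_interarrival(0.3, nu=11.2, lam=1.0)
        assert logf == pytest.approx(ORACLE_LOG_F, abs=1e-10)
        assert cdf == pytest.approx(ORACLE_CDF, abs=1e-12)

    def test_first_point_matches_oracle(self):
        assert gx.stationary_first_point_logdensity(
            0.1, nu=18.6, lam=0.973
        ) == pytest.approx(ORACLE_LOG_G, abs=1e-10)

    def test_prob_zero_matches_oracle(self):
        assert math.log(gx.prob_zero_observed(0.8, nu=10.0, lam=1.0)) == pytest.approx(
            ORACLE_LOG_P0, abs=1e-10
        )

    def test_single_crossover_pathway_matches_oracle(self):
        assert gx.gamma_pathway_loglik([0.45], 0.9, nu=11.2, lam=1.0) == pytest.approx(
            ORACLE_PATHWAY_1XO, abs=1e-10
        )

    def test_stahl_matches_frozen_oracle(self):
        ll = gx.stahl_chromosome_loglik(
            [0.2, 0.5, 0.8], 1.0, gx.InterferenceParams(11.2, 0.0094)
        )
        assert ll == pytest.approx(ORACLE_STAHL_3XO, abs=1e-10)

    def test_stahl_matches_live_sympy(self):
        """Recompute one 2^3-term enumeration with 40-digit sympy."""
        sp = pytest.importorskip("sympy")
        PREC = 40

        def o_S(y, nu, lam, Ktr=120):
            nu_, lam_ = sp.Float(nu, PREC), sp.Float(lam, PREC)
            b = 2 * nu_ * lam_
            y_ = sp.Float(y, PREC)
            s = sum(
                sp.Rational(1, 2) ** k * sp.uppergamma(k * nu_, b * y_) / sp.gamma(k * nu_)
                for k in range(1, Ktr + 1)
            )
            return sp.N(s + sp.Rational(1, 2) ** Ktr, PREC)

        def o_f(y, nu, lam, Ktr=120):
            nu_, lam_ = sp.Float(nu, PREC), sp.Float(lam, PREC)
            b = 2 * nu_ * lam_
            y_ = sp.Float(y, PREC)
            return sp.N(
                sum(
                    sp.Rational(1, 2) ** k
                    * b ** (k * nu_) * y_ ** (k * nu_ - 1) * sp.exp(-b * y_)
                    / sp.gamma(k * nu_)
                    for k in range(1, Ktr + 1)
                ),
                PREC,
            )

        def o_p0(L, nu, lam, Ktr=120):
            nu_, lam_ = sp.Float(nu, PREC), sp.Float(lam, PREC)
            b = 2 * nu_ * lam_
            L_ = sp.Float(L, PREC)
            s = sp.Float(0, PREC)
            for k in range(1, Ktr + 1):
                a = k * nu_
                s += sp.Rational(1, 2) ** k * (
                    L_ * sp.lowergamma(a, b * L_) / sp.gamma(a)
                    - (a / b) * sp.lowergamma(a + 1, b * L_) / sp.gamma(a + 1)
                )
            return sp.N(1 - lam_ * L_ + lam_ * s, PREC)

        def o_pathway(pos, L, nu, lam):
            if not pos:
                return o_p0(L, nu, lam)
            lik = sp.Float(lam, PREC) * o_S(pos[0], nu, lam)
            for a, b2 in zip(pos, pos[1:]):
                lik *= o_f(b2 - a, nu, lam)
            return sp.N(lik * o_S(L - pos[-1], nu, lam), PREC)

        pos, L, nu, p = [0.2, 0.5, 0.8], 1.0, 11.2, 0.0094
        lam = 1.0 - p
        tot = sp.Float(0, PREC)
        for mask in range(8):
            sub = [pos[i] for i in range(3) if mask >> i & 1]
            tot += o_pathway(sub, L, nu, lam) * sp.Float(p, PREC) ** (3 - len(sub))
        expected = float(sp.log(tot * sp.exp(-sp.Float(p, PREC) * sp.Float(L, PREC))))
        assert expected == pytest.approx(ORACLE_STAHL_3XO, abs=1e-12)
        ll = gx.stahl_chromosome_loglik(pos, L, gx.InterferenceParams(nu, p))
        assert ll == pytest.approx(expected, abs=1e-10)


class TestNormalizationAndMoments:
    @pytest.mark.parametrize("nu, lam", [(11.2, 1.0), (18.6, 0.973)])
    def test_first_point_density_integrates_to_one(self, nu, lam):
        val, _ = quad(
            lambda t: math.exp(gx.stationary_first_point_logdensity(t, nu, lam)),
            0.0, 30.0 / lam, limit=300,
        )
        assert val == pytest.approx(1.0, abs=1e-6)

    @pytest.mark.parametrize("nu", [0.5, 1.0, 2.0, 11.2, 18.6])
    @pytest.mark.parametrize("lam", [1.0, 0.973])
    def test_thinned_mean_is_inverse_rate(self, nu, lam):
        mean, _ = quad(
            lambda t: t * math.exp(gx.thinned_interarrival(t, nu, lam)[0]),
            0.0, 60.0 / lam, limit=400,
        )
        assert mean == pytest.approx(1.0 / lam, rel=1e-6)


class TestProbZero:
    def test_matches_quadrature(self):
        for nu, lam, L in [(10.0, 1.0, 0.8), (18.6, 0.973, 0.5), (0.7, 0.9, 1.1)]:
            integral, _ = quad(
                lambda t: math.exp(gx.stationary_first_point_logdensity(t, nu, lam)),
                0.0, L, limit=300,
            )
            assert gx.prob_zero_observed(L, nu, lam) == pytest.approx(
                1.0 - integral, abs=1e-8
            )

    def test_short_chromosome_limit(self):
        assert gx.prob_zero_observed(1e-9, 11.2, 1.0) == pytest.approx(1.0, abs=1e-8)

    def test_matches_simulation(self):
        """Zero-crossover frequency from 1e6 simulated chromatids at
        (nu=10, L=0.8 Morgans) within 3 Monte-Carlo SEs."""
        rng = np.random.default_rng(123)
        counts = gx.simulate_counts(10.0, 0.0, 80.0, 1_000_000, rng)
        freq = np.mean(counts == 0)
        p0 = gx.prob_zero_observed(0.8, 10.0, 1.0)
        se = math.sqrt(p0 * (1 - p0) / counts.size)
        assert abs(freq - p0) < 3 * se


class TestStahlLikelihood:
    @pytest.mark.parametrize("p", [0.0, 0.1, 0.3, 0.7])
    @pytest.mark.parametrize("positions", [[], [0.3, 0.7], [0.05, 0.5, 0.95]])
    def test_nu1_collapse_independent_of_p(self, p, positions):
        """At nu=1 both pathways are Poisson; the superposition has rate 1
        regardless of p, so the likelihood is exp(-L)."""
        ll = gx.stahl_chromosome_loglik(positions, 1.0, gx.InterferenceParams(1.0, p))
        assert ll == pytest.approx(-1.0, abs=1e-8)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        L=st.floats(0.3, 1.5),
        p=st.floats(0.0, 0.95),
        frac=st.lists(st.floats(0.01, 0.99), min_size=0, max_size=4, unique=True),
    )
    def test_nu1_collapse_property(self, L, p, frac):
        """Poisson collapse holds for arbitrary valid records, not just
        hand-picked ones."""
        pos = np.sort(np.asarray(frac)) * L
        if pos.size >= 2 and np.min(np.diff(pos)) < 1e-4:
            return
        ll = gx.stahl_chromosome_loglik(pos, L, gx.InterferenceParams(1.0, p))
        assert ll == pytest.approx(-L, abs=1e-8)

    def test_p_to_zero_continuity(self):
        pos = [0.2, 0.55]
        ll_eps = gx.stahl_chromosome_loglik(
            pos, 0.9, gx.InterferenceParams(11.2, 1e-10)
        )
        ll_zero = gx.gamma_pathway_loglik(pos, 0.9, 11.2, 1.0)
        assert ll_eps == pytest.approx(ll_zero, abs=1e-6)

    def test_empty_record_factorizes(self):
        ll = gx.stahl_chromosome_loglik([], 1.2, gx.InterferenceParams(5.0, 0.02))
        expected = math.log(gx.prob_zero_observed(1.2, 5.0, 0.98)) - 0.02 * 1.2
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_enumeration(self):
        """Log-sum-exp subset sum equals a linear-space enumeration (fsum
        of exponentiated pathway terms) on random instances with n <= 6."""
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(0, 7))
            L = float(rng.uniform(0.5, 1.4))
            pos = np.sort(rng.uniform(0.0, L, size=n))
            while n >= 2 and np.min(np.diff(pos)) < 1e-4:
                pos = np.sort(rng.uniform(0.0, L, size=n))
            nu = float(rng.choice([0.8, 2.5, 11.2, 18.6]))
            p = float(rng.choice([0.01, 0.2, 0.5]))
            lam = 1.0 - p
            terms = []
            for subset_bits in itertools.product([0, 1], repeat=n):
                sub = pos[np.asarray(subset_bits, dtype=bool)] if n else pos
                ll_gamma = gx.gamma_pathway_loglik(sub, L, nu, lam)
                terms.append(math.exp(ll_gamma) * p ** (n - int(sum(subset_bits))))
            expected = math.log(math.fsum(terms)) - p * L
            got = gx.stahl_chromosome_loglik(pos, L, gx.InterferenceParams(nu, p))
            assert got == pytest.approx(expected, rel=1e-10), (n, nu, p, L)

    def test_subset_guard(self):
        pos = np.linspace(0.01, 0.95, 21)
        with pytest.raises(ValueError, match="guard"):
            gx.stahl_chromosome_loglik(pos, 1.0, gx.InterferenceParams(11.2, 0.1))


class TestDomainErrors:
    def test_nonpositive_distance(self):
        with pytest.raises(ValueError):
            gx.thinned_interarrival(0.0, 11.2)

    def test_negative_first_point(self):
        with pytest.raises(ValueError):
            gx.stationary_first_point_logdensity(-0.1, 11.2)

    def test_unsorted_positions(self):
        with pytest.raises(ValueError):
            gx.gamma_pathway_loglik([0.7, 0.3], 1.0, 11.2)

    def test_out_of_range_positions(self):
        with pytest.raises(ValueError):
            gx.gamma_pathway_loglik([1.5], 1.0, 11.2)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            gx.InterferenceParams(nu=-1.0)
        with pytest.raises(ValueError):
            gx.InterferenceParams(nu=1.0, p=1.0)

    def test_series_cap_raises(self):
        """At very small nu the survival series needs many terms; a tight
        term cap must fail loudly rather than truncate silently."""
        opts = gx.NumericOptions(series_max_terms=50)
        with pytest.raises(SeriesConvergenceError):
            gx.thinned_interarrival(2.0, nu=0.1, lam=1.0, opts=opts)


class TestDatasetLoglik:
    def test_additive_over_records(self, toy_dataset):
        scheme = gx.assign_groups(toy_dataset, "by_sex")
        params = {
            (0, 0): gx.InterferenceParams(11.2, 0.0094),
            (1, 0): gx.InterferenceParams(18.6, 0.027),
        }
        total = gx.dataset_loglik(toy_dataset, scheme, params, engine="exact")
        by_hand = sum(
            gx.stahl_chromosome_loglik(
                r.positions / 100.0, r.length_cM / 100.0,
                params[scheme.cell_of(r)],
            )
            for r in toy_dataset.records
        )
        assert total == pytest.approx(by_hand, abs=1e-10)

    def test_all_empty_poisson_is_total_map_length(self, toy_map):
        recs = [
            gx.TransmittedChromosome(m, s, c, toy_map.length(c, s), np.array([]))
            for m, s in [("a", "F"), ("b", "M")]
            for c in ("1", "2")
        ]
        data = gx.CrossoverDataset(recs, toy_map)
        scheme = gx.assign_groups(data, "by_sex")
        params = {(i, 0): gx.InterferenceParams(1.0, 0.25) for i in range(2)}
        expected = -sum(r.length_cM for r in recs) / 100.0
        assert gx.dataset_loglik(data, scheme, params, engine="exact") == pytest.approx(
            expected, abs=1e-8
        )

    def test_missing_cell_params_error(self, toy_dataset):
        scheme = gx.assign_groups(toy_dataset, "by_sex")
        with pytest.raises(KeyError):
            gx.dataset_loglik(toy_dataset, scheme, {(0, 0): gx.InterferenceParams(10.0)})


class TestFastKernel:
    def test_incomplete_gamma_matches_scipy(self):
        a_grid = np.concatenate([np.geomspace(0.05, 900.0, 40), [1.0, 11.2, 18.6]])
        for a in a_grid:
            for x in [1e-6, 0.01, 0.5, a * 0.5 + 0.01, a, a * 1.5 + 1.0, a + 30.0]:
                assert K._gammap(a, x) == pytest.approx(
                    float(special.gammainc(a, x)), abs=1e-12, rel=1e-10
                )
                assert K._gammaq(a, x) == pytest.approx(
                    float(special.gammaincc(a, x)), abs=1e-12, rel=1e-10
                )

    @pytest.mark.parametrize(
        "nu, p",
        [(1.0, 0.0), (0.7, 0.1), (5.0, 0.0), (11.2, 0.0094), (18.6, 0.3)],
    )
    def test_matches_exact_path_on_simulated_data(self, nu, p, small_dataset):
        scheme = gx.assign_groups(small_dataset, "by_sex")
        params = {(i, 0): gx.InterferenceParams(nu, p) for i in range(2)}
        fast = gx.dataset_loglik(small_dataset, scheme, params, engine="fast")
        exact = gx.dataset_loglik(small_dataset, scheme, params, engine="exact")
        assert fast == pytest.approx(exact, abs=5e-3, rel=1e-6)

    def test_log_p0_matches_exact(self):
        for nu, lam, L in [(11.2, 1.0, 0.9), (18.6, 0.973, 0.45), (0.6, 0.8, 1.3)]:
            assert K._log_p0(nu, lam, L) == pytest.approx(
                math.log(gx.prob_zero_observed(L, nu, lam)), abs=1e-10
            )
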