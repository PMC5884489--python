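import math
from fractions import Fraction

import numpy as np
import pytest
from scipy import integrate, stats

from barcodepop import popgen as pg
from barcodepop.sequence_io import LabeledAlignment, Record


def _aln(seqs):
    return LabeledAlignment(
        [
            Record(id=f"s{i}", sequence=s, species="spA", population="p1")
            for i, s in enumerate(seqs)
        ]
    )


class TestDiversity:
    def test_identical_sample(self):
        d = pg.diversity(["ACGT"] * 4)
        assert d.h == 0.0
        assert d.pi == 0.0
        assert d.S == 0
        assert d.mean_pairwise_diff == 0.0

    def test_two_distinct_haplotypes_h_is_one(self):
        d = pg.diversity(["AAAA", "AAAT"])
        assert d.h == pytest.approx(1.0)

    def test_toy_fixture_values(self, toy):
        fx = toy["two_haplotypes"]
        d = pg.diversity(fx["alignment"])
        exp = fx["expected"]
        assert d.h == pytest.approx(exp["h"])
        assert d.S == exp["S"]
        assert d.mean_pairwise_diff == pytest.approx(exp["mean_pairwise_diff"])

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            pg.diversity(["ACGT"])


class TestGrantBowen:
    @pytest.mark.parametrize(
        "h,pi,expected",
        [
            (0.6, 0.003, "large-h/small-pi"),
            (0.85, 0.006, "large-h/large-pi"),
            (0.3, 0.001, "small-h/small-pi"),
            (0.2, 0.02, "small-h/large-pi"),
            (0.5, 0.005, "small-h/small-pi"),  # boundary goes to "small"
        ],
    )
    def test_classification(self, h, pi, expected):
        assert pg.grant_bowen_class(h, pi) == expected


def _tajima_d_oracle(seqs):
    """Independent textbook computation: explicit loops, no shared code."""
    n = len(seqs)
    L = len(seqs[0])
    S = 0
    for j in range(L):
        if len({s[j] for s in seqs}) > 1:
            S += 1
    tot, cnt = 0, 0
    for i in range(n):
        for j in range(i + 1, n):
            tot += sum(1 for a, b in zip(seqs[i], seqs[j]) if a != b)
            cnt += 1
    k = tot / cnt
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


class TestTajimasD:
    def test_matches_arithmetic_oracle(self):
        seqs = ["AAAAA", "AAAAT", "AAATT", "AATTT", "ATTTT"]
        d, _ = pg.tajimas_d(seqs, n_sims=10, seed=0)
        assert d == pytest.approx(_tajima_d_oracle(seqs), abs=1e-12)

    def test_second_toy_alignment(self):
        seqs = ["ACGTACGT", "ACGAACGT", "ACGAACTT", "ACGTACTT", "ACGTACGT", "ACGAACGT"]
        d, _ = pg.tajimas_d(seqs, n_sims=10, seed=0)
        assert d == pytest.approx(_tajima_d_oracle(seqs), abs=1e-12)

    def test_no_segregating_sites_is_na(self):
        d, p = pg.tajimas_d(["ACGT"] * 5, n_sims=10, seed=0)
        assert math.isnan(d) and math.isnan(p)

    def test_null_distribution_centred(self):
        """Neutral constant-size simulations give D averaging near zero."""
        rng = np.random.default_rng(3)
        ds = []
        while len(ds) < 500:
            diffs, S = pg.simulate_coalescent_diffs(10, 3.0, rng)
            if S == 0:
                continue
            kb = float(np.mean(diffs[np.triu_indices(10, 1)]))
            ds.append(pg._tajima_d_from(kb, S, 10))
        assert -0.3 < np.mean(ds) < 0.3

    def test_p_value_in_range_and_seeded(self):
        seqs = ["AAAAA", "AAAAT", "AAATT", "AATTT", "ATTTT"]
        d1, p1 = pg.tajimas_d(seqs, n_sims=200, seed=7)
        d2, p2 = pg.tajimas_d(seqs, n_sims=200, seed=7)
        assert (d1, p1) == (d2, p2)
        assert 0 <= p1 <= 1


def _ewens_tail_exact(n, k_obs, theta):
    """Exact-rational Ewens tail: brute-force Stirling triangle + Fractions."""
    th = Fraction(theta)
    row = [Fraction(1)]
    for m in range(n):
        new = [Fraction(0)] * (len(row) + 1)
        for k, v in enumerate(row):
            new[k] += m * v
            new[k + 1] += v
        row = new
    rise = Fraction(1)
    for i in range(n):
        rise *= th + i
    return float(sum(row[k] * th**k / rise for k in range(k_obs, n + 1)))


class TestFusFs:
    @pytest.mark.parametrize("n", [4, 5, 6])
    @pytest.mark.parametrize("theta", [0.5, 1.0, 2.5])
    def test_ewens_tail_matches_exact_enumeration(self, n, theta):
        for k_obs in range(1, n + 1):
            assert pg.ewens_k_tail(n, k_obs, theta) == pytest.approx(
                _ewens_tail_exact(n, k_obs, theta), abs=1e-12
            )

    def test_excess_haplotypes_for_small_theta_is_negative(self):
        # all three sequences distinct yet nearly identical: more haplotypes
        # than the small pairwise diversity predicts -> negative Fs
        seqs = ["AAAAAAAAAA", "AAAAAAAAAT", "AAAAAAAATA"]
        fs, _ = pg.fus_fs(seqs, n_sims=10, seed=0)
        assert fs < 0

    def test_monomorphic_is_na(self):
        fs, p = pg.fus_fs(["ACGT"] * 4, n_sims=10, seed=0)
        assert math.isnan(fs) and math.isnan(p)

    def test_p_value_seeded(self):
        seqs = ["AAAAA", "AAAAT", "AAATT", "AATTT"]
        a = pg.fus_fs(seqs, n_sims=200, seed=11)
        b = pg.fus_fs(seqs, n_sims=200, seed=11)
        assert a == b
        assert 0 <= a[1] <= 1


class TestMismatchObserved:
    def test_identical_sample_all_mass_at_zero(self, toy):
        obs = pg.mismatch_observed(toy["identical"]["alignment"])
        assert obs.tolist() == [6]

    def test_two_haplotype_classes(self, toy):
        fx = toy["two_haplotypes"]
        obs = pg.mismatch_observed(fx["alignment"])
        assert {i: int(c) for i, c in enumerate(obs) if c} == fx["expected"]["mismatch"]

    def test_sums_to_pair_count(self, study_aln):
        aln, _ = study_aln
        pop = aln.by_species()["structured_sp"].by_population()["Australia"]
        obs = pg.mismatch_observed(pop)
        n = pop.n
        assert obs.sum() == n * (n - 1) // 2


def _spatial_quadrature(tau, theta, M, J):
    """Numerical integration of the coalescence-time mixing density."""
    b = (1 + 2 * M) / theta
    w = math.exp(-b * tau) + (2 * M / (1 + 2 * M)) * (1 - math.exp(-b * tau))
    out = []
    for j in range(J):
        f1, _ = integrate.quad(
            lambda t: (1 / theta) * math.exp(-b * t) * stats.poisson.pmf(j, t), 0, tau
        )
        f2, _ = integrate.quad(
            lambda t: (w / theta)
            * math.exp(-(t - tau) / theta)
            * stats.poisson.pmf(j, t),
            tau,
            np.inf,
        )
        out.append(f1 + f2)
    return np.array(out)


class TestExpectedMismatch:
    def test_sudden_at_tau_zero_is_geometric(self):
        theta = 2.0
        j = np.arange(25)
        geom = theta**j / (theta + 1) ** (j + 1)
        assert np.allclose(pg.expected_mismatch("sudden", (0.0, theta), 25), geom)

    def test_spatial_at_tau_zero_is_geometric(self):
        theta = 1.3
        j = np.arange(25)
        geom = theta**j / (theta + 1) ** (j + 1)
        assert np.allclose(pg.expected_mismatch("spatial", (0.0, theta, 4.0), 25), geom)

    @pytest.mark.parametrize("params", [(2.5, 1.5, 3.0), (1.0, 0.4, 0.5), (5.0, 2.0, 20.0)])
    def test_spatial_matches_quadrature_oracle(self, params):
        closed = pg.expected_mismatch("spatial", params, 18)
        quad = _spatial_quadrature(*params, 18)
        assert np.allclose(closed, quad, atol=1e-9)

    def test_distributions_integrate_to_one(self):
        assert pg.expected_mismatch("sudden", (3.0, 1.5), 400).sum() == pytest.approx(1.0)
        assert pg.expected_mismatch("spatial", (3.0, 1.5, 2.0), 400).sum() == pytest.approx(
            1.0, abs=1e-9
        )

    def test_raggedness_hand_value(self):
        # x = (0.5, 0.5): r = (0.5-0.5)^2... with trailing 0: 0 + 0.25 = 0.25
        assert pg.raggedness([0.5, 0.5]) == pytest.approx(0.25)


class TestFitExpansion:
    def test_sudden_model_tau_recovery(self):
        """Average fitted tau within 20% of truth on simulated data (n=50)."""
        rng = np.random.default_rng(5)
        true_tau = 4.0
        taus = []
        for _ in range(60):
            d, _ = pg.simulate_coalescent_diffs(50, 1.0, rng, model="sudden", tau=true_tau)
            counts = np.bincount(d[np.triu_indices(50, 1)])
            taus.append(pg.fit_expansion(counts, n=50, model="sudden").tau)
        assert abs(np.mean(taus) - true_tau) / true_tau < 0.20

    def test_bootstrap_p_values_and_determinism(self, toy):
        obs = pg.mismatch_observed(toy["two_haplotypes"]["alignment"])
        f1 = pg.fit_expansion(obs, n=4, model="sudden", n_boot=50, seed=3)
        f2 = pg.fit_expansion(obs, n=4, model="sudden", n_boot=50, seed=3)
        assert 0 <= f1.p_ssd <= 1 and 0 <= f1.p_raggedness <= 1
        assert f1.p_ssd == f2.p_ssd and f1.tau == f2.tau

    def test_spatial_fit_returns_migration(self, study_aln):
        aln, _ = study_aln
        pop = aln.by_species()["starlike_sp"].by_population()["Eurasia"]
        fit = pg.fit_expansion(pg.mismatch_observed(pop), n=pop.n, model="spatial")
        assert fit.tau >= 0 and fit.theta >= 0 and fit.M >= 0
        assert fit.ssd < 0.05

    def test_empty_observed_is_error(self):
        with pytest.raises(ValueError):
            pg.fit_expansion([0, 0, 0])


class TestExpansionTime:
    def test_tau_zero_gives_zero(self):
        assert pg.expansion_time(0.0, 1.77e-8, 456).t_years == 0.0

    def test_study_scale_conversion(self):
        """tau = 1.081 at the COI clock over 456 bp dates to ~67 ka."""
        et = pg.expansion_time(1.081, 1.77e-8, 456, 1.0)
        assert et.t_years == pytest.approx(6.70e4, rel=0.01)

    def test_linear_in_tau(self):
        a = pg.expansion_time(1.0, 1.77e-8, 456).t_years
        b = pg.expansion_time(2.0, 1.77e-8, 456).t_years
        assert b == pytest.approx(2 * a)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            pg.expansion_time(1.0, 0.0, 456)
        with pytest.raises(ValueError):
            pg.expansion_time(-1.0, 1e-8, 456)
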