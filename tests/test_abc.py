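import numpy as np
import pytest
from scipy import stats

from barcodepop import abc_inference as abc
from barcodepop.abc_inference import Prior, PriorSet
from barcodepop.synthetic_data import study_priors


def _fast_priors(t1_range, t2_range):
    """Small, fast scenario priors for unit tests (short sequences)."""
    return PriorSet(
        params={
            "N1": Prior("loguniform", 1e4, 1e5),
            "N2": Prior("loguniform", 1e4, 1e5),
            "N3": Prior("loguniform", 1e4, 1e5),
            "N2b": Prior("loguniform", 10, 1e3),
            "N3b": Prior("loguniform", 10, 1e3),
            "t1": Prior("uniform", *t1_range),
            "t2": Prior("uniform", *t2_range),
            "t_db": Prior("uniform", 100, 2000),
            "mu": Prior("fixed", 2e-8),
        },
        kappa=4.0,
        gamma_shape=None,
    )


@pytest.fixture(scope="module")
def small_ref():
    priors = {
        "recent": _fast_priors((30_000, 200_000), (5_000, 25_000)),
        "ancient": _fast_priors((600_000, 1_500_000), (250_000, 500_000)),
    }
    ref = abc.build_reference(
        priors, n_sims=600, sample_sizes=(8, 8, 8), L=200, seed=21
    )
    return ref, priors


class TestPriors:
    def test_draws_respect_bounds(self):
        rng = np.random.default_rng(0)
        p = Prior("loguniform", 10, 1000)
        draws = [p.draw(rng) for _ in range(200)]
        assert min(draws) >= 10 and max(draws) <= 1000

    def test_invalid_bounds_raise(self):
        with pytest.raises(ValueError):
            Prior("uniform", 5, 5)
        with pytest.raises(ValueError):
            Prior("loguniform", -1, 10)
        with pytest.raises(ValueError):
            Prior("exotic", 0, 1)

    def test_prior_set_requires_all_parameters(self):
        with pytest.raises(ValueError, match="mu"):
            PriorSet(params={"N1": Prior("uniform", 1, 2)})


class TestSummaryStatistics:
    def test_hand_checked_two_population_vector(self):
        # pop a: two identical; pop b: two sequences differing at one site
        mat = np.array(
            [
                [0, 1, 2, 3, 0],
                [0, 1, 2, 3, 0],
                [3, 1, 2, 3, 0],
                [3, 1, 2, 0, 0],
            ]
        )
        pops = ["a", "a", "b", "b"]
        vec, names = abc.summary_statistics(mat, pops)
        s = dict(zip(names, vec))
        assert s["a:K"] == 1 and s["b:K"] == 2
        assert s["a:S"] == 0 and s["b:S"] == 1
        assert s["a:mean_pairdiff"] == 0.0 and s["b:mean_pairdiff"] == 1.0
        assert s["a:private_S"] == 0 and s["b:private_S"] == 1
        # between: pairs (r0,r2)=1 (r0,r3)=2 (r1,r2)=1 (r1,r3)=2 -> 1.5
        assert s["a-b:between_mean"] == pytest.approx(1.5)
        # Hudson-style: Hw = mean(0, 1) = 0.5, Hb = 1.5
        assert s["a-b:fst"] == pytest.approx(1 - 0.5 / 1.5)
        assert s["a-b:shared_K"] == 0
        assert s["a:tajima_D_na"] == 1.0  # n < 4 within the population

    def test_shared_haplotypes_counted(self):
        mat = np.array([[0, 1], [0, 1], [0, 1], [2, 1]])
        vec, names = abc.summary_statistics(mat, ["a", "a", "b", "b"])
        s = dict(zip(names, vec))
        assert s["a-b:shared_K"] == 1

    def test_population_roles_control_vector_ordering(self):
        """Observed vectors must align with the reference's pop1/2/3 columns
        even when the data's population labels sort differently."""
        from barcodepop.sequence_io import LabeledAlignment, Record

        seqs = {"zebra": ["AAAA", "AAAT"], "alpha": ["TTTT", "TTAA"]}
        recs = [
            Record(id=f"{p}{i}", sequence=s, species="x", population=p)
            for p, ss in seqs.items()
            for i, s in enumerate(ss)
        ]
        aln = LabeledAlignment(recs)
        # zebra plays pop1 although it sorts after alpha
        vec, names = abc.summarize_alignment(
            aln, roles={"zebra": "pop1", "alpha": "pop2"}
        )
        s = dict(zip(names, vec))
        assert s["pop1:mean_pairdiff"] == 1.0  # zebra pair: 1 difference
        assert s["pop2:mean_pairdiff"] == 2.0  # alpha pair: 2 differences
        with pytest.raises(ValueError, match="role"):
            abc.summarize_alignment(aln, roles={"zebra": "pop1"})


class TestReferenceTable:
    def test_reproducible_under_seed(self):
        priors = {"only": _fast_priors((30_000, 60_000), (5_000, 20_000))}
        a = abc.build_reference(priors, n_sims=10, sample_sizes=(4, 4, 4), L=100, seed=5)
        b = abc.build_reference(priors, n_sims=10, sample_sizes=(4, 4, 4), L=100, seed=5)
        assert a.df.equals(b.df)

    def test_point_mass_priors_fix_parameters(self):
        pri = PriorSet(
            params={
                "N1": Prior("fixed", 5e4),
                "N2": Prior("fixed", 5e4),
                "N3": Prior("fixed", 5e4),
                "N2b": Prior("fixed", 50),
                "N3b": Prior("fixed", 50),
                "t1": Prior("fixed", 50_000),
                "t2": Prior("fixed", 10_000),
                "t_db": Prior("fixed", 1_000),
                "mu": Prior("fixed", 2e-8),
            }
        )
        ref = abc.build_reference({"pt": pri}, n_sims=8, sample_sizes=(4, 4, 4), L=100, seed=2)
        assert (ref.df["t2"] == 10_000).all()
        assert ref.df[ref.stat_names].std().sum() > 0  # summaries still vary

    def test_impossible_priors_raise(self):
        bad = _fast_priors((5_000, 6_000), (50_000, 60_000))  # t2 always > t1
        with pytest.raises(abc.ScenarioError):
            abc.build_reference({"bad": bad}, n_sims=2, sample_sizes=(4, 4, 4), L=100, seed=1)


class TestScenarioChoice:
    def test_exact_row_with_k1(self, small_ref):
        ref, _ = small_ref
        row = ref.df.iloc[17]
        obs = row[ref.stat_names].to_numpy(dtype=float)
        post = abc.scenario_posterior_direct(ref, obs, k=1)
        assert post[row["scenario"]] == 1.0

    def test_probabilities_sum_to_one(self, small_ref):
        ref, _ = small_ref
        obs = ref.stats_matrix().mean(axis=0)
        post = abc.scenario_posterior_direct(ref, obs, k=50)
        assert sum(post.values()) == pytest.approx(1.0)

    def test_invariant_to_affine_stat_rescaling(self, small_ref):
        """Normalisation correctness: scaling a statistic changes nothing."""
        ref, _ = small_ref
        obs = ref.stats_matrix()[3].copy()
        base = abc.scenario_posterior_direct(ref, obs, k=50)
        scaled = abc.ReferenceTable(
            df=ref.df.copy(),
            param_names=ref.param_names,
            stat_names=ref.stat_names,
            mad=ref.mad.copy(),
            sample_sizes=ref.sample_sizes,
            L=ref.L,
            base_freqs=ref.base_freqs,
        )
        col = ref.stat_names[2]
        scaled.df[col] = scaled.df[col] * 7.0
        stats_mat = scaled.df[ref.stat_names].to_numpy(dtype=float)
        med = np.median(stats_mat, axis=0)
        mad = np.median(np.abs(stats_mat - med), axis=0)
        mad[mad == 0] = 1.0
        scaled.mad = mad
        obs2 = obs.copy()
        obs2[2] *= 7.0
        rescaled = abc.scenario_posterior_direct(scaled, obs2, k=50)
        # many statistics are integer-valued so distances tie exactly; the
        # invariance holds up to tie-breaking at the k-th neighbour boundary
        for name in base:
            assert rescaled[name] == pytest.approx(base[name], abs=0.1)

    def test_separated_scenarios_classified_correctly(self, small_ref):
        ref, priors = small_ref
        rng = np.random.default_rng(3)
        correct = 0
        for i in range(30):
            name = ["recent", "ancient"][i % 2]
            stats_vec = abc._simulate_pod(name, priors[name], ref, rng)
            if abc._classify(ref, stats_vec, k=40) == name:
                correct += 1
        assert correct / 30 > 0.75

    def test_logistic_agrees_with_direct_when_separated(self, small_ref):
        ref, priors = small_ref
        rng = np.random.default_rng(4)
        for name in ("recent", "ancient"):
            stats_vec = abc._simulate_pod(name, priors[name], ref, rng)
            direct = abc.scenario_posterior_direct(ref, stats_vec, k=60)
            logistic = abc.scenario_posterior_logistic(ref, stats_vec, closest_fraction=0.2)
            assert sum(logistic.values()) == pytest.approx(1.0, abs=1e-6)
            assert abs(direct[name] - logistic[name]) < 0.15

    def test_k_validation(self, small_ref):
        ref, _ = small_ref
        with pytest.raises(ValueError):
            abc.scenario_posterior_direct(ref, ref.stats_matrix()[0], k=0)


class TestParameterEstimation:
    def test_no_data_limit_returns_prior(self, small_ref):
        """closest_fraction=1 without adjustment reproduces the prior."""
        ref, priors = small_ref
        obs = ref.stats_matrix().mean(axis=0)
        est = abc.estimate_parameters(
            ref, obs, "recent", closest_fraction=1.0, adjust=False
        )
        t2 = est["samples"]["t2"].to_numpy()
        lo, hi = priors["recent"].params["t2"].low, priors["recent"].params["t2"].high
        u = (t2 - lo) / (hi - lo)
        assert stats.kstest(u, "uniform").pvalue > 0.01

    def test_too_few_retained_is_error(self, small_ref):
        ref, _ = small_ref
        obs = ref.stats_matrix().mean(axis=0)
        with pytest.raises(ValueError, match="reference table"):
            abc.estimate_parameters(ref, obs, "recent", closest_fraction=0.01)

    def test_summary_quantiles_ordered(self, small_ref):
        ref, _ = small_ref
        obs = ref.stats_matrix()[10]
        est = abc.estimate_parameters(ref, obs, "recent", closest_fraction=0.5)
        s = est["summary"]
        assert (s["q2.5"] <= s["median"]).all()
        assert (s["median"] <= s["q97.5"]).all()

    def test_unknown_scenario_is_error(self, small_ref):
        ref, _ = small_ref
        with pytest.raises(ValueError):
            abc.estimate_parameters(ref, ref.stats_matrix()[0], "nope")


class TestDiagnostics:
    def test_prior_preevaluation_median_obs_unflagged(self, small_ref):
        ref, _ = small_ref
        obs = np.median(ref.stats_matrix(), axis=0)
        rep = abc.prior_preevaluation(ref, obs)
        assert not rep["flag"].any()
        # skewed discrete statistics keep median quantiles loosely central
        assert (rep["quantile"] - 0.5).abs().max() < 0.3

    def test_prior_preevaluation_outlier_flagged(self, small_ref):
        ref, _ = small_ref
        obs = ref.stats_matrix().max(axis=0) * 10 + 100
        rep = abc.prior_preevaluation(ref, obs)
        assert rep["flag"].any()

    def test_model_check_flags_extreme_observation(self, small_ref):
        ref, priors = small_ref
        obs = ref.stats_matrix()[5]
        est = abc.estimate_parameters(ref, obs, "recent", closest_fraction=0.5)
        extreme = obs * 0 + 1e6
        rep = abc.model_check(
            est["samples"], "recent", extreme, ref, priors["recent"], n_rep=20, seed=1
        )
        assert rep["flag"].mean() > 0.5

    def test_scenario_confidence_errors_bounded(self, small_ref):
        ref, priors = small_ref
        res = abc.scenario_confidence(
            ref, priors, n_pods=20, k=40, seed=8, target="recent"
        )
        assert 0 <= res["type1"] <= 1
        assert 0 <= res["type2"] <= 1
        # scenarios are well separated: both error rates should be small
        assert res["type1"] < 0.4 and res["type2"] < 0.4
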