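import math

import numpy as np
import pandas as pd
import pytest

from elbar import (
    DetectionResult,
    SimConfig,
    binarize,
    compute_betas,
    f1_score,
    intensity_zscore,
    merge_methylomes,
    polarization_fraction,
    probe_success_rate,
    rank_correlation,
    set_enrichment,
    simulate_manifest,
    simulate_sample,
)
from elbar.sigset import Manifest


def det_of(pvals):
    return DetectionResult(method="X", p=pd.Series(pvals, dtype=float))


class TestSuccessRate:
    def test_counting(self):
        assert probe_success_rate(det_of([0.01, 0.2, 0.04])) == pytest.approx(2 / 3)

    def test_all_failed(self):
        assert probe_success_rate(det_of([1.0, 1.0])) == 0.0

    def test_non_decreasing_in_threshold(self):
        rng = np.random.default_rng(1)
        det = det_of(rng.uniform(0, 1, 500))
        rates = [probe_success_rate(det, t) for t in np.linspace(0.01, 1.0, 25)]
        assert (np.diff(rates) >= 0).all()


class TestBinarize:
    @pytest.mark.parametrize("beta,call", [(0.6, 1.0), (0.5, 0.0), (0.49, 0.0), (1.0, 1.0)])
    def test_strict_rule(self, beta, call):
        assert binarize(pd.Series([beta]))[0] == call

    def test_nan_preserved(self):
        assert math.isnan(binarize(pd.Series([np.nan]))[0])


class TestF1:
    def test_printed_formula(self):
        # TP=3, FP=1, FN=1 -> 2*3 / (6+1+1) = 0.75
        test = pd.Series([1, 1, 1, 1, 0, 0], dtype=float)
        ref = pd.Series([1, 1, 1, 0, 1, 0], dtype=float)
        assert f1_score(test, ref) == pytest.approx(0.75)

    def test_identity_is_one(self):
        v = pd.Series([1, 0, 1, 0], dtype=float)
        assert f1_score(v, v) == 1.0

    def test_total_miss_is_zero(self):
        assert f1_score(pd.Series([0.0] * 4), pd.Series([1.0] * 4)) == 0.0

    def test_undefined_probes_excluded(self):
        test = pd.Series({"a": 1.0, "b": np.nan, "c": 0.0})
        ref = pd.Series({"a": 1.0, "b": 0.0, "c": 0.0})
        assert f1_score(test, ref) == 1.0

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError):
            f1_score(pd.Series({"a": np.nan}), pd.Series({"a": 1.0}))


class TestSpearman:
    def test_monotone(self):
        assert rank_correlation(pd.Series([1, 2, 3]), pd.Series([10, 20, 30])) == 1.0

    def test_anti_monotone(self):
        assert rank_correlation(pd.Series([1, 2, 3]), pd.Series([30, 20, 10])) == -1.0

    def test_midranks_for_ties(self):
        # both vectors rank as {1, 2.5, 2.5, 4} -> rho = 1
        rho = rank_correlation(pd.Series([1, 2, 2, 4]), pd.Series([1, 3, 3, 4]))
        assert rho == pytest.approx(1.0)

    def test_constant_vector_undefined(self):
        assert math.isnan(rank_correlation(pd.Series([1, 1, 1]), pd.Series([1, 2, 3])))


class TestPolarization:
    def test_half_polarized(self):
        ref = pd.Series([0.5, 0.5, 0.9])
        test = pd.Series([0.05, 0.5, 0.9])
        assert polarization_fraction(test, ref) == pytest.approx(0.5)

    def test_identical_vectors_zero(self):
        v = pd.Series([0.4, 0.5, 0.6])
        assert polarization_fraction(v, v) == 0.0

    def test_fully_dichotomized_one(self):
        ref = pd.Series([0.4, 0.5, 0.6])
        assert polarization_fraction(pd.Series([0.0, 1.0, 1.0]), ref) == 1.0

    def test_no_eligible_probes_raises(self):
        with pytest.raises(ValueError):
            polarization_fraction(pd.Series([0.5]), pd.Series([0.9]))


class TestMerge:
    def test_mean_of_defined(self):
        a = pd.Series({"p": 0.0})
        b = pd.Series({"p": 1.0})
        merged, support = merge_methylomes([a, b])
        assert merged["p"] == 0.5 and support["p"] == 2

    def test_single_support(self):
        a = pd.Series({"p": 0.3, "q": np.nan})
        b = pd.Series({"p": np.nan, "q": np.nan})
        merged, support = merge_methylomes([a, b])
        assert merged["p"] == 0.3 and support["p"] == 1
        assert math.isnan(merged["q"]) and support["q"] == 0

    def test_counting_mean(self):
        vecs = [pd.Series({"p": 1.0 if i < 4 else 0.0}) for i in range(10)]
        merged, _ = merge_methylomes(vecs)
        assert merged["p"] == pytest.approx(0.4)

    def test_law_of_large_numbers_at_200_cells(self):
        """Merged single-cell allelic betas converge to the population beta."""
        rng = np.random.default_rng(9)
        beta_true = rng.uniform(0, 1, 300)
        idx = pd.Index([f"p{i}" for i in range(300)])
        vecs = [
            pd.Series(rng.binomial(2, beta_true) / 2.0, index=idx) for _ in range(200)
        ]
        merged, support = merge_methylomes(vecs)
        dev = np.abs(merged.to_numpy() - beta_true)
        assert (support == 200).all()
        assert np.mean(dev) < 0.025
        assert np.mean(dev <= 0.05) >= 0.95


class TestZscore:
    def test_hand_example(self):
        z = intensity_zscore(pd.Series([2.0, 4.0, 6.0]))
        assert list(z) == pytest.approx([-1.0, 0.0, 1.0])

    def test_location_invariance_and_normalization(self):
        rng = np.random.default_rng(2)
        x = pd.Series(rng.normal(10, 3, 100))
        z1, z2 = intensity_zscore(x), intensity_zscore(x + 42.0)
        assert np.allclose(z1, z2)
        assert z1.mean() == pytest.approx(0.0, abs=1e-12)
        assert z1.std(ddof=1) == pytest.approx(1.0)

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            intensity_zscore(pd.Series([3.0, 3.0, 3.0]))


def manifest_with_set(members, universe):
    rows = {pid: ("II", 10, "SINGLE", "S" if pid in members else "") for pid in universe}
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["design", "n_C", "copy_class", "probe_sets"]
    )
    table.index.name = "probe_id"
    return Manifest(table)


def hypergeom_two_sided(a, b, c, d):
    """Independent oracle: sum of table probabilities <= that of the observed."""
    from scipy.stats import hypergeom

    n_query, n_set, n_tot = a + b, a + c, a + b + c + d
    rv = hypergeom(n_tot, n_set, n_query)
    p_obs = rv.pmf(a)
    support = np.arange(max(0, n_query + n_set - n_tot), min(n_query, n_set) + 1)
    return float(rv.pmf(support)[rv.pmf(support) <= p_obs * (1 + 1e-9)].sum())


class TestEnrichment:
    def test_log2_odds_ratio_example(self):
        # table (40, 60, 160, 740): OR = 3.0833, log2 = 1.6245
        universe = [f"p{i}" for i in range(1000)]
        members = set(universe[:40]) | set(universe[100:260])
        query = set(universe[:100])
        man = manifest_with_set(members, universe)
        res = set_enrichment(query, man, universe)
        assert res.loc["S", "overlap"] == 40
        assert res.loc["S", "log2_odds_ratio"] == pytest.approx(np.log2(40 * 740 / (60 * 160)))

    def test_independent_set_or_one(self):
        universe = [f"p{i}" for i in range(100)]
        members = set(universe[:20]) | set(universe[50:58])
        # query = first 10 of the set and 25 outside: a=10,b=25,c=18,d=47? build exact
        members = set(universe[:50])
        query = set(universe[:25]) | set(universe[50:75])  # a=25,b=25,c=25,d=25
        man = manifest_with_set(members, universe)
        res = set_enrichment(query, man, universe)
        assert res.loc["S", "log2_odds_ratio"] == pytest.approx(0.0)

    @pytest.mark.parametrize(
        "a,b,c,d", [(5, 10, 3, 12), (0, 8, 7, 15), (10, 0, 5, 15), (1, 1, 1, 1), (12, 3, 4, 11)]
    )
    def test_p_matches_hypergeometric_oracle(self, a, b, c, d):
        universe = [f"p{i}" for i in range(a + b + c + d)]
        members = set(universe[: a + c])
        query = set(universe[:a]) | set(universe[a + c : a + c + b])
        man = manifest_with_set(members, universe)
        res = set_enrichment(query, man, universe)
        assert res.loc["S", "overlap"] == a
        assert res.loc["S", "p"] == pytest.approx(hypergeom_two_sided(a, b, c, d), rel=1e-6)

    def test_bh_adjustment_step_up(self):
        from statsmodels.stats.multitest import multipletests

        # frozen hand computation of the step-up procedure
        fdr = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        assert list(fdr) == pytest.approx([0.03, 0.03, 0.04])

    def test_query_must_be_subset(self):
        universe = [f"p{i}" for i in range(10)]
        man = manifest_with_set(set(universe[:3]), universe)
        with pytest.raises(ValueError):
            set_enrichment({"zzz"}, man, universe)

    def test_fdr_at_least_p(self):
        cfg = SimConfig(n_probes=500, seed=3, input_scale=0.05)
        man = simulate_manifest(cfg)
        ss, truth = simulate_sample(man, cfg)
        detected = set(truth.index[truth["captured_copies"] > 0])
        res = set_enrichment(detected, man, set(truth.index))
        assert (res["fdr"] >= res["p"] - 1e-12).all()
        assert res["fdr"].between(0, 1).all()
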