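"""Rank statistics: Bray-Curtis, ATS, Wilcoxon, Cliff's delta, BH, screen."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

import fibrascope as fs
from fibrascope import design as dsg
from fibrascope.errors import DegenerateDataError
from fibrascope.stats import ats_interaction, subject_cell_table


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert fs.bray_curtis([1, 2, 3], [1, 2, 3]) == 0.0

    def test_disjoint_supports_one(self):
        assert fs.bray_curtis([1, 0, 2], [0, 3, 0]) == 1.0

    def test_hand_value(self):
        assert fs.bray_curtis([1, 0, 3], [0, 2, 1]) == pytest.approx(5 / 7)

    def test_both_all_zero_rejected(self):
        with pytest.raises(DegenerateDataError):
            fs.bray_curtis([0, 0], [0, 0])

    @given(st.lists(st.tuples(st.floats(0, 100), st.floats(0, 100)),
                    min_size=1, max_size=20))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_and_range(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if (x + y).sum() == 0:
            return
        d = fs.bray_curtis(x, y)
        assert d == pytest.approx(fs.bray_curtis(y, x))
        assert 0 <= d <= 1

    def test_shared_constant_feature_decreases_dissimilarity(self):
        x, y = np.array([1.0, 0.0, 3.0]), np.array([0.0, 2.0, 1.0])
        base = fs.bray_curtis(x, y)
        extended = fs.bray_curtis(np.append(x, 5.0), np.append(y, 5.0))
        assert extended < base


class TestAtsInteraction:
    def simulate_null(self, rng, n, sd_subject=1.0, sd_noise=1.0):
        subject = rng.normal(0, sd_subject, (n, 1))
        return subject + rng.normal(0, sd_noise, (n, 4))

    def test_all_tied_rejected(self):
        with pytest.raises(DegenerateDataError):
            ats_interaction(np.ones((6, 4)))

    def test_too_few_subjects_rejected(self):
        with pytest.raises(DegenerateDataError):
            ats_interaction(np.array([[1.0, 2.0, 3.0, 4.0]]))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = self.simulate_null(rng, 12)
        assert ats_interaction(x) == pytest.approx(ats_interaction(np.exp(x)))

    def test_null_rejection_rate_near_nominal(self):
        """Type-I error at alpha=0.05 within the 99% binomial band over
        200 null simulations (n=40 subjects)."""
        rng = np.random.default_rng(12345)
        rejections = sum(
            ats_interaction(self.simulate_null(rng, 40)) <= 0.05
            for _ in range(200))
        # Binomial(200, 0.05): 10 +/- 2.576 * sqrt(9.5)
        assert 2 <= rejections <= 18

    def test_agrees_with_within_subject_permutation_oracle(self):
        """On n=8 data the ATS p-value is close to the exact within-subject
        permutation p (all 2^8 bread-label swaps)."""
        rng = np.random.default_rng(77)
        x = self.simulate_null(rng, 8)
        x[:, 1] += 1.2  # mild interaction signal on mf_post
        p_obs = ats_interaction(x)
        count = 0
        total = 0
        for flips in itertools.product([False, True], repeat=8):
            perm = x.copy()
            for i, flip in enumerate(flips):
                if flip:  # swap the two bread blocks within the subject
                    perm[i] = perm[i][[2, 3, 0, 1]]
            total += 1
            if ats_interaction(perm) <= p_obs:
                count += 1
        p_perm = count / total
        assert abs(p_obs - p_perm) <= 0.05

    def test_detects_planted_interaction(self):
        rng = np.random.default_rng(9)
        x = self.simulate_null(rng, 40, sd_noise=0.5)
        x[:, 1] += 2.0
        assert ats_interaction(x) < 1e-4


class TestWilcoxonSignedRank:
    def test_five_positive_pairs_exact(self):
        pre = np.zeros(5)
        post = np.array([1.0, 2.0, 0.5, 3.0, 1.5])
        assert fs.wilcoxon_signed_rank(pre, post) == pytest.approx(2 / 32)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        pre, post = rng.normal(size=12), rng.normal(size=12)
        assert fs.wilcoxon_signed_rank(pre, post) == pytest.approx(
            fs.wilcoxon_signed_rank(post, pre))

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            d = rng.normal(size=rng.integers(6, 20))
            expected = sps.wilcoxon(d, method="exact").pvalue
            assert fs.wilcoxon_signed_rank(np.zeros_like(d), d) == pytest.approx(expected)

    def test_ties_match_exhaustive_enumeration_n4(self):
        """Mid-rank handling of tied |differences| equals brute force."""
        d = np.array([1.0, -1.0, 2.0, 3.0])  # one tie among |d|
        ranks = sps.rankdata(np.abs(d))
        w_obs = ranks[d > 0].sum()
        stats_all = [np.where(signs, ranks, 0).sum()
                     for signs in itertools.product([0, 1], repeat=4)]
        cdf = np.mean([w <= w_obs for w in stats_all])
        sf = np.mean([w >= w_obs for w in stats_all])
        expected = min(1.0, 2 * min(cdf, sf))
        assert fs.wilcoxon_signed_rank(np.zeros_like(d), d) == pytest.approx(expected)

    def test_all_zero_differences_rejected(self):
        with pytest.raises(DegenerateDataError):
            fs.wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_normal_approximation_close_to_exact_at_boundary(self):
        rng = np.random.default_rng(8)
        d = rng.normal(0.4, 1.0, 26)  # just above the exact-mode limit
        approx = fs.wilcoxon_signed_rank(np.zeros_like(d), d)
        exact = sps.wilcoxon(d, method="exact").pvalue
        assert approx == pytest.approx(exact, abs=0.01)

    def test_pratt_zero_method(self):
        d = np.array([0.0, 1.0, -2.0, 3.0, 4.0])
        p = fs.wilcoxon_signed_rank(np.zeros_like(d), d, zero_method="pratt")
        expected = sps.wilcoxon(d, zero_method="pratt", method="approx",
                                correction=True).pvalue
        assert 0 < p <= 1
        assert p == pytest.approx(expected, abs=0.05)


class TestCliffsDelta:
    def test_identical_distributions_zero(self):
        x = [1, 2, 3, 4]
        assert fs.cliffs_delta(x, x) == 0.0

    def test_complete_separation(self):
        assert fs.cliffs_delta([5, 6, 7], [1, 2]) == 1.0
        assert fs.cliffs_delta([1, 2], [5, 6, 7]) == -1.0

    def test_hand_value(self):
        assert fs.cliffs_delta([1, 2, 3], [2, 3, 4]) == pytest.approx(-5 / 9)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            fs.cliffs_delta([], [1.0])

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=15),
           st.lists(st.floats(-50, 50), min_size=1, max_size=15))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_antisymmetry_and_range(self, x, y):
        d = fs.cliffs_delta(x, y)
        assert d == pytest.approx(-fs.cliffs_delta(y, x))
        assert -1 <= d <= 1

    def test_location_shift_monotonicity(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=30)
        deltas = [fs.cliffs_delta(y + shift, y) for shift in (0.0, 0.5, 1.0, 2.0)]
        assert deltas == sorted(deltas)


class TestGradeEffectSize:
    @pytest.mark.parametrize("delta,grade", [
        (0.72, "large"), (-0.27, "small"), (0.46, "medium"), (0.07, "negligible"),
        (0.04, "negligible"), (0.147, "small"), (0.33, "medium"), (0.474, "large"),
        (-1.0, "large"), (0.0, "negligible"),
    ])
    def test_printed_thresholds(self, delta, grade):
        assert fs.grade_effect_size(delta).grade == grade

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fs.grade_effect_size(1.2)


class TestBenjaminiHochberg:
    def test_single_p_unchanged(self):
        assert fs.benjamini_hochberg([0.04])[0] == pytest.approx(0.04)

    def test_hand_stepup_value(self):
        np.testing.assert_allclose(fs.benjamini_hochberg([0.01, 0.02, 0.04]),
                                   [0.03, 0.03, 0.04])

    def test_permutation_equivariance(self):
        p = np.array([0.3, 0.01, 0.2, 0.04, 0.9])
        perm = np.array([4, 2, 0, 1, 3])
        np.testing.assert_allclose(fs.benjamini_hochberg(p[perm]),
                                   fs.benjamini_hochberg(p)[perm])

    def test_q_at_least_p(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        assert (fs.benjamini_hochberg(p) >= p - 1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fs.benjamini_hochberg([0.5, 1.5])


@pytest.fixture(scope="module")
def screen_inputs():
    catalog = fs.generate_catalog(n_genes=1000, n_msp=10, seed=21)
    design, comp = fs.generate_cohort(
        catalog, n_subjects=20,
        effects=(fs.PlantedEffect("msp_0004", 0.8),), seed=22)
    return design, comp.T  # features x samples


class TestDifferentialScreen:

    def test_one_row_per_analyzable_feature(self, screen_inputs):
        design, features = screen_inputs
        results, excluded = fs.differential_screen(features, design)
        assert len(results) + len(excluded) == len(features)
        assert (results["q_value"] >= results["p_interaction"] - 1e-12).all()
        assert (results["significant"] == (results["q_value"] <= 0.1)).all()

    def test_planted_feature_flagged_with_large_grade(self, screen_inputs):
        design, features = screen_inputs
        results, _ = fs.differential_screen(features, design)
        row = results.set_index("feature_id").loc["msp_0004"]
        assert row["significant"]
        assert row["grade_mf"] == "large"
        assert row["cliffs_delta_mf"] > 0.4

    def test_degenerate_feature_reported_not_tested(self, screen_inputs):
        design, features = screen_inputs
        features = features.copy()
        features.loc["flat"] = 1.0
        results, excluded = fs.differential_screen(features, design)
        assert "flat" in excluded["feature_id"].tolist()
        assert "flat" not in results["feature_id"].tolist()

    def test_misaligned_samples_rejected(self, screen_inputs):
        design, features = screen_inputs
        with pytest.raises(KeyError):
            fs.differential_screen(features.iloc[:, :5], design)


class TestDeltaDeltaSpearman:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(3)
        x = pd.DataFrame({"f": rng.normal(size=15)})
        out = fs.delta_delta_spearman(x, x.rename(columns={"f": "v"}))
        assert out.iloc[0]["rho"] == pytest.approx(1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        base = rng.normal(size=20)
        f = pd.DataFrame({"f": base})
        v1 = pd.DataFrame({"v": base + rng.normal(0, 0.5, 20)})
        v2 = np.exp(v1)
        rho1 = fs.delta_delta_spearman(f, v1).iloc[0]["rho"]
        rho2 = fs.delta_delta_spearman(f, v2).iloc[0]["rho"]
        assert rho1 == pytest.approx(rho2)

    def test_too_few_pairs_skipped(self):
        f = pd.DataFrame({"f": [1.0, 2.0, np.nan, np.nan]})
        v = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        out = fs.delta_delta_spearman(f, v)
        assert np.isnan(out.iloc[0]["rho"])


class TestIntraIndividualDissimilarity:
    def test_per_subject_per_arm_values(self):
        catalog = fs.generate_catalog(n_genes=500, n_msp=4, seed=31)
        design, comp = fs.generate_cohort(catalog, n_subjects=6, seed=32)
        out = fs.intra_individual_dissimilarity(comp.T, design)
        assert out.shape == (6, 2)
        assert ((0 <= out) & (out <= 1)).all().all()
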