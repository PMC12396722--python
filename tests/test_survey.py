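"""Forced-choice survey analysis: proportions, Monte Carlo null, correlations."""

import numpy as np
import pandas as pd
import pytest

import graphophon as gp


def make_responses(rows):
    return gp.ResponseSet(
        pd.DataFrame(rows, columns=["participant_id", "group", "question_id", "chosen_type", "assignment_consistent"])
    )


@pytest.fixture
def tiny_responses():
    """3 UK participants × 10 questions: 12 english, 10 chinese, 8 korean
    choices; 7 of the first 10 records assignment-consistent."""
    seq = ["english"] * 12 + ["chinese"] * 10 + ["korean"] * 8
    rows = []
    for i, choice in enumerate(seq):
        part, q = divmod(i, 10)
        rows.append((f"UK_{part}", "UK", q + 1, choice, i % 10 < 7))
    return make_responses(rows)


class TestResponseSetValidation:
    def test_duplicate_participant_question_rejected(self):
        rows = [("a", "UK", 1, "english", True), ("a", "UK", 1, "korean", True)]
        with pytest.raises(ValueError, match="duplicate"):
            make_responses(rows)

    def test_incomplete_questions_rejected(self):
        rows = [("a", "UK", 1, "english", True), ("a", "UK", 2, "english", True),
                ("b", "UK", 1, "korean", True)]
        with pytest.raises(ValueError, match="complete"):
            make_responses(rows)

    def test_unknown_group_rejected(self):
        with pytest.raises(ValueError, match="group"):
            make_responses([("a", "FR", 1, "english", True)])


class TestProportions:
    def test_unanimous_group(self):
        rows = [(f"p{i}", "KR", q, "korean", True) for i in range(2) for q in (1, 2)]
        r = make_responses(rows)
        assert gp.preference_proportions(r, "KR") == {"english": 0.0, "chinese": 0.0, "korean": 1.0}

    def test_counting_example(self, tiny_responses):
        props = gp.preference_proportions(tiny_responses, "UK")
        assert props["english"] == pytest.approx(0.4)
        assert props["chinese"] == pytest.approx(1 / 3)
        assert props["korean"] == pytest.approx(8 / 30)
        assert sum(props.values()) == pytest.approx(1.0)

    def test_unknown_group_raises(self, tiny_responses):
        with pytest.raises(KeyError):
            gp.preference_proportions(tiny_responses, "KR")

    def test_uniform_simulation_recovers_one_third(self):
        rs = gp.simulate_responses(gp.ResponseGenConfig(n_per_group={"UK": 300}, seed=8))
        se = np.sqrt((1 / 3) * (2 / 3) / 3000)
        for p in gp.preference_proportions(rs, "UK").values():
            assert p == pytest.approx(1 / 3, abs=3 * se)


class TestIntendedRate:
    def test_all_intended(self):
        rows = [(f"p{i}", "UK", q, "english", True) for i in range(2) for q in (1, 2)]
        assert gp.intended_rate(make_responses(rows))["UK"] == 1.0

    def test_matches_preference_proportion_under_any_designation(self, tiny_responses):
        props = gp.preference_proportions(tiny_responses, "UK")
        for t in gp.MATERIAL_TYPES:
            assert gp.intended_rate(tiny_responses, {"UK": t})["UK"] == pytest.approx(props[t])

    def test_missing_designation_raises(self, tiny_responses):
        with pytest.raises(KeyError):
            gp.intended_rate(tiny_responses, {"KR": "korean"})


class TestMappingConsistency:
    def test_fixture_rate(self, tiny_responses):
        # 7 of each participant's 10 records are consistent
        assert gp.mapping_consistency_rate(tiny_responses) == pytest.approx(0.7)

    def test_all_consistent(self):
        rows = [("a", "UK", q, "english", True) for q in (1, 2, 3)]
        assert gp.mapping_consistency_rate(make_responses(rows)) == 1.0


class TestPermutationNull:
    def test_rows_sum_to_one(self):
        null = gp.permutation_null(50, 10, reps=20, seed=1)
        assert np.allclose(null.replicates.sum(axis=1), 1.0)

    def test_reproducible_from_seed(self):
        a = gp.permutation_null(50, 10, reps=100, seed=9)
        b = gp.permutation_null(50, 10, reps=100, seed=9)
        assert np.array_equal(a.replicates, b.replicates)

    def test_mean_and_sd_match_binomial_theory(self):
        null = gp.permutation_null(266, 10, reps=10_000, seed=3)
        n = 266 * 10
        assert null.replicates.mean(axis=0) == pytest.approx(1 / 3, abs=0.001)
        sd_theory = np.sqrt((1 / 3) * (2 / 3) / n)
        for t in gp.MATERIAL_TYPES:
            assert null.column(t).std() == pytest.approx(sd_theory, rel=0.05)


class TestPermutationP:
    def test_observed_at_chance_gives_p_near_one(self):
        null = gp.permutation_null(266, 10, reps=2000, seed=5)
        assert gp.permutation_p_value(null, 1 / 3, "korean") > 0.9

    def test_far_observed_gives_minimal_smoothed_p(self):
        null = gp.permutation_null(266, 10, reps=2000, seed=5)
        assert gp.permutation_p_value(null, 0.45, "korean") == pytest.approx(1 / 2001)

    def test_ties_count_as_extreme(self):
        null = gp.NullDistribution(np.array([[0.4, 0.3, 0.3]] * 4), 4, 1, 10, 0)
        # observed deviation equals every replicate's deviation → all 4 count
        assert gp.permutation_p_value(null, 0.4, "english") == pytest.approx(1.0)


class TestQuestionMatrix:
    def test_unanimous_group_vector_is_ones(self):
        rows = [(f"p{i}", "KR", q, "korean", True) for i in range(3) for q in (1, 2, 3)]
        vectors = gp.question_preference_matrix(make_responses(rows), {"KR": "korean"})
        assert np.allclose(vectors.loc["KR preferring Korean"], 1.0)
        assert np.allclose(vectors.loc["KR selecting Korean (intended)"], 1.0)

    def test_per_question_proportions_partition(self, tiny_responses):
        vectors = gp.question_preference_matrix(tiny_responses, {"UK": "english"})
        total = sum(vectors.loc[f"UK preferring {t.capitalize()}"] for t in gp.MATERIAL_TYPES)
        assert np.allclose(total, 1.0)

    def test_planted_heterogeneity_matches_hand_counts(self):
        # 2 participants, 2 questions: q1 split english/korean, q2 both chinese
        rows = [
            ("a", "UK", 1, "english", True), ("a", "UK", 2, "chinese", True),
            ("b", "UK", 1, "korean", True), ("b", "UK", 2, "chinese", True),
        ]
        vectors = gp.question_preference_matrix(make_responses(rows), {"UK": "english"})
        assert vectors.loc["UK preferring English"].tolist() == [0.5, 0.0]
        assert vectors.loc["UK preferring Chinese"].tolist() == [0.0, 1.0]


class TestCorrelationMatrix:
    def test_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(2)
        vectors = pd.DataFrame(rng.random((5, 10)), index=[f"v{i}" for i in range(5)])
        r, p = gp.preference_correlation_matrix(vectors)
        assert np.allclose(r, r.T)
        assert np.allclose(np.diag(r), 1.0)
        assert ((p.to_numpy() >= 0) & (p.to_numpy() <= 1)).all()

    def test_antiphase_vectors_give_minus_one(self):
        v = np.arange(10.0)
        vectors = pd.DataFrame([v, -v], index=["up", "down"])
        r, _ = gp.preference_correlation_matrix(vectors)
        assert r.loc["up", "down"] == pytest.approx(-1.0)

    def test_constant_vector_flagged_as_nan(self):
        vectors = pd.DataFrame([np.ones(5), np.arange(5.0)], index=["const", "ramp"])
        r, p = gp.preference_correlation_matrix(vectors)
        assert np.isnan(r.loc["const", "ramp"]) and np.isnan(p.loc["const", "ramp"])

    def test_within_group_preference_vectors_cannot_all_positively_correlate(self):
        rs = gp.simulate_responses(
            gp.ResponseGenConfig(n_per_group={"UK": 40}, weights={"UK": (0.5, 0.3, 0.2)}, seed=6)
        )
        vectors = gp.question_preference_matrix(rs, {"UK": "english"})
        prefs = vectors.loc[[f"UK preferring {t.capitalize()}" for t in gp.MATERIAL_TYPES]]
        r, _ = gp.preference_correlation_matrix(prefs)
        off = r.to_numpy()[np.triu_indices(3, 1)]
        assert (off < 0).any()  # compositional constraint forces a negative pair

    def test_stars(self):
        assert gp.significance_stars(0.0001) == "***"
        assert gp.significance_stars(0.005) == "**"
        assert gp.significance_stars(0.03) == "*"
        assert gp.significance_stars(0.2) == ""
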