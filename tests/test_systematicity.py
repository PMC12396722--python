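"""Systematicity scoring, cross-validation, and the exclusivity rule."""

import numpy as np
import pytest

import graphophon as gp
from _oracles import pearson_textbook, spearman_textbook


class TestScore:
    def test_perfect_linear_relation(self):
        x = np.arange(1.0, 11.0)
        s = gp.score_systematicity(x, 2 * x + 1)
        assert s.pearson_r == pytest.approx(1.0)
        assert s.pearson_p < 1e-9

    def test_perfect_negative_relation(self):
        x = np.arange(1.0, 11.0)
        s = gp.score_systematicity(x, -x)
        assert s.pearson_r == pytest.approx(-1.0)
        assert s.spearman_rho == pytest.approx(-1.0)

    def test_spearman_rank_formula_example(self):
        # 1 - 6*Σd²/(n(n²-1)) with Σd² = 2, n = 5
        s = gp.score_systematicity([1, 2, 3, 4, 5], [1, 3, 2, 5, 4])
        assert s.spearman_rho == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gp.score_systematicity([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            gp.score_systematicity([1, 2], [3, 4])

    def test_matches_textbook_oracle_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(100):
            n = int(rng.integers(5, 30))
            x, y = rng.random(n), rng.random(n)
            s = gp.score_systematicity(x, y)
            r_o, p_o = pearson_textbook(x, y)
            rho_o, sp_o = spearman_textbook(x, y)
            assert s.pearson_r == pytest.approx(r_o, abs=1e-12)
            assert s.pearson_p == pytest.approx(p_o, abs=1e-12)
            assert s.spearman_rho == pytest.approx(rho_o, abs=1e-12)
            assert s.spearman_p == pytest.approx(sp_o, abs=1e-12)


class TestMaterialVectors:
    def test_toy_material_pixel_distances_match_hand_arithmetic(self, ref_table):
        g1 = gp.GlyphRaster("g1", np.ones((2, 2)))  # 4 px
        g2 = gp.GlyphRaster("g2", np.ones((3, 3)))  # 9 px
        g3 = gp.GlyphRaster("g3", np.ones((1, 5)))  # 5 px
        g4 = gp.GlyphRaster("g4", np.ones((4, 4)))  # 16 px
        lib = gp.GlyphLibrary("toy", [g1, g2, g3, g4])
        mat = gp.Material(
            "english",
            [("g", "s", "g1", "g2"), ("k", "s", "g3", "g4"), ("p", "b", "g1", "g4")],
            "pixel",
        )
        phon, glyph = gp.pair_distance_vectors(mat, ref_table, lib, "pixel")
        assert glyph.tolist() == [5.0, 11.0, 12.0]
        assert phon.tolist() == [2.24, 2.0, 1.0]

    def test_identical_glyph_pairs_give_zero_vector(self, ref_table):
        g = gp.GlyphRaster("g", np.ones((3, 3)))
        lib = gp.GlyphLibrary("one", [g])
        mat = gp.Material("english", [("g", "s", "g", "g"), ("k", "s", "g", "g")], "pixel")
        _, glyph = gp.pair_distance_vectors(mat, ref_table, lib, "pixel")
        assert np.allclose(glyph, 0)

    def test_missing_glyph_raises_lookup_error(self, ref_table):
        lib = gp.GlyphLibrary("empty-ish", [gp.GlyphRaster("g", np.ones((2, 2)))])
        mat = gp.Material("english", [("g", "s", "g", "nope")], "pixel")
        with pytest.raises(KeyError):
            gp.pair_distance_vectors(mat, ref_table, lib, "pixel")

    def test_pair_order_permutation_leaves_score_unchanged(self, ref_table, planted_pixel):
        lib, mat = planted_pixel
        rng = np.random.default_rng(0)
        perm = list(rng.permutation(len(mat.pairs)))
        shuffled = gp.Material(mat.material_type, [mat.pairs[i] for i in perm], mat.intended_metric)
        s0 = gp.score_material(mat, ref_table, lib)
        s1 = gp.score_material(shuffled, ref_table, lib)
        assert s0 == s1


class TestCrossvalAndExclusivity:
    def test_scoring_is_deterministic(self, ref_table, planted_pixel):
        lib, mat = planted_pixel
        assert gp.score_material(mat, ref_table, lib) == gp.score_material(mat, ref_table, lib)

    def test_planted_material_is_exclusive(self, ref_table, planted_pixel):
        lib, mat = planted_pixel
        cv = gp.crossval_matrix([mat], ref_table, lib)
        assert cv["pixel"]["english"].pearson_p < 0.001
        assert cv["pc"]["english"].pearson_p >= 0.05
        assert cv["hausdorff"]["english"].pearson_p >= 0.05
        report = gp.exclusivity_check(cv)
        assert report["english"]["passed"]

    def test_exclusivity_fails_when_everything_is_significant(self):
        s_sig = gp.SystematicityScore(0.95, 1e-5, 0.9, 1e-4, 10)
        cv = {m: {"english": s_sig} for m in gp.METRICS}
        report = gp.exclusivity_check(cv)
        assert not report["english"]["passed"]
        assert any("off metric" in r for r in report["english"]["reasons"])

    def test_exclusivity_on_published_crossval_pattern(self):
        # the printed 3×3 Pearson cross-validation grid: each material
        # significant only under its intended metric
        p_grid = {
            "pixel": {"english": 1e-5, "chinese": 0.19, "korean": 0.07},
            "pc": {"english": 0.19, "chinese": 1e-5, "korean": 0.15},
            "hausdorff": {"english": 0.32, "chinese": 0.10, "korean": 1e-5},
        }
        r_grid = {
            "pixel": {"english": 0.98, "chinese": 0.45, "korean": 0.62},
            "pc": {"english": 0.48, "chinese": 0.91, "korean": 0.52},
            "hausdorff": {"english": 0.37, "chinese": 0.55, "korean": 0.96},
        }
        cv = {
            m: {
                t: gp.SystematicityScore(r_grid[m][t], p_grid[m][t], 0.5, 0.5, 10)
                for t in gp.MATERIAL_TYPES
            }
            for m in gp.METRICS
        }
        report = gp.exclusivity_check(cv)
        assert all(report[t]["passed"] for t in gp.MATERIAL_TYPES)

    def test_null_type_one_error_rate_is_calibrated(self):
        """i.i.d. glyph distances independent of the phonetic distances
        should reject at about the nominal 5% rate."""
        rng = np.random.default_rng(99)
        phon = gp.reference_distance_table().distances()
        hits = 0
        reps = 2000
        for _ in range(reps):
            y = rng.random(10)
            hits += gp.score_systematicity(phon, y).pearson_p < 0.05
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_duplicate_intended_metrics_rejected(self, ref_table, planted_pixel):
        lib, mat = planted_pixel
        with pytest.raises(ValueError, match="distinct"):
            gp.crossval_matrix([mat, mat], ref_table, lib)

    def test_crossval_frame_has_nine_rows(self, ref_table, planted_pixel):
        lib, mat = planted_pixel
        cv = gp.crossval_matrix([mat], ref_table, lib)
        frame = gp.crossval_to_frame(cv)
        assert len(frame) == 3  # one material × three metrics
        assert set(frame["metric"]) == set(gp.METRICS)


class TestMaterialValidation:
    def test_standard_material_shape_enforced(self, ref_table, planted_pixel):
        _, mat = planted_pixel
        mat.validate_standard()  # 10 pairs, 20 glyphs
        short = gp.Material("english", mat.pairs[:5], "pixel")
        with pytest.raises(ValueError, match="10 pairs"):
            short.validate_standard()

    def test_csv_round_trip(self, tmp_path, planted_pixel):
        _, mat = planted_pixel
        mat.to_csv(tmp_path / "m.csv")
        loaded = gp.Material.from_csv(tmp_path / "m.csv")
        assert loaded.pairs == mat.pairs
        assert loaded.intended_metric == "pixel"
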