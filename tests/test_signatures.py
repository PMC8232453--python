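"""Network signatures, correlation, and the classification harness."""

import numpy as np
import pandas as pd
import pytest

from netclosure import (
    feature_importance,
    loocv_classify,
    pearson,
    random_directed_gnp,
    signature,
    signatures_frame,
    standardize,
)


def synthetic_signature_table(n_per_class=4, sep=5.0, seed=0):
    """Two well-separated classes in the 8 pattern features."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, shift in (("a", 0.0), ("b", sep)):
        for k in range(n_per_class):
            feats = rng.normal(shift, 0.2, size=8)
            rows.append({"name": f"{label}{k}", "class_label": label,
                         **dict(zip(["c_head", "c_mid", "c_end", "c_cyc",
                                     "e_head", "e_mid", "e_end", "e_cyc"], feats))})
    return pd.DataFrame(rows)


class TestSignature:
    def test_ff3_pattern_averages(self, ff3):
        s = signature(ff3, name="ff3", label="motif")
        assert (s.n_nodes, s.n_edges) == (3, 3)
        assert s.avg_degree == 1.0 and s.reciprocity == 0.0
        for v in (s.e_head, s.e_mid, s.e_end):
            assert v == pytest.approx(1 / 3)
        assert s.e_cyc == 0.0
        assert s.c_head == s.c_end == pytest.approx(1 / 6)
        assert s.c_mid == pytest.approx(1 / 3) and s.c_cyc == 0.0
        assert s.avg_c_d == s.avg_e_d == 0.5

    def test_cy3_all_cyclic(self, cy3):
        s = signature(cy3)
        assert s.e_cyc == 1.0 and s.c_cyc == 1.0
        assert s.e_head == s.e_mid == s.e_end == 0.0
        assert s.c_head == s.c_mid == s.c_end == 0.0

    def test_all_averages_in_unit_interval(self):
        g = random_directed_gnp(40, 0.15, seed=3)
        s = signature(g)
        for f in ("avg_c_d", "avg_e_d", "c_head", "c_mid", "c_end", "c_cyc",
                  "e_head", "e_mid", "e_end", "e_cyc"):
            assert 0.0 <= getattr(s, f) <= 1.0

    def test_frame_round_trip(self, ff3, cy3):
        df = signatures_frame([signature(ff3, "ff3", "x"), signature(cy3, "cy3", "y")])
        assert list(df["name"]) == ["ff3", "cy3"] and df.shape[0] == 2


class TestStandardize:
    def test_two_point_column(self):
        out = standardize(np.array([[0.0], [2.0]]))
        assert out.tolist() == [[-1.0], [1.0]]

    def test_already_standardized_unchanged(self):
        x = np.array([[-1.0, 0.5], [1.0, -0.5]])
        x = (x - x.mean(0)) / x.std(0)
        assert np.allclose(standardize(x), x)

    def test_constant_column_zeroed_with_warning(self):
        with pytest.warns(UserWarning, match="constant"):
            out = standardize(np.array([[1.0, 3.0], [2.0, 3.0]]))
        assert np.allclose(out[:, 1], 0.0)

    def test_single_row_errors(self):
        with pytest.raises(ValueError):
            standardize(np.array([[1.0, 2.0]]))


class TestPearson:
    def test_perfect_and_anti_correlation(self):
        x = [1.0, 2.0, 5.0]
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, [-v for v in x]) == pytest.approx(-1.0)

    def test_hand_value(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(0.981980506, abs=1e-6)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson([1, 1, 1], [1, 2, 3])


class TestClassifierHarness:
    @pytest.mark.parametrize("model", ["tree", "forest", "boosted"])
    def test_separable_classes_perfect_accuracy(self, model):
        df = synthetic_signature_table()
        reps = 3 if model != "tree" else 10
        assert loocv_classify(df, "both", model, repeats=reps, seed=0) == 1.0

    def test_feature_subsets_select_columns(self):
        df = synthetic_signature_table()
        for fs in ("clustering", "closure", "both"):
            acc = loocv_classify(df, fs, "tree", repeats=3, seed=1)
            assert acc == 1.0
        with pytest.raises(ValueError, match="unknown feature set"):
            loocv_classify(df, "bogus", "tree", repeats=1)

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(5)
        df = synthetic_signature_table(n_per_class=8, seed=5)
        df["class_label"] = rng.permutation(df["class_label"].to_numpy())
        acc = loocv_classify(df, "both", "tree", repeats=20, seed=5)
        assert acc < 0.85  # far from the separable 1.0

    def test_single_member_class_rejected(self):
        df = synthetic_signature_table(n_per_class=1)
        with pytest.raises(ValueError, match="single member"):
            loocv_classify(df, "both", "tree", repeats=1)

    def test_seeded_runs_identical(self):
        df = synthetic_signature_table()
        a = loocv_classify(df, "both", "forest", repeats=2, seed=9)
        b = loocv_classify(df, "both", "forest", repeats=2, seed=9)
        assert a == b


class TestFeatureImportance:
    def test_single_informative_feature_dominates(self):
        rng = np.random.default_rng(2)
        df = synthetic_signature_table(n_per_class=6, sep=0.0, seed=2)
        df["e_mid"] = np.where(df["class_label"] == "a", 0.0, 1.0)
        imp = feature_importance(df, "both", "tree", repeats=20, seed=2)
        assert imp["e_mid"] > 0.9

    def test_scores_sum_to_one(self):
        df = synthetic_signature_table(seed=7)
        for model in ("tree", "forest", "boosted"):
            imp = feature_importance(df, "both", model, repeats=3, seed=7)
            assert imp.sum() == pytest.approx(1.0, abs=1e-9)
            assert (imp >= 0).all()

    def test_degenerate_identical_features_uniform(self):
        df = synthetic_signature_table(sep=0.0, seed=3)
        for col in ("c_head", "c_mid", "c_end", "c_cyc",
                    "e_head", "e_mid", "e_end", "e_cyc"):
            df[col] = 1.0
        imp = feature_importance(df, "both", "tree", repeats=2, seed=3)
        assert np.allclose(imp, 1 / 8)
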