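"""Gene-level statistics: rank-sum test, BH, fold change, screen, module
score, bimodal split — each checked against an independent oracle or a
hand-computed value."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scresponse import deg
from scresponse.containers import ExpressionMatrix
from scresponse.errors import ValidationError

from oracles import bh_step_up, exact_rank_sum_p


class TestHighVarianceFilter:
    def test_hand_computed_variance(self):
        # gene g2: values [0, 6] -> unbiased variance ((0-3)^2+(6-3)^2)/1 = 18
        X = ExpressionMatrix(
            pd.DataFrame({"g1": [1.0, 1.0], "g2": [0.0, 6.0]}, index=["a", "b"])
        )
        assert deg.select_high_variance_genes(X, threshold=6) == ["g2"]
        assert deg.select_high_variance_genes(X, threshold=np.inf) == []

    def test_single_row_is_an_error(self):
        X = ExpressionMatrix(pd.DataFrame({"g": [1.0]}, index=["a"]))
        with pytest.raises(ValidationError):
            deg.select_high_variance_genes(X)


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all 3 group-A ranks below group-B: most extreme of C(6,3)=20 splits,
        # two-sided p = 2/20 = 0.1
        assert deg.wilcoxon_test([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_groups_convention(self):
        assert deg.wilcoxon_test([1.0, 1.0, 2.0], [1.0, 2.0, 1.0]) == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            deg.wilcoxon_test([], [1.0])

    @given(
        n=st.integers(1, 8),
        m=st.integers(1, 8),
        data=st.data(),
    )
    def test_matches_enumeration_oracle_tie_free(self, n, m, data):
        rng = np.random.default_rng(data.draw(st.integers(0, 10_000)))
        pooled = rng.permutation(np.arange(1, n + m + 1)).astype(float)
        a, b = pooled[:n], pooled[n:]
        assert deg.wilcoxon_test(a, b) == pytest.approx(exact_rank_sum_p(a, b), abs=1e-12)

    def test_normal_approximation_close_to_exact(self):
        # group sizes 11/9 take the asymptotic branch; the enumeration
        # oracle is still tractable (C(20,11) assignments)
        rng = np.random.default_rng(3)
        for _ in range(3):
            pooled = rng.permutation(np.arange(20.0))
            a, b = pooled[:11], pooled[11:]
            approx = deg.wilcoxon_test(a, b)
            assert abs(approx - exact_rank_sum_p(a, b)) < 0.02


class TestBenjaminiHochberg:
    def test_hand_example(self):
        np.testing.assert_allclose(
            deg.benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_degenerate_inputs(self):
        assert deg.benjamini_hochberg([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(deg.benjamini_hochberg([1.0, 1.0]), [1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            deg.benjamini_hochberg([0.5, 1.5])

    @given(st.integers(0, 10_000))
    def test_matches_step_up_oracle(self, seed):
        p = np.random.default_rng(seed).random(25)
        np.testing.assert_allclose(deg.benjamini_hochberg(p), bh_step_up(p), atol=1e-12)

    def test_adjusted_never_below_raw(self):
        p = np.random.default_rng(5).random(100)
        assert (deg.benjamini_hochberg(p) >= p - 1e-12).all()


class TestFoldChange:
    def test_closed_form_on_constants(self):
        # A constant at log2(3+1)=2, B at 0 -> log2((3+1)/(0+1)) = 2
        assert deg.log2_fold_change([2.0, 2.0], [0.0, 0.0]) == pytest.approx(2.0)

    def test_identity_and_antisymmetry(self):
        a = [0.5, 1.5, 2.5]
        b = [0.1, 2.0, 1.1]
        assert deg.log2_fold_change(a, a) == pytest.approx(0.0)
        assert deg.log2_fold_change(a, b) == pytest.approx(-deg.log2_fold_change(b, a))

    def test_logdiff_variant(self):
        assert deg.log2_fold_change([2.0, 4.0], [1.0, 1.0], method="logdiff") == pytest.approx(2.0)


class TestDegScreen:
    def test_recovers_planted_degs(self, small_cohort):
        X, meta, truth = small_cohort["X"], small_cohort["meta"], small_cohort["truth"]
        table = deg.deg_screen(X, meta["response"])
        planted = set(truth.planted_deg_up_responder) | set(truth.planted_deg_up_nonresponder)
        flagged = set(table.loc[table["passes"], "gene"])
        sensitivity = len(flagged & planted) / len(planted)
        fdr = len(flagged - planted) / max(len(flagged), 1)
        assert sensitivity >= 0.9
        assert fdr <= 0.07
        # planted responder genes point in the responder direction
        up_r = table.set_index("gene").loc[truth.planted_deg_up_responder]
        assert (up_r["log2fc"] > 0).mean() > 0.9

    def test_invariant_to_row_and_column_permutation(self, small_cohort):
        X, meta = small_cohort["X"], small_cohort["meta"]
        rng = np.random.default_rng(1)
        rows = rng.permutation(X.shape[0])
        cols = rng.permutation(X.shape[1])
        Xp = ExpressionMatrix(X.data.iloc[rows, cols])
        base = deg.deg_screen(X, meta["response"]).set_index("gene").sort_index()
        perm = (
            deg.deg_screen(Xp, meta["response"].iloc[rows].reset_index(drop=True))
            .set_index("gene")
            .sort_index()
        )
        pd.testing.assert_frame_equal(base, perm)

    def test_marker_mode_prevalence_prefilter(self):
        rng = np.random.default_rng(0)
        n = 100
        # gene expressed in ~5% of cells in both groups -> never tested
        sparse = np.where(rng.random(2 * n) < 0.05, 5.0, 0.0)
        dense = rng.gamma(2, 1, size=2 * n)
        X = ExpressionMatrix(
            pd.DataFrame({"sparse": sparse, "dense": dense}, index=[f"c{i}" for i in range(2 * n)])
        )
        labels = pd.Series(["responder"] * n + ["non-responder"] * n)
        table = deg.deg_screen(X, labels, mode="marker")
        assert "sparse" not in set(table["gene"])

    def test_all_zero_matrix_warns_and_returns_empty(self):
        X = ExpressionMatrix(
            pd.DataFrame(np.zeros((6, 4)), index=[f"c{i}" for i in range(6)], columns=list("abcd"))
        )
        labels = pd.Series(["responder"] * 3 + ["non-responder"] * 3)
        with pytest.warns(UserWarning):
            table = deg.deg_screen(X, labels)
        assert table.empty

    def test_single_group_rejected(self):
        X = ExpressionMatrix(
            pd.DataFrame(np.ones((6, 2)), index=[f"c{i}" for i in range(6)], columns=["a", "b"])
        )
        with pytest.raises(ValidationError):
            deg.deg_screen(X, pd.Series(["responder"] * 6))


class TestModuleScore:
    def test_constant_matrix_scores_zero(self):
        X = ExpressionMatrix(
            pd.DataFrame(np.full((10, 30), 2.0), index=[f"c{i}" for i in range(10)],
                         columns=[f"g{i}" for i in range(30)])
        )
        score = deg.module_score(X, ["g0", "g1"], seed=0)
        np.testing.assert_allclose(score.to_numpy(), 0.0, atol=1e-12)

    def test_recovers_additive_shift(self):
        # set genes shifted by +delta over a matched-mean background; the
        # control pool is drawn from the set genes' expression bin, which
        # (faithfully to the reference algorithm) may include other set
        # genes, so recovery is delta up to a small shrinkage
        rng = np.random.default_rng(7)
        n_cells, n_genes, delta = 200, 1000, 1.5
        base = rng.normal(5.0, 1.0, size=(n_cells, n_genes))
        base[:, :5] += delta
        X = ExpressionMatrix(
            pd.DataFrame(np.maximum(base, 0), index=[f"c{i}" for i in range(n_cells)],
                         columns=[f"g{i}" for i in range(n_genes)])
        )
        score = deg.module_score(X, [f"g{i}" for i in range(5)], n_bins=4, seed=1)
        assert score.mean() == pytest.approx(delta, abs=0.25)

    def test_missing_gene_listed(self, small_cohort):
        with pytest.raises(ValidationError, match="GHOST"):
            deg.module_score(small_cohort["X"], ["GHOST"])


class TestBimodalSplit:
    def test_recovers_two_well_separated_modes(self):
        rng = np.random.default_rng(0)
        comp = rng.random(600) < 0.5
        values = np.where(comp, rng.normal(4, 0.5, 600), rng.normal(0, 0.5, 600))
        res = deg.bimodal_split(values, seed=0)
        assert 1.0 < res.threshold < 3.0
        recovered = (res.labels == "high").to_numpy() == comp
        assert recovered.mean() >= 0.99
        assert not res.low_confidence

    def test_sign_symmetry(self):
        rng = np.random.default_rng(1)
        values = np.concatenate([rng.normal(0, 0.4, 100), rng.normal(3, 0.4, 100)])
        res = deg.bimodal_split(values, seed=0)
        neg = deg.bimodal_split(-values, seed=0)
        # negation swaps high and low labels
        assert ((res.labels == "high") == (neg.labels == "low")).all()
        assert neg.threshold == pytest.approx(-res.threshold, abs=0.1)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            deg.bimodal_split(np.ones(50))

    def test_too_few_values_rejected(self):
        with pytest.raises(ValidationError):
            deg.bimodal_split(np.arange(10.0))
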