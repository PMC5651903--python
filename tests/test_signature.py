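"""Differential expression, signature derivation, scoring, and stratification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from perksig.io import ExpressionStudy
from perksig.signature import (
    DifferentialTable,
    GeneSignature,
    ScoreTable,
    bin_by_score,
    derive_signature,
    differential_expression,
    nested_bins,
    read_scores,
    read_strata,
    score_samples,
    write_scores,
    write_strata,
)


def study_from_groups(tumor_cols: dict, normal_cols: dict, genes):
    values = pd.DataFrame({**tumor_cols, **normal_cols}, index=genes)
    groups = pd.Series(
        ["tumor"] * len(tumor_cols) + ["normal"] * len(normal_cols),
        index=list(tumor_cols) + list(normal_cols),
    )
    return ExpressionStudy(values=values, sample_group=groups)


class TestDifferentialExpression:
    def test_hand_computed_pooled_t(self):
        """Tumor {3,7,15} vs normal {1,3} at c=1: log2 values {2,3,4} vs {1,2},
        so log2fc = 1.5 and the pooled-variance t is 1.8 on 3 df."""
        study = study_from_groups(
            {"t1": [3.0], "t2": [7.0], "t3": [15.0]},
            {"n1": [1.0], "n2": [3.0]},
            ["g"],
        )
        diff = differential_expression(study)
        row = diff.table.loc["g"]
        assert row["log2fc"] == pytest.approx(1.5)
        assert row["t"] == pytest.approx(1.8)
        assert row["p"] == pytest.approx(0.169680, abs=1e-5)

    def test_identical_groups_give_null_result(self):
        study = study_from_groups(
            {"t1": [2.0], "t2": [5.0]}, {"n1": [2.0], "n2": [5.0]}, ["g"]
        )
        diff = differential_expression(study)
        assert diff.table.loc["g", "log2fc"] == 0.0
        assert diff.table.loc["g", "p"] == pytest.approx(1.0)

    def test_constant_gene_flagged_with_p_one(self):
        study = study_from_groups(
            {"t1": [4.0], "t2": [4.0]}, {"n1": [4.0], "n2": [4.0]}, ["g"]
        )
        diff = differential_expression(study)
        assert diff.table.loc["g", "constant"]
        assert diff.table.loc["g", "t"] == 0.0 and diff.table.loc["g", "p"] == 1.0

    def test_small_group_errors(self):
        study = study_from_groups({"t1": [1.0], "t2": [2.0]}, {"n1": [1.0]}, ["g"])
        with pytest.raises(ValueError, match=">=2 samples"):
            differential_expression(study)


class TestDeriveSignature:
    def test_bonferroni_cut_applied(self):
        diff = DifferentialTable(
            pd.DataFrame(
                {"log2fc": [1.5, 2.0, 0.5], "p": [1e-10, 0.04, 1e-10]},
                index=["gene1", "gene2", "gene3"],
            )
        )
        sig = derive_signature(diff, fc_threshold_log2=1.0, alpha=0.05, n_tests=3)
        assert sig.genes == ["gene1"]  # cutoff p <= 0.0167 excludes gene2

    def test_infinite_threshold_gives_empty_signature(self):
        diff = DifferentialTable(
            pd.DataFrame({"log2fc": [5.0], "p": [1e-20]}, index=["g"])
        )
        assert len(derive_signature(diff, fc_threshold_log2=np.inf)) == 0

    def test_provenance_recorded(self):
        diff = DifferentialTable(
            pd.DataFrame({"log2fc": [2.0], "p": [1e-9]}, index=["g"]), pseudocount=2.0
        )
        sig = derive_signature(diff)
        assert sig.provenance == {
            "fc_threshold_log2": 1.0,
            "alpha": 0.05,
            "n_tests": 1,
            "pseudocount": 2.0,
        }

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        fcs=st.lists(st.floats(-3, 4), min_size=1, max_size=20),
        ps=st.data(),
        thr=st.floats(0.5, 3),
        alpha=st.floats(0.001, 0.1),
    )
    def test_monotone_in_thresholds(self, fcs, ps, thr, alpha):
        """Raising either threshold never adds signature members."""
        pvals = ps.draw(
            st.lists(st.floats(1e-12, 1), min_size=len(fcs), max_size=len(fcs))
        )
        diff = DifferentialTable(
            pd.DataFrame(
                {"log2fc": fcs, "p": pvals},
                index=[f"g{i}" for i in range(len(fcs))],
            )
        )
        base = set(derive_signature(diff, thr, alpha).genes)
        stricter_fc = set(derive_signature(diff, thr + 0.5, alpha).genes)
        stricter_alpha = set(derive_signature(diff, thr, alpha / 10).genes)
        assert stricter_fc <= base and stricter_alpha <= base


class TestScoreSamples:
    def test_single_gene_identity(self):
        study = ExpressionStudy(
            values=pd.DataFrame({"s1": [15.0]}, index=["g"]),
        )
        scores = score_samples(study, GeneSignature(genes=["g"]))
        assert scores.scores["s1"] == pytest.approx(4.0)  # log2(16)

    def test_two_gene_mean(self):
        study = ExpressionStudy(
            values=pd.DataFrame({"s1": [1.0, 3.0]}, index=["g1", "g2"]),
        )
        scores = score_samples(study, GeneSignature(genes=["g1", "g2"]))
        assert scores.scores["s1"] == pytest.approx(1.5)  # mean(log2 2, log2 4)

    def test_invariant_under_gene_reordering(self, tiny_study):
        a = score_samples(tiny_study, GeneSignature(genes=["gA", "gC"]))
        b = score_samples(tiny_study, GeneSignature(genes=["gC", "gA"]))
        pd.testing.assert_series_equal(a.scores, b.scores)

    def test_strict_missing_gene_errors(self, tiny_study):
        with pytest.raises(ValueError, match="missing"):
            score_samples(tiny_study, GeneSignature(genes=["gA", "gZ"]))

    def test_empty_signature_errors(self, tiny_study):
        with pytest.raises(ValueError, match="empty"):
            score_samples(tiny_study, GeneSignature(genes=[]))


def scores_of(n, seed=0):
    rng = np.random.default_rng(seed)
    ids = [f"s{i:04d}" for i in range(n)]
    return ScoreTable(pd.Series(rng.normal(size=n), index=ids))


class TestBinByScore:
    def test_half_scheme_1093_gives_546_high(self):
        strata = bin_by_score(scores_of(1093), scheme="half")
        assert strata.counts()["high"] == 546

    def test_tertile_547_gives_182_arms(self):
        strata = bin_by_score(scores_of(547), scheme="tertile")
        counts = strata.counts()
        assert counts["high"] == 182 and counts["low"] == 182 and counts["mid"] == 183

    def test_three_samples_one_per_tertile(self):
        strata = bin_by_score(scores_of(3), scheme="tertile")
        assert sorted(strata.counts().values()) == [1, 1, 1]

    def test_p33_leaves_middle_unassigned(self):
        strata = bin_by_score(scores_of(10), scheme="p33")
        assert strata.counts() == {"high": 3, "low": 3}

    def test_tertile_is_a_partition(self):
        scores = scores_of(100, seed=3)
        strata = bin_by_score(scores, scheme="tertile")
        assert set(strata.labels.index) == set(scores.scores.index)
        assert not (set(strata.samples_in("high")) & set(strata.samples_in("low")))

    def test_ties_broken_by_ascending_sample_id(self):
        scores = ScoreTable(pd.Series([1.0, 1.0, 0.0], index=["b", "a", "c"]))
        strata = bin_by_score(scores, scheme="tertile")
        assert strata.samples_in("high") == ["a"]

    def test_nan_score_rejected(self):
        with pytest.raises(ValueError):
            ScoreTable(pd.Series([np.nan, 1.0], index=["a", "b"]))


class TestNestedBins:
    def test_nine_samples_one_per_cell(self):
        outer = scores_of(9, seed=1)
        inner = ScoreTable(pd.Series(
            np.random.default_rng(2).normal(size=9), index=outer.scores.index
        ))
        strata = nested_bins(outer, inner)
        assert sorted(strata.counts().values()) == [1, 1, 1, 1]
        assert set(strata.counts()) == {"high_high", "high_low", "low_high", "low_low"}

    def test_inner_binning_is_local_to_outer_bin(self):
        """Changing scores of samples outside an outer bin never changes the
        inner assignment within that bin."""
        outer = scores_of(30, seed=5)
        inner = ScoreTable(pd.Series(
            np.random.default_rng(6).normal(size=30), index=outer.scores.index
        ))
        strata = nested_bins(outer, inner)
        outer_bins = bin_by_score(outer, scheme="p33")
        shuffled = inner.scores.copy()
        low_members = outer_bins.samples_in("low")
        shuffled.loc[low_members] = shuffled.loc[low_members].sample(
            frac=1, random_state=0
        ).to_numpy()
        strata2 = nested_bins(outer, ScoreTable(shuffled))
        high_members = outer_bins.samples_in("high")
        mask = strata.labels.index.isin(high_members)
        pd.testing.assert_series_equal(
            strata.labels[mask].sort_index(), strata2.labels[strata2.labels.index.isin(high_members)].sort_index()
        )

    def test_mismatched_sample_sets_error(self):
        with pytest.raises(ValueError, match="same samples"):
            nested_bins(scores_of(9), scores_of(8))


def test_score_and_strata_tsv_round_trip(tmp_path):
    scores = scores_of(12, seed=8)
    write_scores(scores, tmp_path / "scores.tsv")
    back = read_scores(tmp_path / "scores.tsv")
    np.testing.assert_allclose(back.scores.to_numpy(), scores.scores.to_numpy())
    strata = bin_by_score(scores, scheme="tertile")
    write_strata(strata, tmp_path / "strata.tsv")
    back_s = read_strata(tmp_path / "strata.tsv")
    assert back_s.scheme == "tertile"
    pd.testing.assert_series_equal(back_s.labels.sort_index(), strata.labels.sort_index())


def test_null_bonferroni_false_positive_control():
    """With no planted genes the expected count of Bonferroni-significant,
    twofold-up genes per dataset is far below alpha; over 50 small null
    datasets the total should stay near zero."""
    total = 0
    from perksig.simulate import ExpressionScenario, gen_expression_study

    for seed in range(50):
        cfg = ExpressionScenario(
            n_genes=100, n_tumors=40, n_normals=40, n_planted=0, shift_log2=0.0,
            seed=seed,
        )
        study, _ = gen_expression_study(cfg)
        diff = differential_expression(study)
        total += len(derive_signature(diff))
    assert total <= 5  # expected total is 50 * alpha_bound = 2.5 at most
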