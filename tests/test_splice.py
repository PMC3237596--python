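"""Splicing index, the a-e filter cascade, and event mapping."""

import numpy as np
import pandas as pd
import pytest

from exonflow.annotation import EventAnnotation
from exonflow.simulate import simulate_experiment
from exonflow.splice import (
    FOLD_CAP_LOG2,
    RATIO_BOUND_LOG2,
    call_differential_splicing,
    event_class_summary,
    filter_a_expressed,
    filter_b_reliability,
    filter_c_foldcap,
    filter_d_ttest,
    filter_e_exon_detect,
    map_events,
    splicing_index,
)
from exonflow.summarize import quantile_normalize_matrix, summarize_chip

from conftest import small_config


class TestSplicingIndex:
    def test_equal_estimates_give_zero(self):
        s = pd.Series([5.0, 6.0], index=["a", "b"])
        assert (splicing_index(s, s) == 0).all()

    def test_arithmetic(self):
        ps = pd.Series([6.0], index=["a"])
        gene = pd.Series([8.0], index=["a"])
        assert splicing_index(ps, gene).iloc[0] == -2.0

    def test_invariant_to_gene_level_shift(self):
        ps = pd.Series([6.0, 7.0], index=["a", "b"])
        gene = pd.Series([8.0, 8.5], index=["a", "b"])
        si = splicing_index(ps, gene)
        si_shifted = splicing_index(ps + 3.0, gene + 3.0)
        pd.testing.assert_series_equal(si, si_shifted)

    def test_sample_mismatch_rejected(self):
        with pytest.raises(ValueError, match="sample"):
            splicing_index(
                pd.Series([1.0], index=["a"]), pd.Series([1.0], index=["b"])
            )


class TestFilters:
    def test_a_all_replicates_detected(self):
        assert filter_a_expressed([0.001] * 4, [0.001] * 4)[2]

    def test_a_two_replicates_fail(self):
        n_ctrl, _n_trt, ok = filter_a_expressed(
            [0.001, 0.001, 0.5, 0.5], [0.001] * 4
        )
        assert n_ctrl == 2 and not ok

    def test_a_exactly_three_boundary_passes(self):
        assert filter_a_expressed([0.01, 0.01, 0.01, 0.5], [0.01, 0.01, 0.01, 0.9])[2]

    def test_b_identical_vectors(self):
        block = np.array([[1.0], [2.0], [3.0], [4.0]])
        r, rho, ok = filter_b_reliability(block, block)
        assert r == pytest.approx(1.0) and rho == pytest.approx(1.0) and ok

    def test_b_anticorrelated_fails(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0]])
        b = a[::-1]
        r, rho, ok = filter_b_reliability(a, b)
        assert rho == pytest.approx(-1.0) and not ok

    def test_b_outlier_keeps_rank_correlation(self):
        a = np.array([[1.0], [2.0], [3.0], [4.0]])
        b = np.array([[1.0], [2.0], [3.0], [100.0]])
        r, rho, ok = filter_b_reliability(a, b)
        # brute-force Pearson on the 4-point set
        av, bv = a.ravel(), b.ravel()
        expected_r = np.sum((av - av.mean()) * (bv - bv.mean())) / np.sqrt(
            np.sum((av - av.mean()) ** 2) * np.sum((bv - bv.mean()) ** 2)
        )
        assert rho == pytest.approx(1.0)
        assert r == pytest.approx(expected_r)
        assert ok

    def test_b_zero_variance_fails_with_warning(self):
        flat = np.full((4, 2), 3.0)
        varied = np.array([[1.0, 1.0], [2.0, 2.0], [3.0, 3.0], [4.0, 4.0]])
        with pytest.warns(RuntimeWarning):
            r, rho, ok = filter_b_reliability(flat, varied)
        assert not ok and np.isnan(r)

    def test_c_boundaries(self):
        assert filter_c_foldcap([8.0] * 4, [8.0] * 4) == (0.0, True)
        assert not filter_c_foldcap([8.0] * 4, [12.0] * 4)[1]
        fc, ok = filter_c_foldcap([0.0] * 4, [np.log2(10.0)] * 4)
        assert fc == pytest.approx(FOLD_CAP_LOG2) and ok  # exactly 10-fold passes

    def test_d_identical_index_vectors_fail(self):
        p, ok = filter_d_ttest([0.5] * 4, [0.5] * 4)
        assert p == 1.0 and not ok

    def test_d_strong_shift_passes(self):
        p, ok = filter_d_ttest([0.0, 0.0, 0.0, 0.0], [1.5, 1.4, 1.6, 1.5])
        assert p < 1e-6 and ok

    def test_d_boundary_inclusive(self):
        assert filter_d_ttest([0.0] * 3, [1.0] * 3, p_threshold=1.0)[1]

    def test_e_detected_with_zero_ratio(self):
        cond, ratio, ok = filter_e_exon_detect(
            [0.5] * 4, [0.001] * 4, [0.0] * 4, [0.0] * 4
        )
        assert ok and cond == "treated" and ratio == 0.0

    def test_e_out_of_range_in_detected_condition_fails(self):
        _cond, _ratio, ok = filter_e_exon_detect(
            [0.5] * 4, [0.001] * 4, [0.0] * 4, [3.0] * 4
        )
        assert not ok

    def test_e_either_condition_suffices(self):
        cond, ratio, ok = filter_e_exon_detect(
            [0.001] * 4, [0.001] * 4, [0.5] * 4, [3.0] * 4
        )
        assert ok and cond == "control" and ratio == pytest.approx(0.5)


@pytest.fixture(scope="module")
def splice_run():
    cfg = small_config(
        n_genes=200,
        probesets_per_gene=(8, 12),
        fraction_spliced_probesets=0.06,
        seed=31,
    )
    exp = simulate_experiment(cfg)
    normalized = quantile_normalize_matrix(exp.matrix)
    est = summarize_chip(normalized, exp.annotation)
    calls = call_differential_splicing(est, normalized, exp.annotation)
    return exp, map_events(calls, exp.events)


class TestCascade:
    def test_overall_call_is_pure_conjunction(self, splice_run):
        _exp, calls = splice_run
        conj = (
            calls["a_pass"] & calls["b_pass"] & calls["c_pass"]
            & calls["d_pass"] & calls["e_pass"]
        )
        assert (calls["called"] == conj).all()

    def test_recorded_quantities_reproduce_flags(self, splice_run):
        _exp, calls = splice_run
        assert (
            calls["a_pass"]
            == ((calls["a_ctrl_reps"] >= 3) & (calls["a_trt_reps"] >= 3))
        ).all()
        b_expected = (calls["b_pearson"] >= 0.7) & (calls["b_spearman"] >= 0.7)
        assert (calls["b_pass"] == b_expected.fillna(False)).all()
        assert (calls["c_pass"] == (calls["c_abs_log2fc"] <= FOLD_CAP_LOG2)).all()
        assert (calls["d_pass"] == (calls["d_p"] <= 0.001)).all()
        e_recorded = calls["e_pass"]
        has_cond = calls["e_condition"] != ""
        assert (e_recorded == has_cond).all()
        assert (
            calls.loc[e_recorded, "e_log2_ratio"].abs() <= RATIO_BOUND_LOG2 + 1e-12
        ).all()

    def test_correlations_in_unit_range(self, splice_run):
        _exp, calls = splice_run
        finite = calls.dropna(subset=["b_pearson", "b_spearman"])
        assert finite["b_pearson"].between(-1, 1).all()
        assert finite["b_spearman"].between(-1, 1).all()

    def test_unexpressed_genes_never_called(self, splice_run):
        exp, calls = splice_run
        truth = exp.truth.genes.set_index("meta_probeset_id")
        unexpr = calls["meta_probeset_id"].map(~truth["expressed"])
        assert not calls.loc[unexpr.fillna(False).astype(bool), "called"].any()

    def test_planted_effects_recovered(self, splice_run):
        exp, calls = splice_run
        ps_truth = exp.truth.probesets.set_index("probeset_id")
        merged = calls.set_index("probeset_id").join(ps_truth[["planted"]])
        planted = merged["planted"].fillna(False).astype(bool)
        assert merged.loc[planted, "called"].mean() > 0.6
        # false-call rate among unplanted probesets stays low
        assert merged.loc[~planted, "called"].mean() < 0.01

    def test_splicing_index_invariant_to_gene_scaling(self, splice_run):
        # multiplying all probes of one gene by a per-sample constant moves
        # probeset and gene estimates together, leaving the index unchanged
        exp, calls = splice_run
        gene = calls["meta_probeset_id"].iloc[0]
        annot = exp.annotation
        est0 = summarize_chip(exp.matrix, annot)
        probes = annot.foreground.loc[
            annot.foreground["meta_probeset_id"] == gene, "probe_id"
        ]
        scaled = exp.matrix.intensities.copy()
        factors = 2.0 ** np.arange(scaled.shape[1])
        scaled.loc[probes] = scaled.loc[probes] * factors
        est1 = summarize_chip(
            exp.matrix.__class__(scaled, exp.matrix.samples), annot
        )
        ps_ids = annot.probesets.loc[
            annot.probesets["meta_probeset_id"] == gene, "probeset_id"
        ]
        for ps in ps_ids:
            si0 = est0.probeset_log2.loc[ps] - est0.gene_log2.loc[gene]
            si1 = est1.probeset_log2.loc[ps] - est1.gene_log2.loc[gene]
            # median polish absorbs per-sample shifts into the sample
            # effects only up to its iteration tolerance
            assert np.allclose(si0, si1, atol=0.01)


class TestMapEvents:
    @staticmethod
    def make_calls(n, called=True):
        return pd.DataFrame(
            {
                "probeset_id": [f"ps{i}" for i in range(n)],
                "called": [called] * n,
                "event_class": [""] * n,
            }
        )

    def test_annotated_probeset_gets_class(self):
        calls = self.make_calls(2)
        events = EventAnnotation(
            events=pd.DataFrame(
                {"probeset_id": ["ps0"], "event_class": ["cassette_exon"]}
            )
        )
        out = map_events(calls, events)
        assert out.loc[0, "event_class"] == "cassette_exon"
        assert out.loc[1, "event_class"] == ""

    def test_conflicting_classes_joined_with_warning(self):
        calls = self.make_calls(1)
        events = EventAnnotation(
            events=pd.DataFrame(
                {
                    "probeset_id": ["ps0", "ps0"],
                    "event_class": ["cassette_exon", "alt_5ss"],
                }
            )
        )
        with pytest.warns(RuntimeWarning):
            out = map_events(calls, events)
        assert set(out.loc[0, "event_class"].split("|")) == {"cassette_exon", "alt_5ss"}

    def test_uncalled_probesets_not_annotated(self):
        calls = self.make_calls(1, called=False)
        events = EventAnnotation(
            events=pd.DataFrame(
                {"probeset_id": ["ps0"], "event_class": ["cassette_exon"]}
            )
        )
        out = map_events(calls, events)
        assert out.loc[0, "event_class"] == ""

    def test_summary_fractions(self):
        calls = self.make_calls(10)
        events = EventAnnotation(
            events=pd.DataFrame(
                {
                    "probeset_id": ["ps0", "ps1", "ps2"],
                    "event_class": ["cassette_exon", "cassette_exon", "alt_first_exon"],
                }
            )
        )
        summary = event_class_summary(map_events(calls, events))
        by_class = summary.set_index("event_class")
        assert by_class.loc["cassette_exon", "n"] == 2
        assert by_class.loc["cassette_exon", "pct_of_called"] == pytest.approx(20.0)
        assert by_class.loc["mapped", "n"] == 3
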