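"""Normalization, DABG and median-polish summarization."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from exonflow.annotation import ChipAnnotation
from exonflow.simulate import simulate_experiment
from exonflow.summarize import (
    GcBackground,
    ProbeMatrix,
    SummarizationError,
    dabg_probe_p,
    dabg_probeset_p,
    median_polish,
    median_polish_summarize,
    quantile_normalize,
    read_estimates,
    summarize_chip,
    write_estimates,
)

from conftest import small_config


class TestQuantileNormalize:
    def test_identical_columns_unchanged(self):
        df = pd.DataFrame({"a": [1.0, 5.0, 2.0], "b": [1.0, 5.0, 2.0]})
        out = quantile_normalize(df)
        pd.testing.assert_frame_equal(out, df)

    def test_two_column_hand_example(self):
        df = pd.DataFrame({"a": [1.0, 2.0], "b": [3.0, 4.0]})
        out = quantile_normalize(df)
        assert list(out["a"]) == [2.0, 3.0]
        assert list(out["b"]) == [2.0, 3.0]

    def test_column_means_equalized(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(50, 4)))
        out = quantile_normalize(df)
        means = out.mean(axis=0).to_numpy()
        assert np.allclose(means, means[0])

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(40, 3)))
        once = quantile_normalize(df)
        twice = quantile_normalize(once)
        assert np.max(np.abs(once.to_numpy() - twice.to_numpy())) < 1e-12

    def test_rank_preserved_within_column(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.lognormal(3, 1, size=(30, 3)))
        out = quantile_normalize(df)
        for col in df:
            assert list(np.argsort(df[col])) == list(np.argsort(out[col]))

    def test_nonpositive_rejected(self):
        df = pd.DataFrame({"a": [1.0, -2.0], "b": [3.0, 4.0]})
        with pytest.raises(SummarizationError):
            quantile_normalize(df)


class TestDabg:
    def test_above_all_background(self):
        bg = GcBackground(np.arange(1.0, 101.0), np.full(100, 12))
        assert dabg_probe_p(1000.0, 12, bg) == pytest.approx(1 / 101)

    def test_below_all_background(self):
        bg = GcBackground(np.arange(1.0, 101.0), np.full(100, 12))
        assert dabg_probe_p(0.5, 12, bg) == 1.0

    def test_at_bin_median(self):
        # 101 members, x at the median: 51 members >= x, p = 52/102
        bg = GcBackground(np.arange(1.0, 102.0), np.full(101, 12))
        assert dabg_probe_p(51.0, 12, bg) == pytest.approx(52 / 102)

    def test_empty_bin_pools_to_nearest(self):
        bg = GcBackground(np.array([1.0, 2.0, 3.0]), np.array([10, 10, 10]))
        assert dabg_probe_p(10.0, 25, bg) == pytest.approx(1 / 4)

    def test_empty_registry_rejected(self):
        with pytest.raises(SummarizationError):
            GcBackground(np.array([]), np.array([]))

    def test_probeset_single_probe_identity(self):
        assert dabg_probeset_p([0.05]) == pytest.approx(0.05, rel=1e-9)

    def test_probeset_all_ones(self):
        assert dabg_probeset_p([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_probeset_fisher_combination(self):
        # X = -2(ln 0.01 + ln 0.04) = 15.648, chi-square df 4 upper tail
        x = -2 * (np.log(0.01) + np.log(0.04))
        expected = stats.chi2.sf(x, 4)
        assert dabg_probeset_p([0.01, 0.04]) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.0035, abs=2e-4)

    def test_empty_probeset_rejected(self):
        with pytest.raises(SummarizationError):
            dabg_probeset_p([])

    def test_null_probe_pvalues_approximately_uniform(self):
        # probes drawn from the background model should give ~uniform DABG p
        pvals = []
        for seed in (1, 2, 3):
            cfg = small_config(fraction_unexpressed=0.5, n_background_probes=1500, seed=seed)
            exp = simulate_experiment(cfg)
            truth = exp.truth.genes.set_index("meta_probeset_id")
            fg = exp.annotation.foreground
            unexpr = fg.loc[~truth.loc[fg["meta_probeset_id"], "expressed"].to_numpy()]
            bg = exp.annotation.background
            col = exp.matrix.intensities["trt_2"]
            registry = GcBackground(
                col.loc[bg["probe_id"]].to_numpy(), bg["probe_gc"].to_numpy()
            )
            p = registry.p_values(
                col.loc[unexpr["probe_id"]].to_numpy(), unexpr["probe_gc"].to_numpy()
            )
            pvals.append(stats.kstest(p, "uniform").pvalue)
        assert np.mean(pvals) > 0.01


def bruteforce_median_polish(x, max_iter=10, tol=1e-6):
    """Plain-loop Tukey median polish, written independently of the package."""
    z = [[float(v) for v in row] for row in x]
    nr, nc = len(z), len(z[0])
    t, row, col = 0.0, [0.0] * nr, [0.0] * nc

    def med(vals):
        s = sorted(vals)
        m = len(s) // 2
        return s[m] if len(s) % 2 else 0.5 * (s[m - 1] + s[m])

    for _ in range(max_iter):
        old = [r[:] for r in z]
        for i in range(nr):
            d = med(z[i])
            row[i] += d
            for j in range(nc):
                z[i][j] -= d
        d = med(col)
        t += d
        for j in range(nc):
            col[j] -= d
        for j in range(nc):
            d = med([z[i][j] for i in range(nr)])
            col[j] += d
            for i in range(nr):
                z[i][j] -= d
        d = med(row)
        t += d
        for i in range(nr):
            row[i] -= d
        if max(abs(z[i][j] - old[i][j]) for i in range(nr) for j in range(nc)) < tol:
            break
    return [t + c for c in col]


class TestMedianPolish:
    def test_single_probe_passthrough(self):
        x = np.array([[3.0, 5.0, 4.0]])
        assert np.allclose(median_polish_summarize(x), [3.0, 5.0, 4.0])

    def test_exactly_additive_two_by_two(self):
        est = median_polish_summarize(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(est, [2.0, 3.0])
        *_, resid = median_polish(np.array([[1.0, 2.0], [3.0, 4.0]]))
        assert np.allclose(resid, 0.0)

    def test_probe_order_irrelevant(self):
        rng = np.random.default_rng(3)
        x = rng.normal(8, 1, size=(5, 4))
        est = median_polish_summarize(x)
        est_perm = median_polish_summarize(x[::-1])
        assert np.allclose(est, est_perm)

    def test_matches_independent_bruteforce(self):
        rng = np.random.default_rng(4)
        for _ in range(30):
            nr, nc = rng.integers(1, 7, size=2)
            x = rng.normal(0, 2, size=(nr, nc))
            assert np.allclose(
                median_polish_summarize(x), bruteforce_median_polish(x), atol=1e-9
            )


class TestSummarizeChip:
    def test_gene_below_core_probe_minimum_excluded(self):
        # 10 core probes only: below the >=11 threshold, gene flagged out
        rows = []
        for ps in range(2):
            for p in range(5):
                rows.append((f"g1_ps{ps}_p{p}", f"g1_ps{ps}", "g1", "core", 12, False))
        for i in range(30):
            rows.append((f"bg{i}", "", "", "", 12, True))
        annot = ChipAnnotation(
            probes=pd.DataFrame(
                rows,
                columns=[
                    "probe_id", "probeset_id", "meta_probeset_id",
                    "probeset_class", "probe_gc", "is_background",
                ],
            )
        )
        rng = np.random.default_rng(0)
        samples = pd.DataFrame(
            {
                "sample_id": ["ctrl_1", "ctrl_2", "trt_1", "trt_2"],
                "condition": ["control", "control", "treated", "treated"],
            }
        )
        pm = ProbeMatrix(
            intensities=pd.DataFrame(
                rng.lognormal(5, 1, size=(len(rows), 4)),
                index=[r[0] for r in rows],
                columns=samples["sample_id"],
            ),
            samples=samples,
        )
        est = summarize_chip(pm, annot)
        assert list(est.excluded["meta_probeset_id"]) == ["g1"]
        assert est.excluded["n_core_probes"].iloc[0] == 10
        assert "g1" not in est.gene_log2.index

    def test_constant_gene_estimates_log2_value(self):
        rows = []
        for ps in range(3):
            for p in range(4):
                rows.append((f"g1_ps{ps}_p{p}", f"g1_ps{ps}", "g1", "core", 12, False))
        for i in range(20):
            rows.append((f"bg{i}", "", "", "", 12, True))
        annot = ChipAnnotation(
            probes=pd.DataFrame(
                rows,
                columns=[
                    "probe_id", "probeset_id", "meta_probeset_id",
                    "probeset_class", "probe_gc", "is_background",
                ],
            )
        )
        samples = pd.DataFrame(
            {
                "sample_id": ["ctrl_1", "ctrl_2", "trt_1", "trt_2"],
                "condition": ["control", "control", "treated", "treated"],
            }
        )
        vals = np.full((len(rows), 4), 4.0)
        vals[12:] = np.random.default_rng(1).lognormal(1, 0.3, size=(20, 4))
        pm = ProbeMatrix(
            intensities=pd.DataFrame(
                vals, index=[r[0] for r in rows], columns=samples["sample_id"]
            ),
            samples=samples,
        )
        est = summarize_chip(pm, annot, min_core_probes=11)
        assert np.allclose(est.gene_log2.loc["g1"], 2.0)

    def test_noise_free_simulation_recovers_planted_means(self):
        cfg = small_config(
            n_genes=6,
            fraction_unexpressed=0.0,
            fraction_de_genes=1.0,
            fraction_spliced_probesets=0.0,
            log2fc_de=1.0,
            noise_sd=1e-9,
            seed=9,
        )
        exp = simulate_experiment(cfg)
        est = summarize_chip(exp.matrix, exp.annotation)
        truth = exp.truth.genes.set_index("meta_probeset_id")
        ctrl = est.condition_samples("control")
        trt = est.condition_samples("treated")
        for gene in est.gene_log2.index:
            fc = est.gene_log2.loc[gene, trt].mean() - est.gene_log2.loc[gene, ctrl].mean()
            assert fc == pytest.approx(truth.loc[gene, "log2fc"], abs=1e-6)

    def test_unknown_probe_rejected(self, small_experiment):
        pm = small_experiment.matrix
        bad = pm.intensities.copy()
        bad.index = ["alien"] + list(bad.index[1:])
        with pytest.raises(SummarizationError, match="alien"):
            summarize_chip(ProbeMatrix(bad, pm.samples), small_experiment.annotation)

    def test_dabg_in_unit_interval(self, small_estimates):
        p = small_estimates.probeset_dabg.to_numpy()
        assert (p > 0).all() and (p <= 1).all()

    def test_estimates_roundtrip(self, small_estimates, tmp_path):
        write_estimates(small_estimates, tmp_path / "est")
        back = read_estimates(tmp_path / "est")
        pd.testing.assert_frame_equal(back.gene_log2, small_estimates.gene_log2)
        pd.testing.assert_frame_equal(back.probeset_log2, small_estimates.probeset_log2)
        pd.testing.assert_frame_equal(
            back.samples, small_estimates.samples, check_dtype=False
        )
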