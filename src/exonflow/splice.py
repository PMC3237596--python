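"""Splicing-index computation and the five-criterion filter cascade.

A probeset's *splicing index* (normalized probeset intensity) is its log2
exon-level estimate minus the log2 gene-level estimate of its
meta-probeset, per sample.  Removing the gene-level signal makes the
statistic invariant to overall expression changes, so a residual
treated-vs-control difference indicates a shift in isoform usage.

A probeset is called differentially spliced when ALL of these hold:

a. the gene is expressed in both conditions: gene-level DABG p <= 0.01 in
   at least 3 replicates of each condition;
b. the gene-level estimate is reliable: per-probe condition-mean vectors
   over the meta-probeset's probes correlate between conditions with
   Pearson r >= 0.7 and Spearman rho >= 0.7;
c. gene expression does not change more than 10-fold between conditions
   (|log2 FC| <= log2(10) = 3.32);
d. the t-test on the splicing-index replicate vectors gives p <= 0.001;
e. the exon is detected in at least one condition (probeset DABG p <= 0.01
   in >= 3 replicates) and, in that condition, the probeset sits within
   5-fold of the gene level (|log2 probeset - log2 gene| <= log2(5) = 2.32).

Called probesets are then mapped to annotated alternative events.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ChipAnnotation, EventAnnotation
from .diffexp import student_t_test
from .summarize import ExpressionEstimates, ProbeMatrix

__all__ = [
    "FOLD_CAP_LOG2",
    "RATIO_BOUND_LOG2",
    "DEFAULT_SPLICE_P",
    "splicing_index",
    "filter_a_expressed",
    "filter_b_reliability",
    "filter_c_foldcap",
    "filter_d_ttest",
    "filter_e_exon_detect",
    "call_differential_splicing",
    "map_events",
    "event_class_summary",
]

#: Gene expression between conditions must not exceed 10-fold (criterion c).
FOLD_CAP_LOG2 = float(np.log2(10.0))
#: Probeset intensity must lie within 5-fold of the gene level (criterion e).
RATIO_BOUND_LOG2 = float(np.log2(5.0))
#: Significance threshold for the splicing-index t-test (criterion d);
#: the stricter published alternative is 0.0005.
DEFAULT_SPLICE_P = 0.001

DABG_ALPHA = 0.01
MIN_DETECTED_REPS = 3
CORR_MIN = 0.7


def splicing_index(probeset_log2: pd.Series, gene_log2: pd.Series) -> pd.Series:
    """Per-sample probeset minus gene log2 estimate (normalized intensity)."""
    if list(probeset_log2.index) != list(gene_log2.index):
        raise ValueError("probeset and gene estimates cover different samples")
    return probeset_log2 - gene_log2


def filter_a_expressed(
    gene_dabg_ctrl, gene_dabg_trt,
    dabg_alpha: float = DABG_ALPHA, min_reps: int = MIN_DETECTED_REPS,
) -> tuple[int, int, bool]:
    """Criterion a: gene detected in >= 3 replicates of *each* condition.

    Returns (detected control replicates, detected treated replicates, pass).
    """
    n_ctrl = int(np.sum(np.asarray(gene_dabg_ctrl, dtype=float) <= dabg_alpha))
    n_trt = int(np.sum(np.asarray(gene_dabg_trt, dtype=float) <= dabg_alpha))
    return n_ctrl, n_trt, (n_ctrl >= min_reps and n_trt >= min_reps)


def filter_b_reliability(
    probe_log2_ctrl: np.ndarray, probe_log2_trt: np.ndarray,
    corr_min: float = CORR_MIN,
) -> tuple[float, float, bool]:
    """Criterion b: per-probe condition means must correlate between conditions.

    Inputs are probes × replicates log2 intensity blocks for the whole
    meta-probeset.  Returns (Pearson r, Spearman rho, pass); zero variance
    in either mean vector leaves the correlations undefined and fails.
    """
    mean_ctrl = np.asarray(probe_log2_ctrl, dtype=float).mean(axis=1)
    mean_trt = np.asarray(probe_log2_trt, dtype=float).mean(axis=1)
    if mean_ctrl.size < 3:
        raise ValueError("reliability check needs at least 3 probes")
    if np.std(mean_ctrl) == 0 or np.std(mean_trt) == 0:
        warnings.warn("zero variance in condition-mean probe vector", RuntimeWarning)
        return float("nan"), float("nan"), False
    r = float(stats.pearsonr(mean_ctrl, mean_trt).statistic)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant-rank warnings handled above
        rho = float(stats.spearmanr(mean_ctrl, mean_trt).statistic)
    if np.isnan(rho):
        return r, rho, False
    return r, rho, (r >= corr_min and rho >= corr_min)


def filter_c_foldcap(
    gene_log2_ctrl, gene_log2_trt, fold_cap_log2: float = FOLD_CAP_LOG2
) -> tuple[float, bool]:
    """Criterion c: |gene log2 FC| must not exceed log2(10); boundary passes."""
    fc = abs(float(np.mean(gene_log2_trt)) - float(np.mean(gene_log2_ctrl)))
    return fc, fc <= fold_cap_log2


def filter_d_ttest(
    si_ctrl, si_trt, p_threshold: float = DEFAULT_SPLICE_P
) -> tuple[float, bool]:
    """Criterion d: splicing-index t-test p <= threshold; boundary passes."""
    _t, p = student_t_test(si_ctrl, si_trt)
    return p, p <= p_threshold


def filter_e_exon_detect(
    ps_dabg_ctrl, ps_dabg_trt,
    ratio_log2_ctrl, ratio_log2_trt,
    dabg_alpha: float = DABG_ALPHA,
    min_reps: int = MIN_DETECTED_REPS,
    ratio_bound_log2: float = RATIO_BOUND_LOG2,
) -> tuple[str, float, bool]:
    """Criterion e: detectable exon with in-range probeset/gene ratio.

    The probeset must be detected (DABG <= 0.01 in >= 3 replicates) in at
    least one condition, and in that same condition the mean log2
    probeset - gene ratio must lie within ±log2(5).  Returns (qualifying
    condition or '', the ratio in that condition, pass).
    """
    for name, dabg, ratio in (
        ("treated", ps_dabg_trt, ratio_log2_trt),
        ("control", ps_dabg_ctrl, ratio_log2_ctrl),
    ):
        detected = int(np.sum(np.asarray(dabg, dtype=float) <= dabg_alpha)) >= min_reps
        mean_ratio = float(np.mean(ratio))
        if detected and abs(mean_ratio) <= ratio_bound_log2:
            return name, mean_ratio, True
    return "", float("nan"), False


def call_differential_splicing(
    est: ExpressionEstimates,
    pm: ProbeMatrix,
    annot: ChipAnnotation,
    p_threshold: float = DEFAULT_SPLICE_P,
    corr_min: float = CORR_MIN,
    fold_cap_log2: float = FOLD_CAP_LOG2,
    ratio_bound_log2: float = RATIO_BOUND_LOG2,
    dabg_alpha: float = DABG_ALPHA,
    min_reps: int = MIN_DETECTED_REPS,
) -> pd.DataFrame:
    """Evaluate every probeset of every included gene against criteria a–e.

    The overall ``called`` flag is the pure conjunction of the five
    criteria; every measured quantity behind each flag is recorded so the
    decisions are reproducible from the table alone.  ``pm`` must be the
    same (normalized) matrix the estimates were computed from — criterion b
    works on its probe-level intensities.
    """
    ctrl = est.condition_samples("control")
    trt = est.condition_samples("treated")
    samples = list(est.gene_log2.columns)

    fg = annot.foreground.set_index("probe_id")
    fg = fg.loc[fg.index.intersection(pm.intensities.index)]
    log2_probes = pd.DataFrame(
        np.log2(pm.intensities.loc[fg.index].to_numpy(dtype=float)),
        index=fg.index,
        columns=pm.intensities.columns,
    )

    included = set(est.gene_log2.index)
    ps_info = est.probeset_info.set_index("probeset_id")

    # gene-level criteria (a, b, c) once per meta-probeset
    gene_flags: dict[str, dict] = {}
    probes_by_gene = fg.groupby("meta_probeset_id").groups
    for gene in sorted(included):
        dab_ctrl = est.gene_dabg.loc[gene, ctrl]
        dab_trt = est.gene_dabg.loc[gene, trt]
        a_ctrl, a_trt, a_pass = filter_a_expressed(dab_ctrl, dab_trt, dabg_alpha, min_reps)
        block = log2_probes.loc[probes_by_gene[gene]]
        r, rho, b_pass = filter_b_reliability(
            block[ctrl].to_numpy(), block[trt].to_numpy(), corr_min
        )
        c_fc, c_pass = filter_c_foldcap(
            est.gene_log2.loc[gene, ctrl], est.gene_log2.loc[gene, trt], fold_cap_log2
        )
        gene_flags[gene] = {
            "a_ctrl_reps": a_ctrl, "a_trt_reps": a_trt, "a_pass": a_pass,
            "b_pearson": r, "b_spearman": rho, "b_pass": b_pass,
            "c_abs_log2fc": c_fc, "c_pass": c_pass,
        }

    # probeset-level criteria (d, e) vectorized over all candidate probesets
    candidates = ps_info.index[ps_info["meta_probeset_id"].isin(included)]
    ps_log2 = est.probeset_log2.loc[candidates]
    gene_of = ps_info.loc[candidates, "meta_probeset_id"]
    gene_log2_for_ps = est.gene_log2.loc[gene_of.values]
    gene_log2_for_ps.index = candidates
    si = ps_log2[samples].to_numpy() - gene_log2_for_ps[samples].to_numpy()
    si_df = pd.DataFrame(si, index=candidates, columns=samples)

    ctrl_idx = [samples.index(s) for s in ctrl]
    trt_idx = [samples.index(s) for s in trt]
    with np.errstate(invalid="ignore", divide="ignore"):
        t_stat, d_p = stats.ttest_ind(
            si[:, trt_idx], si[:, ctrl_idx], axis=1, equal_var=True
        )
    t_stat = np.where(np.isnan(t_stat), 0.0, t_stat)
    d_p = np.where(np.isnan(d_p), 1.0, d_p)
    d_pass = d_p <= p_threshold

    ps_dabg = est.probeset_dabg.loc[candidates]
    det_ctrl = (ps_dabg[ctrl] <= dabg_alpha).sum(axis=1).to_numpy() >= min_reps
    det_trt = (ps_dabg[trt] <= dabg_alpha).sum(axis=1).to_numpy() >= min_reps
    ratio_ctrl = si[:, ctrl_idx].mean(axis=1)
    ratio_trt = si[:, trt_idx].mean(axis=1)
    ok_ctrl = det_ctrl & (np.abs(ratio_ctrl) <= ratio_bound_log2)
    ok_trt = det_trt & (np.abs(ratio_trt) <= ratio_bound_log2)
    e_pass = ok_ctrl | ok_trt
    e_condition = np.where(ok_trt, "treated", np.where(ok_ctrl, "control", ""))
    e_ratio = np.where(ok_trt, ratio_trt, np.where(ok_ctrl, ratio_ctrl, np.nan))

    rows = pd.DataFrame(
        {
            "probeset_id": candidates,
            "meta_probeset_id": gene_of.values,
            "mean_si_ctrl": ratio_ctrl,
            "mean_si_trt": ratio_trt,
            "delta_si": ratio_trt - ratio_ctrl,
            "t": t_stat,
            "d_p": d_p,
            "d_pass": d_pass,
            "e_condition": e_condition,
            "e_log2_ratio": e_ratio,
            "e_pass": e_pass,
        }
    )
    gene_part = pd.DataFrame.from_dict(gene_flags, orient="index")
    rows = rows.join(gene_part, on="meta_probeset_id")
    rows["called"] = (
        rows["a_pass"] & rows["b_pass"] & rows["c_pass"] & rows["d_pass"] & rows["e_pass"]
    )
    rows["event_class"] = ""
    si_cols = {s: si_df[s].to_numpy() for s in samples}
    for s in samples:
        rows[f"si_{s}"] = si_cols[s]
    return rows.reset_index(drop=True)


def map_events(calls: pd.DataFrame, events: EventAnnotation) -> pd.DataFrame:
    """Annotate called probesets with their alternative-event class.

    Probesets without an event record stay unannotated (empty class); a
    probeset carrying several conflicting records is annotated with all of
    them (joined with ``|``) and triggers a warning.
    """
    out = calls.copy()
    by_ps = events.events.groupby("probeset_id")["event_class"].agg(list)
    conflicts = by_ps[by_ps.map(len) > 1]
    if len(conflicts) and out.loc[out["called"], "probeset_id"].isin(conflicts.index).any():
        warnings.warn(
            f"{len(conflicts)} probesets carry multiple event classes", RuntimeWarning
        )
    mapped = out["probeset_id"].map(by_ps).map(
        lambda v: "|".join(v) if isinstance(v, list) else ""
    )
    out["event_class"] = np.where(out["called"], mapped, "")
    return out


def event_class_summary(calls: pd.DataFrame) -> pd.DataFrame:
    """Counts and percentages of event classes among called probesets.

    Percentages are relative to the total number of called probesets.
    Multi-class probesets count once per class; the ``mapped`` row counts
    each probeset once.
    """
    called = calls.loc[calls["called"]]
    total = len(called)
    counts: dict[str, int] = {}
    mapped = 0
    for classes in called["event_class"]:
        if classes:
            mapped += 1
            for cls in classes.split("|"):
                counts[cls] = counts.get(cls, 0) + 1
    rows = [
        {"event_class": cls, "n": n, "pct_of_called": 100.0 * n / total if total else 0.0}
        for cls, n in sorted(counts.items())
    ]
    rows.append(
        {
            "event_class": "mapped",
            "n": mapped,
            "pct_of_called": 100.0 * mapped / total if total else 0.0,
        }
    )
    rows.append({"event_class": "called_total", "n": total, "pct_of_called": 100.0})
    return pd.DataFrame(rows, columns=["event_class", "n", "pct_of_called"])
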