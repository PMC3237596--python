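"""Gene-level differential expression calling.

Treated vs control gene-level log2 estimates are compared with a two-sided
pooled-variance Student t-test; multiplicity is handled with Storey
q-values, and a gene is called regulated when it is detected above
background, |log2 fold change| >= 1 (two-fold) and q < 0.005.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .summarize import ExpressionEstimates

__all__ = [
    "QvalueFit",
    "student_t_test",
    "storey_qvalues",
    "call_differential_genes",
    "DEFAULT_ALPHA_Q",
    "DEFAULT_MIN_FOLD",
]

DEFAULT_ALPHA_Q = 0.005   # q-value significance cutoff
DEFAULT_MIN_FOLD = 2.0    # minimum linear fold change


def student_t_test(group_a, group_b) -> tuple[float, float]:
    """Two-sided equal-variance (pooled) t-test; df = n_a + n_b - 2.

    The sign of t follows mean(a) - mean(b).  Degenerate inputs: two
    constant equal groups give (0, 1); two constant unequal groups give
    p = 0 with a warning, since the pooled variance vanishes.
    """
    a = np.asarray(list(group_a), dtype=float)
    b = np.asarray(list(group_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("t-test needs at least 2 replicates per group")
    if np.var(a) == 0 and np.var(b) == 0:
        if a.mean() == b.mean():
            return 0.0, 1.0
        warnings.warn("degenerate variance: constant unequal groups", RuntimeWarning)
        return float(np.sign(a.mean() - b.mean()) * np.inf), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass(frozen=True)
class QvalueFit:
    """Storey FDR fit: tuning parameter lambda, pi0 estimate, q-values."""

    lambda_: float
    pi0: float
    qvalues: np.ndarray


def storey_qvalues(pvals, lambda_: float = 0.5, pi0: float | None = None) -> QvalueFit:
    """Storey q-values with the fixed-lambda plug-in pi0 estimate.

    pi0 = min(1, #{p > lambda} / (m (1 - lambda))); for sorted p_(i),
    q_(i) = min_{j >= i} pi0 * m * p_(j) / j, capped at 1.  A pi0 of zero
    (no p above lambda) is floored at 1/m so that pi0 stays in (0, 1].
    Forcing ``pi0=1`` reproduces Benjamini–Hochberg adjusted p-values.
    """
    p = np.asarray(list(pvals), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)) or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if pi0 is None:
        pi0 = np.sum(p > lambda_) / (m * (1.0 - lambda_))
        pi0 = min(1.0, pi0)
        if pi0 <= 0:
            pi0 = 1.0 / m
    if not 0 < pi0 <= 1:
        raise ValueError("pi0 must be in (0, 1]")
    order = np.argsort(p, kind="stable")
    ranked = pi0 * m * p[order] / np.arange(1, m + 1)
    q_sorted = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return QvalueFit(lambda_=lambda_, pi0=float(pi0), qvalues=q)


def call_differential_genes(
    est: ExpressionEstimates,
    alpha_q: float = DEFAULT_ALPHA_Q,
    min_fold: float = DEFAULT_MIN_FOLD,
    dabg_alpha: float = 0.01,
    min_detected_reps: int = 3,
) -> pd.DataFrame:
    """Call up/down-regulated genes from gene-level estimates.

    A gene enters the test when its gene-level DABG p is <= ``dabg_alpha``
    in at least ``min_detected_reps`` replicates of at least one condition.
    q-values are computed across the detected genes; the call is ``up``
    iff log2FC >= log2(min_fold), q < alpha_q and detected (``down``
    symmetric).  Returns one row per included gene.
    """
    ctrl = est.condition_samples("control")
    trt = est.condition_samples("treated")
    if len(ctrl) < 2 or len(trt) < 2:
        raise ValueError("need at least 2 replicates per condition")

    genes = est.gene_log2.index
    ctrl_vals = est.gene_log2[ctrl].to_numpy()
    trt_vals = est.gene_log2[trt].to_numpy()

    detected = (
        ((est.gene_dabg[ctrl] <= dabg_alpha).sum(axis=1) >= min_detected_reps)
        | ((est.gene_dabg[trt] <= dabg_alpha).sum(axis=1) >= min_detected_reps)
    ).to_numpy()

    t, p = stats.ttest_ind(trt_vals, ctrl_vals, axis=1, equal_var=True)
    log2fc = trt_vals.mean(axis=1) - ctrl_vals.mean(axis=1)
    t = np.where(np.isnan(t), 0.0, t)
    p = np.where(np.isnan(p), 1.0, p)

    q = np.full(len(genes), np.nan)
    if detected.any():
        q[detected] = storey_qvalues(p[detected]).qvalues

    min_log2fc = np.log2(min_fold)
    call = np.where(
        detected & (q < alpha_q) & (log2fc >= min_log2fc),
        "up",
        np.where(detected & (q < alpha_q) & (log2fc <= -min_log2fc), "down", "none"),
    )

    return pd.DataFrame(
        {
            "meta_probeset_id": genes,
            "mean_log2_ctrl": ctrl_vals.mean(axis=1),
            "mean_log2_trt": trt_vals.mean(axis=1),
            "log2fc": log2fc,
            "fc": np.exp2(log2fc),
            "t": t,
            "p": p,
            "q": q,
            "detected": detected,
            "call": call,
        }
    ).reset_index(drop=True)
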