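"""Normalization, probe summarization and detection-above-background.

The probe-level entry point is a positive linear-scale intensity matrix
(probes × samples) with ``control`` / ``treated`` condition labels.  This
module turns it into probeset-level (exon-level) and meta-probeset-level
(gene-level) log2 expression estimates:

1. quantile normalization across arrays,
2. log2 transform and Tukey median-polish summarization of the additive
   model  log2(I) = overall + probe effect + sample effect + residual,
   per probeset (all probes) and per gene (core probes only),
3. DABG (detection above background) p-values — the empirical upper-tail
   rank of each probe's intensity within its GC-matched antigenomic
   background bin, combined to probeset level with Fisher's method.

Genes with fewer than 11 core probes are flagged and excluded from all
downstream analyses; the exclusion threshold is ``min_core_probes``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ChipAnnotation

__all__ = [
    "ProbeMatrix",
    "ExpressionEstimates",
    "GcBackground",
    "SummarizationError",
    "quantile_normalize",
    "quantile_normalize_matrix",
    "read_probe_inputs",
    "dabg_probe_p",
    "dabg_probeset_p",
    "median_polish",
    "median_polish_summarize",
    "summarize_chip",
    "write_estimates",
    "read_estimates",
    "MIN_CORE_PROBES",
]

#: Minimum number of core probes a meta-probeset needs for a reliable
#: gene-level estimate; genes below are excluded from all analyses.
MIN_CORE_PROBES = 11

CONDITIONS = ("control", "treated")


class SummarizationError(ValueError):
    """Raised on malformed intensity input (non-positive, missing, unknown probes)."""


@dataclass(frozen=True)
class ProbeMatrix:
    """Linear-scale probe × sample intensities plus sample condition labels."""

    intensities: pd.DataFrame
    samples: pd.DataFrame  # columns: sample_id, condition

    def __post_init__(self) -> None:
        vals = self.intensities.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise SummarizationError("intensity matrix contains missing cells")
        if (vals <= 0).any():
            raise SummarizationError("intensities must be strictly positive (linear scale)")
        if list(self.samples["sample_id"]) != list(self.intensities.columns):
            raise SummarizationError("sample sheet does not match matrix columns")
        bad = set(self.samples["condition"]) - set(CONDITIONS)
        if bad:
            raise SummarizationError(f"unknown conditions: {sorted(bad)}")

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample_id"]
        return list(sel)


# ---------------------------------------------------------------------------
# Quantile normalization
# ---------------------------------------------------------------------------


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Quantile-normalize columns to the mean empirical distribution.

    Every column's sorted values become the across-column mean of sorted
    values; within-column ranks are preserved, and tied values receive the
    mean of the tied positions' reference values.
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise SummarizationError("quantile normalization needs at least 2 samples")
    if (vals <= 0).any():
        raise SummarizationError("intensities must be strictly positive")
    n, m = vals.shape
    ref = np.sort(vals, axis=0).mean(axis=1)
    out = np.empty_like(vals)
    for j in range(m):
        col = vals[:, j]
        order = np.argsort(col, kind="stable")
        assigned = np.empty(n)
        assigned[order] = ref
        uniq, inv = np.unique(col, return_inverse=True)
        if len(uniq) < n:  # ties: average the reference values they span
            sums = np.bincount(inv, weights=assigned)
            counts = np.bincount(inv)
            assigned = (sums / counts)[inv]
        out[:, j] = assigned
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize_matrix(pm: ProbeMatrix) -> ProbeMatrix:
    """Quantile-normalize a :class:`ProbeMatrix`, keeping its sample sheet."""
    return ProbeMatrix(quantile_normalize(pm.intensities), pm.samples)


# ---------------------------------------------------------------------------
# DABG
# ---------------------------------------------------------------------------


class GcBackground:
    """Antigenomic background intensities of one sample, binned by GC count.

    Empty GC bins are served by the nearest non-empty bin (ties broken
    toward lower GC), so every probe has a reference distribution.
    """

    def __init__(self, intensities: np.ndarray, gc: np.ndarray):
        intensities = np.asarray(intensities, dtype=float)
        gc = np.asarray(gc, dtype=int)
        if intensities.size == 0:
            raise SummarizationError("empty background registry")
        self._bins: dict[int, np.ndarray] = {
            int(g): np.sort(intensities[gc == g]) for g in np.unique(gc)
        }
        self._nonempty = np.array(sorted(self._bins), dtype=int)

    def bin_for(self, gc: int) -> np.ndarray:
        """Sorted background intensities for this GC count (pooled if empty)."""
        if gc in self._bins:
            return self._bins[gc]
        nearest = self._nonempty[np.argmin(np.abs(self._nonempty - gc))]
        return self._bins[int(nearest)]

    def p_value(self, x: float, gc: int) -> float:
        arr = self.bin_for(gc)
        n_ge = arr.size - np.searchsorted(arr, x, side="left")
        return (1.0 + n_ge) / (1.0 + arr.size)

    def p_values(self, x: np.ndarray, gc: np.ndarray) -> np.ndarray:
        """Vectorized probe p-values; groups probes by GC bin internally."""
        x = np.asarray(x, dtype=float)
        gc = np.asarray(gc, dtype=int)
        out = np.empty(x.shape, dtype=float)
        for g in np.unique(gc):
            arr = self.bin_for(int(g))
            mask = gc == g
            n_ge = arr.size - np.searchsorted(arr, x[mask], side="left")
            out[mask] = (1.0 + n_ge) / (1.0 + arr.size)
        return out


def dabg_probe_p(intensity: float, gc: int, background: GcBackground) -> float:
    """Empirical upper-tail p of one probe intensity vs its GC-matched bin.

    p = (1 + #{background >= x}) / (1 + N_bin), so p is in (0, 1].
    """
    return background.p_value(intensity, gc)


def dabg_probeset_p(probe_ps) -> float:
    """Combine probe-level DABG p-values with Fisher's method.

    X = -2 * sum(ln p_i) is referred to a chi-square with 2k degrees of
    freedom; with a single probe this is the identity.
    """
    p = np.asarray(list(probe_ps), dtype=float)
    if p.size == 0:
        raise SummarizationError("cannot combine an empty list of p-values")
    x = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(x, df=2 * p.size))


# ---------------------------------------------------------------------------
# Median polish
# ---------------------------------------------------------------------------


def _median_polish_batch(z: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Tukey median polish of a stack of matrices (units × rows × cols).

    Alternates row- and column-median sweeps of the additive decomposition
    value = overall + row + col + residual, until the largest residual
    change is below ``tol`` or ``max_iter`` sweeps have run.  Returns
    (overall, row effects, column effects, residuals).
    """
    z = np.array(z, dtype=float)
    u, r, c = z.shape
    overall = np.zeros(u)
    row = np.zeros((u, r))
    col = np.zeros((u, c))
    for _ in range(max_iter):
        old = z.copy()
        rdelta = np.median(z, axis=2)
        z -= rdelta[:, :, None]
        row += rdelta
        delta = np.median(col, axis=1)
        col -= delta[:, None]
        overall += delta
        cdelta = np.median(z, axis=1)
        z -= cdelta[:, None, :]
        col += cdelta
        delta = np.median(row, axis=1)
        row -= delta[:, None]
        overall += delta
        if np.max(np.abs(z - old)) < tol:
            break
    return overall, row, col, z


def median_polish(matrix: np.ndarray, max_iter: int = 10, tol: float = 1e-6):
    """Median polish of one probes × samples matrix.

    Returns (overall, probe effects, sample effects, residuals).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.size == 0:
        raise SummarizationError("median polish needs a non-empty 2-D matrix")
    overall, row, col, resid = _median_polish_batch(matrix[None], max_iter, tol)
    return overall[0], row[0], col[0], resid[0]


def median_polish_summarize(log2_submatrix: np.ndarray) -> np.ndarray:
    """Per-sample summary of a log2 probe submatrix: overall + sample effect."""
    overall, _row, col, _resid = median_polish(log2_submatrix)
    return overall + col


# ---------------------------------------------------------------------------
# Chip-level summarization
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionEstimates:
    """Probeset- and gene-level log2 estimates with DABG p-values.

    ``gene_log2`` / ``gene_dabg`` contain only meta-probesets passing the
    core-probe filter; ``excluded`` records the rest with the measured core
    probe count.
    """

    probeset_log2: pd.DataFrame  # probeset × sample
    probeset_dabg: pd.DataFrame  # probeset × sample, Fisher-combined
    gene_log2: pd.DataFrame      # meta-probeset × sample (included genes)
    gene_dabg: pd.DataFrame      # meta-probeset × sample, Fisher over core probesets
    probeset_info: pd.DataFrame  # probeset_id, meta_probeset_id, probeset_class, n_probes
    gene_info: pd.DataFrame      # meta_probeset_id, n_core_probes, included
    excluded: pd.DataFrame       # meta_probeset_id, n_core_probes, reason
    samples: pd.DataFrame        # sample_id, condition

    def condition_samples(self, condition: str) -> list[str]:
        sel = self.samples.loc[self.samples["condition"] == condition, "sample_id"]
        return list(sel)


def _grouped_median_polish(log2: np.ndarray, groups: pd.Series) -> pd.DataFrame:
    """Median-polish summaries for many probe groups sharing a matrix.

    ``groups`` maps matrix row position -> group id.  Groups of equal size
    are polished as one batched call.
    """
    n_samples = log2.shape[1]
    frame = pd.DataFrame({"group": groups.values, "row": np.arange(len(groups))})
    sizes = frame.groupby("group")["row"].agg(list)
    out_index: list = []
    out_rows: list = []
    by_size: dict[int, list] = {}
    for gid, rows in sizes.items():
        by_size.setdefault(len(rows), []).append((gid, rows))
    for size, members in by_size.items():
        idx = np.array([rows for _gid, rows in members])  # (u, size)
        stack = log2[idx]  # (u, size, n_samples)
        overall, _row, col, _resid = _median_polish_batch(stack)
        est = overall[:, None] + col
        out_index.extend(gid for gid, _rows in members)
        out_rows.append(est)
    est_all = np.vstack(out_rows) if out_rows else np.empty((0, n_samples))
    return pd.DataFrame(est_all, index=out_index).sort_index()


def summarize_chip(
    pm: ProbeMatrix,
    annot: ChipAnnotation,
    min_core_probes: int = MIN_CORE_PROBES,
) -> ExpressionEstimates:
    """Summarize a (quantile-normalized) probe matrix to probeset and gene level.

    Probeset estimates use all of a probeset's probes; gene estimates use
    only the gene's core probes.  Meta-probesets with fewer than
    ``min_core_probes`` core probes are excluded.  DABG p-values are
    computed per sample on the supplied (normalized) intensities: probe →
    probeset via Fisher's method, probeset → gene via Fisher's method over
    the gene's core probesets.
    """
    matrix = pm.intensities
    unknown = set(matrix.index) - set(annot.probes["probe_id"])
    if unknown:
        raise SummarizationError(
            f"probes absent from annotation: {sorted(unknown)[:10]}"
        )
    fg = annot.foreground.set_index("probe_id")
    fg = fg.loc[fg.index.intersection(matrix.index)]
    bg = annot.background
    bg_ids = [p for p in bg["probe_id"] if p in matrix.index]
    if not bg_ids:
        raise SummarizationError("no background probes present in the matrix")

    fg_matrix = matrix.loc[fg.index]
    log2 = np.log2(fg_matrix.to_numpy(dtype=float))
    samples = list(matrix.columns)

    # probeset-level estimates (all probes of the probeset)
    ps_est = _grouped_median_polish(log2, fg["probeset_id"])
    ps_est.columns = samples

    # gene-level estimates (core probes only) + exclusion bookkeeping
    core_mask = (fg["probeset_class"] == "core").to_numpy()
    core_counts = annot.core_probe_counts()
    included_genes = core_counts.index[core_counts >= min_core_probes]
    excluded = pd.DataFrame(
        {
            "meta_probeset_id": core_counts.index[core_counts < min_core_probes],
            "n_core_probes": core_counts[core_counts < min_core_probes].values,
        }
    )
    excluded["reason"] = f"fewer than {min_core_probes} core probes"
    core_rows = np.where(core_mask)[0]
    gene_groups = fg["meta_probeset_id"].iloc[core_rows]
    keep = gene_groups.isin(set(included_genes)).to_numpy()
    gene_est = _grouped_median_polish(log2[core_rows[keep]], gene_groups[keep])
    gene_est.columns = samples

    # DABG: per-sample GC-matched empirical p, Fisher-combined upward
    bg_gc = bg.set_index("probe_id").loc[bg_ids, "probe_gc"].to_numpy(dtype=int)
    fg_gc = fg["probe_gc"].to_numpy(dtype=int)
    probe_p = np.empty_like(log2)
    bg_int = matrix.loc[bg_ids].to_numpy(dtype=float)
    fg_int = fg_matrix.to_numpy(dtype=float)
    for j in range(len(samples)):
        registry = GcBackground(bg_int[:, j], bg_gc)
        probe_p[:, j] = registry.p_values(fg_int[:, j], fg_gc)

    neg2logp = -2.0 * np.log(probe_p)
    contrib = pd.DataFrame(neg2logp, columns=samples)
    contrib["probeset_id"] = fg["probeset_id"].values
    ps_group = contrib.groupby("probeset_id")
    ps_x = ps_group[samples].sum()
    ps_k = ps_group.size()
    ps_dabg = pd.DataFrame(
        stats.chi2.sf(ps_x.to_numpy(), df=2 * ps_k.to_numpy()[:, None]),
        index=ps_x.index,
        columns=samples,
    ).clip(lower=np.nextafter(0, 1))

    ps_info = annot.probesets
    core_ps = ps_info.loc[ps_info["probeset_class"] == "core"]
    core_ps_dabg = ps_dabg.loc[ps_dabg.index.intersection(core_ps["probeset_id"])]
    gene_neg2 = -2.0 * np.log(core_ps_dabg)
    gene_neg2["meta_probeset_id"] = (
        core_ps.set_index("probeset_id")
        .loc[core_ps_dabg.index, "meta_probeset_id"]
        .values
    )
    gg = gene_neg2.groupby("meta_probeset_id")
    gene_x = gg[samples].sum()
    gene_k = gg.size()
    gene_dabg = pd.DataFrame(
        stats.chi2.sf(gene_x.to_numpy(), df=2 * gene_k.to_numpy()[:, None]),
        index=gene_x.index,
        columns=samples,
    ).clip(lower=np.nextafter(0, 1))
    gene_dabg = gene_dabg.loc[gene_dabg.index.intersection(included_genes)]

    gene_info = pd.DataFrame(
        {
            "meta_probeset_id": core_counts.index,
            "n_core_probes": core_counts.values,
            "included": core_counts.values >= min_core_probes,
        }
    )

    return ExpressionEstimates(
        probeset_log2=ps_est,
        probeset_dabg=ps_dabg.loc[ps_est.index],
        gene_log2=gene_est.loc[gene_est.index.intersection(included_genes)].sort_index(),
        gene_dabg=gene_dabg.sort_index(),
        probeset_info=ps_info,
        gene_info=gene_info,
        excluded=excluded,
        samples=pm.samples.reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_ESTIMATE_FILES = {
    "probeset_log2": "probeset_log2.tsv",
    "probeset_dabg": "probeset_dabg.tsv",
    "gene_log2": "gene_log2.tsv",
    "gene_dabg": "gene_dabg.tsv",
}


def write_estimates(est: ExpressionEstimates, outdir) -> None:
    """Write an estimate bundle as TSV files under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for attr, fname in _ESTIMATE_FILES.items():
        getattr(est, attr).rename_axis("id").to_csv(outdir / fname, sep="\t")
    est.probeset_info.to_csv(outdir / "probeset_info.tsv", sep="\t", index=False)
    est.gene_info.to_csv(outdir / "gene_info.tsv", sep="\t", index=False)
    est.excluded.to_csv(outdir / "exclusions.tsv", sep="\t", index=False)
    est.samples.to_csv(outdir / "samples.tsv", sep="\t", index=False)


def read_probe_inputs(matrix_path, samples_path, annotation_path):
    """Read a probe matrix, sample sheet and chip annotation from TSV files."""
    from .annotation import read_chip_annotation

    intensities = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    samples = pd.read_csv(samples_path, sep="\t")
    return ProbeMatrix(intensities=intensities, samples=samples), read_chip_annotation(
        annotation_path
    )


def read_estimates(outdir) -> ExpressionEstimates:
    outdir = Path(outdir)
    frames = {
        attr: pd.read_csv(outdir / fname, sep="\t", index_col="id").rename_axis(None)
        for attr, fname in _ESTIMATE_FILES.items()
    }
    return ExpressionEstimates(
        probeset_log2=frames["probeset_log2"],
        probeset_dabg=frames["probeset_dabg"],
        gene_log2=frames["gene_log2"],
        gene_dabg=frames["gene_dabg"],
        probeset_info=pd.read_csv(outdir / "probeset_info.tsv", sep="\t"),
        gene_info=pd.read_csv(outdir / "gene_info.tsv", sep="\t"),
        excluded=pd.read_csv(outdir / "exclusions.tsv", sep="\t"),
        samples=pd.read_csv(outdir / "samples.tsv", sep="\t"),
    )
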