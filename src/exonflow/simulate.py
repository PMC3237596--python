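"""Synthetic probe-level exon-array experiments with known ground truth.

The generator emulates the study design the pipeline targets: four control
vs four androgen-treated replicates on an exon array whose probes are
organised into probesets (exons) and meta-probesets (genes), with core and
extended probeset classes, GC-binned antigenomic background probes,
planted gene-level fold changes, planted isoform effects and a fraction of
unexpressed genes.

Intensities are generated on the log2 scale from the additive model

    x[probe, sample] = mu_gene + a_probe
                       + (c_gene + s_probeset) * [sample is treated]
                       + N(0, noise_sd)

and exponentiated to the linear scale; ``c_gene`` is the planted gene
log2 fold change and ``s_probeset`` a planted splicing-index shift.
Probes of unexpressed genes and background probes are drawn from the
background model ``background_mean + background_gc_slope * (gc - 12.5)
+ N(0, background_sd)``.  Cassette-type events shift a single probeset;
alternative first / last exon events shift a contiguous block of two
probesets at the 5' / 3' end of the gene, the signature alternative
promoter selection and polyadenylation leave on an exon array.

Everything is reproducible from the config seed.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import (
    EVENT_CLASSES,
    ChipAnnotation,
    EventAnnotation,
)
from .summarize import ProbeMatrix

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "SimulatedExperiment",
    "simulate_experiment",
    "write_truth_table",
    "read_truth_table",
    "write_probe_matrix",
    "read_probe_matrix",
]

#: Default mixture over planted event classes.  Alternative first exons
#: dominate, mirroring the androgen response where promoter selection is
#: the largest annotated category, followed by cassette exons.
DEFAULT_EVENT_MIX = {
    "cassette_exon": 0.35,
    "alt_first_exon": 0.30,
    "alt_last_exon": 0.15,
    "alt_5ss": 0.08,
    "alt_3ss": 0.07,
    "mutually_exclusive": 0.05,
}


@dataclass
class SimulationConfig:
    """Study-condition parameters of the synthetic experiment.

    Defaults give a desk-scale experiment: 1000 genes of 8–12 probesets
    with 4 probes each, 2000 background probes, 4 replicates per condition,
    25% unexpressed genes, 10% differentially expressed genes at
    |log2FC| = 1, 5% of probesets carrying an isoform effect of
    |shift| = 1, and log2-scale Gaussian noise of 0.25.
    """

    n_genes: int = 1000
    probesets_per_gene: tuple[int, int] = (8, 12)
    probes_per_probeset: tuple[int, int] = (4, 4)
    n_background_probes: int = 2000
    replicates_per_condition: int = 4
    fraction_unexpressed: float = 0.25
    fraction_de_genes: float = 0.10
    log2fc_de: float = 1.0
    fraction_spliced_probesets: float = 0.05
    splice_effect_log2: float = 1.0
    event_class_mix: dict = field(default_factory=lambda: dict(DEFAULT_EVENT_MIX))
    core_probeset_fraction: float = 0.75
    event_decoy_rate: float = 0.05
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    probe_affinity_sd: float = 1.0
    noise_sd: float = 0.25
    background_mean: float = 4.0
    background_sd: float = 0.8
    background_gc_slope: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        for name in (
            "fraction_unexpressed",
            "fraction_de_genes",
            "fraction_spliced_probesets",
            "core_probeset_fraction",
            "event_decoy_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        for name in ("baseline_sd", "probe_affinity_sd", "noise_sd", "background_sd"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.replicates_per_condition < 2:
            raise ValueError("replicates_per_condition must be >= 2")
        if self.n_genes < 1 or self.n_background_probes < 1:
            raise ValueError("need at least one gene and one background probe")
        lo, hi = self.probesets_per_gene
        plo, phi = self.probes_per_probeset
        if lo < 1 or lo > hi or plo < 1 or plo > phi:
            raise ValueError("count ranges must be non-empty with lo <= hi")
        mix_total = sum(self.event_class_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError("event_class_mix must sum to 1")
        unknown = set(self.event_class_mix) - set(EVENT_CLASSES)
        if unknown:
            raise ValueError(f"unknown event classes in mix: {sorted(unknown)}")


@dataclass(frozen=True)
class TruthTable:
    """Simulator ground truth for parameter-recovery tests.

    ``genes``: meta_probeset_id, expressed, de, log2fc.
    ``probesets``: probeset_id, meta_probeset_id, planted, event_class,
    si_shift.  Planted probesets always belong to expressed genes;
    unexpressed genes carry no effects.
    """

    genes: pd.DataFrame
    probesets: pd.DataFrame

    def __post_init__(self) -> None:
        expressed = set(self.genes.loc[self.genes["expressed"], "meta_probeset_id"])
        planted = self.probesets.loc[self.probesets["planted"], "meta_probeset_id"]
        if not set(planted).issubset(expressed):
            raise ValueError("planted probesets must belong to expressed genes")
        de_unexpr = self.genes.loc[~self.genes["expressed"] & self.genes["de"]]
        if len(de_unexpr):
            raise ValueError("unexpressed genes cannot be differentially expressed")


@dataclass(frozen=True)
class SimulatedExperiment:
    matrix: ProbeMatrix
    annotation: ChipAnnotation
    events: EventAnnotation
    truth: TruthTable
    config: SimulationConfig


def simulate_experiment(config: SimulationConfig) -> SimulatedExperiment:
    """Generate one synthetic experiment; byte-reproducible from the seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_rep = config.replicates_per_condition
    samples = pd.DataFrame(
        {
            "sample_id": [f"ctrl_{i+1}" for i in range(n_rep)]
            + [f"trt_{i+1}" for i in range(n_rep)],
            "condition": ["control"] * n_rep + ["treated"] * n_rep,
        }
    )
    treated = np.array([0.0] * n_rep + [1.0] * n_rep)

    lo, hi = config.probesets_per_gene
    plo, phi = config.probes_per_probeset
    n_ps_per_gene = rng.integers(lo, hi + 1, size=config.n_genes)

    gene_ids = [f"g{i+1:05d}" for i in range(config.n_genes)]
    expressed = rng.random(config.n_genes) < (1.0 - config.fraction_unexpressed)
    de = expressed & (rng.random(config.n_genes) < config.fraction_de_genes)
    de_sign = rng.choice([-1.0, 1.0], size=config.n_genes)
    log2fc = np.where(de, de_sign * config.log2fc_de, 0.0)
    mu = rng.normal(config.baseline_mean, config.baseline_sd, size=config.n_genes)

    # per-gene probeset layout
    ps_gene_idx: list[int] = []
    ps_ids: list[str] = []
    ps_pos_in_gene: list[int] = []
    for gi, nps in enumerate(n_ps_per_gene):
        for k in range(nps):
            ps_gene_idx.append(gi)
            ps_ids.append(f"{gene_ids[gi]}_ps{k+1:02d}")
            ps_pos_in_gene.append(k)
    ps_gene_idx = np.asarray(ps_gene_idx)
    n_ps = len(ps_ids)
    ps_class = np.where(
        rng.random(n_ps) < config.core_probeset_fraction, "core", "extended"
    )
    n_probes_per_ps = rng.integers(plo, phi + 1, size=n_ps)

    # plant isoform effects: expected planted probesets per affected gene
    classes = list(config.event_class_mix)
    class_p = np.array([config.event_class_mix[c] for c in classes])
    block_classes = {"alt_first_exon", "alt_last_exon"}
    mean_ps = (lo + hi) / 2.0
    mean_block = sum(
        p * (2 if c in block_classes else 1) for c, p in zip(classes, class_p)
    )
    p_gene_spliced = min(
        1.0, config.fraction_spliced_probesets * mean_ps / max(mean_block, 1e-12)
    )
    splice_gene = expressed & (rng.random(config.n_genes) < p_gene_spliced)

    ps_shift = np.zeros(n_ps)
    ps_event = np.array([""] * n_ps, dtype=object)
    ps_by_gene: dict[int, np.ndarray] = {}
    for gi in range(config.n_genes):
        ps_by_gene[gi] = np.where(ps_gene_idx == gi)[0]
    for gi in np.where(splice_gene)[0]:
        cls = rng.choice(classes, p=class_p)
        sign = rng.choice([-1.0, 1.0])
        members = ps_by_gene[gi]
        if cls == "alt_first_exon":
            chosen = members[: min(2, len(members))]
        elif cls == "alt_last_exon":
            chosen = members[-min(2, len(members)):]
        else:
            chosen = members[[rng.integers(len(members))]]
        ps_shift[chosen] = sign * config.splice_effect_log2
        ps_event[chosen] = cls

    # decoy annotations on unplanted probesets
    decoy = (ps_event == "") & (rng.random(n_ps) < config.event_decoy_rate)
    decoy_classes = rng.choice(classes, p=class_p, size=n_ps)
    event_class_col = np.where(decoy, decoy_classes, ps_event)

    # probe layout
    probe_ps_idx = np.repeat(np.arange(n_ps), n_probes_per_ps)
    n_probes = len(probe_ps_idx)
    probe_ids = []
    for psi, count in zip(range(n_ps), n_probes_per_ps):
        probe_ids.extend(f"{ps_ids[psi]}_p{j+1}" for j in range(count))
    probe_gene_idx = ps_gene_idx[probe_ps_idx]
    probe_gc = rng.binomial(25, 0.5, size=n_probes)
    affinity = rng.normal(0.0, config.probe_affinity_sd, size=n_probes)

    # log2 intensities
    probe_expressed = expressed[probe_gene_idx]
    signal = (
        mu[probe_gene_idx][:, None]
        + affinity[:, None]
        + (log2fc[probe_gene_idx] + ps_shift[probe_ps_idx])[:, None] * treated[None, :]
    )
    bg_like = (
        config.background_mean
        + config.background_gc_slope * (probe_gc - 12.5)
    )[:, None] * np.ones((1, 2 * n_rep))
    x = np.where(probe_expressed[:, None], signal, bg_like)
    noise_sd = np.where(probe_expressed, config.noise_sd, config.background_sd)
    x = x + rng.normal(0.0, 1.0, size=x.shape) * noise_sd[:, None]

    # antigenomic background probes
    bg_ids = [f"bg{i+1:05d}" for i in range(config.n_background_probes)]
    bg_gc = rng.binomial(25, 0.5, size=config.n_background_probes)
    bg_x = (
        config.background_mean
        + config.background_gc_slope * (bg_gc - 12.5)
    )[:, None] + rng.normal(
        0.0, config.background_sd, size=(config.n_background_probes, 2 * n_rep)
    )

    intensities = pd.DataFrame(
        np.exp2(np.vstack([x, bg_x])),
        index=pd.Index(probe_ids + bg_ids, name="probe_id"),
        columns=list(samples["sample_id"]),
    )
    matrix = ProbeMatrix(intensities=intensities, samples=samples)

    annot_df = pd.DataFrame(
        {
            "probe_id": probe_ids + bg_ids,
            "probeset_id": [ps_ids[i] for i in probe_ps_idx] + [""] * len(bg_ids),
            "meta_probeset_id": [gene_ids[i] for i in probe_gene_idx] + [""] * len(bg_ids),
            "probeset_class": [ps_class[i] for i in probe_ps_idx] + [""] * len(bg_ids),
            "probe_gc": np.concatenate([probe_gc, bg_gc]),
            "is_background": [False] * n_probes + [True] * len(bg_ids),
        }
    )
    annotation = ChipAnnotation(probes=annot_df)

    # event annotation with deterministic genomic intervals
    ev_rows = []
    for psi in np.where(event_class_col != "")[0]:
        gi = ps_gene_idx[psi]
        start = 1_000_000 + gi * 10_000 + ps_pos_in_gene[psi] * 200
        ev_rows.append(
            {
                "probeset_id": ps_ids[psi],
                "event_class": event_class_col[psi],
                "chrom": f"chr{gi % 22 + 1}",
                "start": start,
                "end": start + 100,
                "strand": "+" if gi % 2 == 0 else "-",
            }
        )
    events = EventAnnotation(
        events=pd.DataFrame(
            ev_rows,
            columns=["probeset_id", "event_class", "chrom", "start", "end", "strand"],
        )
    )

    truth = TruthTable(
        genes=pd.DataFrame(
            {
                "meta_probeset_id": gene_ids,
                "expressed": expressed,
                "de": de,
                "log2fc": log2fc,
            }
        ),
        probesets=pd.DataFrame(
            {
                "probeset_id": ps_ids,
                "meta_probeset_id": [gene_ids[i] for i in ps_gene_idx],
                "planted": ps_shift != 0.0,
                "event_class": ps_event,
                "si_shift": ps_shift,
            }
        ),
    )
    return SimulatedExperiment(
        matrix=matrix, annotation=annotation, events=events, truth=truth, config=config
    )


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

_GENES_MARKER = "#[genes]"
_PROBESETS_MARKER = "#[probesets]"


def write_truth_table(truth: TruthTable, path) -> None:
    """Write the truth table as one TSV with a gene and a probeset section."""
    with open(path, "w") as fh:
        fh.write(_GENES_MARKER + "\n")
        truth.genes.to_csv(fh, sep="\t", index=False)
        fh.write(_PROBESETS_MARKER + "\n")
        truth.probesets.to_csv(fh, sep="\t", index=False)


def read_truth_table(path) -> TruthTable:
    text = Path(path).read_text()
    if not text.startswith(_GENES_MARKER):
        raise ValueError("not a truth-table file")
    gene_part, ps_part = text.split(_PROBESETS_MARKER + "\n", 1)
    gene_csv = gene_part[len(_GENES_MARKER) + 1 :]
    genes = pd.read_csv(io.StringIO(gene_csv), sep="\t")
    probesets = pd.read_csv(io.StringIO(ps_part), sep="\t", keep_default_na=False)
    if len(probesets):
        probesets["planted"] = probesets["planted"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    probesets["si_shift"] = probesets["si_shift"].astype(float)
    return TruthTable(genes=genes, probesets=probesets)


def write_probe_matrix(pm: ProbeMatrix, matrix_path, samples_path) -> None:
    pm.intensities.rename_axis("probe_id").to_csv(matrix_path, sep="\t")
    pm.samples.to_csv(samples_path, sep="\t", index=False)


def read_probe_matrix(matrix_path, samples_path) -> ProbeMatrix:
    intensities = pd.read_csv(matrix_path, sep="\t", index_col="probe_id")
    samples = pd.read_csv(samples_path, sep="\t")
    return ProbeMatrix(intensities=intensities, samples=samples)
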