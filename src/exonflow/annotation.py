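"""Chip, event, ontology and gene-association tables.

The exon-array measurement hierarchy has three levels: 25-mer probes are
grouped into *probesets* (one exonic region each), and probesets into
*meta-probesets* (one gene / transcript cluster each).  Probesets carry a
confidence class — ``core`` (RefSeq-supported) or ``extended`` (additional
cDNA evidence).  *Antigenomic background* probes match no genomic sequence;
binned by GC content, they supply the null intensity distribution for
detection-above-background (DABG) calls.

All tables travel as tab-separated text with a mandatory header row and
``#`` comment lines; genomic intervals are 0-based half-open with BED6 as
the interchange format.  Ontologies are read from OBO files, keeping only
``[Term]`` stanzas and ``is_a`` edges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import obonet
import pandas as pd

__all__ = [
    "EVENT_CLASSES",
    "AnnotationError",
    "ChipAnnotation",
    "EventAnnotation",
    "OntologyDag",
    "GeneTermAssociations",
    "read_chip_annotation",
    "write_chip_annotation",
    "read_event_annotation",
    "write_event_annotation",
    "write_event_bed",
    "read_obo_subset",
    "read_gene_associations",
    "write_gene_associations",
]

#: Alternative-event taxonomy: the four classical splicing event kinds plus
#: alternative first exons (promoter selection) and alternative last exons
#: (alternative polyadenylation).
EVENT_CLASSES = (
    "cassette_exon",
    "alt_5ss",
    "alt_3ss",
    "mutually_exclusive",
    "alt_first_exon",
    "alt_last_exon",
)

CHIP_COLUMNS = (
    "probe_id",
    "probeset_id",
    "meta_probeset_id",
    "probeset_class",
    "probe_gc",
    "is_background",
)


class AnnotationError(ValueError):
    """Raised when an annotation table violates its structural invariants."""


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


# ---------------------------------------------------------------------------
# Chip annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChipAnnotation:
    """Probe → probeset → meta-probeset hierarchy plus background registry.

    ``probes`` holds one row per probe with columns ``probe_id``,
    ``probeset_id``, ``meta_probeset_id``, ``probeset_class`` (``core`` or
    ``extended``; empty for background probes), ``probe_gc`` (0–25) and
    ``is_background``.  Background probes carry GC content but no probeset.
    """

    probes: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.probes
        missing = set(CHIP_COLUMNS) - set(df.columns)
        if missing:
            raise AnnotationError(f"chip annotation missing columns: {sorted(missing)}")
        if df["probe_id"].duplicated().any():
            dupes = df.loc[df["probe_id"].duplicated(), "probe_id"].unique()[:5]
            raise AnnotationError(
                "duplicate probe_id (a probe may belong to only one probeset): "
                f"{list(dupes)}"
            )
        gc = df["probe_gc"]
        if ((gc < 0) | (gc > 25)).any():
            raise AnnotationError("probe_gc outside the 0-25 range of a 25-mer")
        bg = df["is_background"].astype(bool)
        if (df.loc[bg, "probeset_id"] != "").any() or (
            df.loc[bg, "meta_probeset_id"] != ""
        ).any():
            raise AnnotationError("background probes must not carry a probeset")
        fg = df.loc[~bg]
        if (fg["probeset_id"] == "").any() or (fg["meta_probeset_id"] == "").any():
            raise AnnotationError("non-background probes need probeset and meta-probeset")
        bad_class = set(fg["probeset_class"]) - {"core", "extended"}
        if bad_class:
            raise AnnotationError(f"unknown probeset_class values: {sorted(bad_class)}")
        per_ps = fg.groupby("probeset_id").agg(
            n_meta=("meta_probeset_id", "nunique"),
            n_class=("probeset_class", "nunique"),
        )
        if (per_ps["n_meta"] > 1).any():
            bad = per_ps.index[per_ps["n_meta"] > 1][:5]
            raise AnnotationError(f"probeset mapped to multiple meta-probesets: {list(bad)}")
        if (per_ps["n_class"] > 1).any():
            bad = per_ps.index[per_ps["n_class"] > 1][:5]
            raise AnnotationError(f"probeset with mixed core/extended class: {list(bad)}")

    # -- convenience views ---------------------------------------------------

    @property
    def foreground(self) -> pd.DataFrame:
        """Rows for probes that interrogate a probeset (non-background)."""
        return self.probes.loc[~self.probes["is_background"].astype(bool)]

    @property
    def background(self) -> pd.DataFrame:
        """Rows for antigenomic background probes (probe_id, probe_gc)."""
        return self.probes.loc[self.probes["is_background"].astype(bool)]

    @property
    def probesets(self) -> pd.DataFrame:
        """One row per probeset: meta_probeset_id, probeset_class, n_probes."""
        fg = self.foreground
        return (
            fg.groupby("probeset_id")
            .agg(
                meta_probeset_id=("meta_probeset_id", "first"),
                probeset_class=("probeset_class", "first"),
                n_probes=("probe_id", "size"),
            )
            .reset_index()
        )

    def core_probe_counts(self) -> pd.Series:
        """Number of core probes per meta-probeset (gene)."""
        fg = self.foreground
        core = fg.loc[fg["probeset_class"] == "core"]
        counts = core.groupby("meta_probeset_id")["probe_id"].size()
        all_meta = fg["meta_probeset_id"].unique()
        return counts.reindex(all_meta, fill_value=0).astype(int)


def read_chip_annotation(path) -> ChipAnnotation:
    """Read a chip-annotation TSV and validate all hierarchy invariants."""
    df = _read_tsv(path)
    missing = set(CHIP_COLUMNS) - set(df.columns)
    if missing:
        raise AnnotationError(f"chip annotation missing columns: {sorted(missing)}")
    try:
        df["probe_gc"] = df["probe_gc"].astype(int)
    except ValueError as exc:
        raise AnnotationError(f"non-integer probe_gc: {exc}") from exc
    df["is_background"] = df["is_background"].map(
        {"1": True, "0": False, "true": True, "false": False, "True": True, "False": False}
    )
    if df["is_background"].isna().any():
        raise AnnotationError("is_background must be 0/1 or true/false")
    return ChipAnnotation(probes=df.reset_index(drop=True))


def write_chip_annotation(annot: ChipAnnotation, path) -> None:
    out = annot.probes.copy()
    out["is_background"] = out["is_background"].astype(bool).map({True: "1", False: "0"})
    out.to_csv(path, sep="\t", index=False, columns=list(CHIP_COLUMNS))


# ---------------------------------------------------------------------------
# Event annotation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EventAnnotation:
    """Probeset → alternative-event class mapping, with optional intervals.

    Columns: ``probeset_id``, ``event_class`` and, when present together,
    ``chrom``, ``start``, ``end`` (0-based half-open) and ``strand``.
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.events
        for col in ("probeset_id", "event_class"):
            if col not in df.columns:
                raise AnnotationError(f"event annotation missing column {col!r}")
        unknown = set(df["event_class"]) - set(EVENT_CLASSES)
        if unknown:
            raise AnnotationError(f"unknown event_class values: {sorted(unknown)}")
        if df.duplicated(subset=["probeset_id", "event_class"]).any():
            bad = df.loc[
                df.duplicated(subset=["probeset_id", "event_class"]), "probeset_id"
            ].unique()[:5]
            raise AnnotationError(f"duplicated (probeset_id, event_class): {list(bad)}")
        if self.has_intervals:
            iv = df.dropna(subset=["chrom", "start", "end"])
            if (iv["start"].astype(int) >= iv["end"].astype(int)).any():
                raise AnnotationError("interval with start >= end (coordinates are 0-based half-open)")
            bad_strand = set(iv.get("strand", pd.Series(dtype=str)).dropna()) - {"+", "-"}
            if bad_strand:
                raise AnnotationError(f"strand must be '+'/'-', got {sorted(bad_strand)}")

    @property
    def has_intervals(self) -> bool:
        return {"chrom", "start", "end"}.issubset(self.events.columns)

    def classes_for(self, probeset_id: str) -> list[str]:
        rows = self.events.loc[self.events["probeset_id"] == probeset_id]
        return list(rows["event_class"])


def read_event_annotation(path) -> EventAnnotation:
    df = _read_tsv(path)
    for col in ("start", "end"):
        if col in df.columns:
            df[col] = df[col].astype(int)
    return EventAnnotation(events=df.reset_index(drop=True))


def write_event_annotation(events: EventAnnotation, path) -> None:
    events.events.to_csv(path, sep="\t", index=False)


def write_event_bed(events: EventAnnotation, path) -> None:
    """Export interval-bearing event records as BED6 (0-based half-open)."""
    if not events.has_intervals:
        raise AnnotationError("event annotation carries no genomic intervals")
    iv = events.events.dropna(subset=["chrom", "start", "end"]).copy()
    bed = pd.DataFrame(
        {
            "chrom": iv["chrom"],
            "start": iv["start"].astype(int),
            "end": iv["end"].astype(int),
            "name": iv["probeset_id"] + "|" + iv["event_class"],
            "score": 0,
            "strand": iv.get("strand", "+"),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


# ---------------------------------------------------------------------------
# Ontology
# ---------------------------------------------------------------------------


@dataclass
class OntologyDag:
    """Acyclic ontology over ``is_a`` edges.

    The graph stores one directed edge per ``child is_a parent`` relation
    (child → parent), so a term's ancestors are the nodes reachable by
    following edges forward.
    """

    graph: nx.DiGraph
    names: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for child, parent in self.graph.edges():
            if parent not in self.graph:
                raise AnnotationError(f"is_a parent {parent!r} not defined")
        if not nx.is_directed_acyclic_graph(self.graph):
            cycle = nx.find_cycle(self.graph)
            raise AnnotationError(
                f"ontology contains a cycle through term {cycle[0][0]!r}"
            )

    @classmethod
    def from_edges(
        cls, terms: Mapping[str, str], is_a: Iterable[tuple[str, str]]
    ) -> "OntologyDag":
        g = nx.DiGraph()
        g.add_nodes_from(terms)
        g.add_edges_from(is_a)
        return cls(graph=g, names=dict(terms))

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.graph

    @property
    def terms(self) -> set:
        return set(self.graph.nodes)

    def ancestors(self, term_id: str) -> set:
        """All terms reachable upward from ``term_id`` via is_a (excl. itself)."""
        if term_id not in self.graph:
            raise KeyError(term_id)
        return set(nx.descendants(self.graph, term_id))

    def descendants(self, term_id: str) -> set:
        """All terms whose is_a closure contains ``term_id`` (excl. itself)."""
        if term_id not in self.graph:
            raise KeyError(term_id)
        return set(nx.ancestors(self.graph, term_id))


def read_obo_subset(path) -> OntologyDag:
    """Parse an OBO file keeping only [Term] stanzas and is_a edges.

    Obsolete terms are skipped; any cycle is a hard error naming one of its
    members.
    """
    multi = obonet.read_obo(str(path))
    g = nx.DiGraph()
    names: dict = {}
    for node, data in multi.nodes(data=True):
        g.add_node(node)
        names[node] = data.get("name", node)
    for child, parent, key in multi.edges(keys=True):
        if key == "is_a":
            g.add_edge(child, parent)
    return OntologyDag(graph=g, names=names)


# ---------------------------------------------------------------------------
# Gene -> term associations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneTermAssociations:
    """Directly annotated ontology terms per gene (pre-propagation)."""

    annotations: dict

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "annotations",
            {g: frozenset(ts) for g, ts in self.annotations.items()},
        )

    def genes(self) -> set:
        return set(self.annotations)

    def terms(self) -> set:
        out: set = set()
        for ts in self.annotations.values():
            out |= ts
        return out

    def __getitem__(self, gene_id: str) -> frozenset:
        return self.annotations.get(gene_id, frozenset())


def read_gene_associations(path, dag: OntologyDag | None = None) -> GeneTermAssociations:
    """Read a two-column (gene_id, term_id) TSV; validate terms against a DAG."""
    df = _read_tsv(path)
    if not {"gene_id", "term_id"}.issubset(df.columns):
        raise AnnotationError("association table needs gene_id and term_id columns")
    if dag is not None:
        unknown = set(df["term_id"]) - dag.terms
        if unknown:
            raise AnnotationError(f"association references unknown terms: {sorted(unknown)[:5]}")
    annotations: dict = {}
    for gene, sub in df.groupby("gene_id"):
        annotations[gene] = frozenset(sub["term_id"])
    return GeneTermAssociations(annotations=annotations)


def write_gene_associations(assoc: GeneTermAssociations, path) -> None:
    rows = [
        {"gene_id": g, "term_id": t}
        for g in sorted(assoc.annotations)
        for t in sorted(assoc.annotations[g])
    ]
    pd.DataFrame(rows, columns=["gene_id", "term_id"]).to_csv(path, sep="\t", index=False)
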