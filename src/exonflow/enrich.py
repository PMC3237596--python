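"""GO-term over-representation with descendant-redundancy pruning.

Annotations are first propagated up the is_a DAG (true-path rule), then
each term with at least one annotated universe gene is tested with a
one-sided Fisher's exact (hypergeometric) test for over-representation of
the input gene set against the universe.  Multiplicity is handled with
Storey q-values at a q <= 0.05 cutoff.

Significant terms whose signal is carried entirely by a single significant
descendant are redundant: when exactly one descendant of a term is
significant and removing that descendant's input genes from the input set
lifts the term's recomputed p above the realized significance cutoff, the
term is flagged as pruned (it stays in the output with its cause).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneTermAssociations, OntologyDag
from .diffexp import storey_qvalues

__all__ = [
    "propagate_annotations",
    "fisher_enrichment",
    "prune_descendant_driven",
    "DEFAULT_ENRICH_Q",
]

DEFAULT_ENRICH_Q = 0.05


def propagate_annotations(
    assoc: GeneTermAssociations, dag: OntologyDag
) -> GeneTermAssociations:
    """Annotate every gene to all ancestors of its direct terms (idempotent)."""
    out: dict = {}
    cache: dict = {}
    for gene, terms in assoc.annotations.items():
        full: set = set()
        for term in terms:
            if term not in dag:
                raise KeyError(f"term {term!r} absent from the ontology")
            if term not in cache:
                cache[term] = dag.ancestors(term) | {term}
            full |= cache[term]
        out[gene] = full
    return GeneTermAssociations(annotations=out)


def _fisher_p(k: int, K: int, n: int, N: int) -> float:
    """One-sided (greater) hypergeometric tail P(X >= k)."""
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def fisher_enrichment(
    input_genes: Iterable[str],
    universe: Iterable[str],
    assoc: GeneTermAssociations,
    dag: OntologyDag,
    q_cutoff: float = DEFAULT_ENRICH_Q,
) -> pd.DataFrame:
    """Per-term over-representation of ``input_genes`` within ``universe``.

    ``assoc`` must already be propagated.  Returns one row per term with
    K >= 1 universe genes: term_id, name, k, K, n, N, p, q, significant,
    pruned, pruned_by — sorted by p.
    """
    input_set = set(input_genes)
    universe_set = set(universe)
    outside = input_set - universe_set
    if outside:
        raise ValueError(f"input genes outside the universe: {sorted(outside)[:5]}")
    n = len(input_set)
    N = len(universe_set)
    term_universe: dict = {}
    for gene in universe_set:
        for term in assoc[gene]:
            term_universe.setdefault(term, set()).add(gene)
    rows = []
    for term, genes in sorted(term_universe.items()):
        K = len(genes)
        k = len(genes & input_set)
        rows.append(
            {
                "term_id": term,
                "name": dag.names.get(term, term),
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p": _fisher_p(k, K, n, N),
            }
        )
    result = pd.DataFrame(
        rows, columns=["term_id", "name", "k", "K", "n", "N", "p"]
    )
    if len(result):
        result["q"] = storey_qvalues(result["p"].to_numpy()).qvalues
    else:
        result["q"] = pd.Series(dtype=float)
    result["significant"] = result["q"] <= q_cutoff
    result["pruned"] = False
    result["pruned_by"] = ""
    return result.sort_values("p", kind="stable").reset_index(drop=True)


def prune_descendant_driven(
    results: pd.DataFrame,
    input_genes: Iterable[str],
    universe: Iterable[str],
    assoc: GeneTermAssociations,
    dag: OntologyDag,
) -> pd.DataFrame:
    """Flag significant terms driven solely by one significant descendant.

    A significant term T is pruned iff exactly one of its descendants is
    significant AND recomputing T's Fisher p after removing the input
    genes annotated to that descendant exceeds the realized p cutoff (the
    largest nominal p among originally significant terms).  Pruned terms
    stay in the table with ``pruned`` set and the descendant recorded.
    """
    out = results.copy()
    sig = out.loc[out["significant"]]
    if not len(sig):
        return out
    p_cutoff = float(sig["p"].max())
    sig_terms = set(sig["term_id"])
    input_set = set(input_genes)
    universe_set = set(universe)
    N = len(universe_set)

    genes_of_term: dict = {}
    for gene in universe_set:
        for term in assoc[gene]:
            genes_of_term.setdefault(term, set()).add(gene)

    for idx, row in sig.iterrows():
        term = row["term_id"]
        sig_desc = dag.descendants(term) & sig_terms
        if len(sig_desc) != 1:
            continue
        desc = next(iter(sig_desc))
        removed = genes_of_term.get(desc, set()) & input_set
        reduced_input = input_set - removed
        n2 = len(reduced_input)
        k2 = len(genes_of_term.get(term, set()) & reduced_input)
        p2 = _fisher_p(k2, int(row["K"]), n2, N)
        if p2 > p_cutoff:
            out.loc[idx, "pruned"] = True
            out.loc[idx, "pruned_by"] = desc
    return out
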