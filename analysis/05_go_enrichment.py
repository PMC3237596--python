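#!/usr/bin/env python
"""GO over-representation of an up-regulated gene set, with pruning.

Builds a small synthetic ontology and annotation universe in which one
functional module (a leaf term) is enriched among up-regulated genes,
then runs the Fisher / q <= 0.05 analysis and the descendant-redundancy
pruning: ancestors that are significant only because of that single leaf
are flagged.  Writes the term table under results/analysis/05_enrich/.
"""

import argparse
from pathlib import Path

import numpy as np

from exonflow.annotation import GeneTermAssociations, OntologyDag
from exonflow.enrich import fisher_enrichment, propagate_annotations, prune_descendant_driven

OUT = Path("results/analysis/05_enrich")


def build_universe(seed: int):
    rng = np.random.default_rng(seed)
    terms = {
        "T:bio": "biological process",
        "T:metab": "metabolic process",
        "T:lipid": "lipid metabolic process",
        "T:sterol": "sterol biosynthetic process",
        "T:signal": "signal transduction",
        "T:kinase": "protein phosphorylation",
    }
    edges = [
        ("T:metab", "T:bio"),
        ("T:lipid", "T:metab"),
        ("T:sterol", "T:lipid"),
        ("T:signal", "T:bio"),
        ("T:kinase", "T:signal"),
    ]
    dag = OntologyDag.from_edges(terms, edges)
    leaves = ["T:sterol", "T:lipid", "T:kinase", "T:signal", "T:metab"]
    gene_terms = {
        f"gene{i:03d}": {leaves[int(rng.integers(len(leaves)))]} for i in range(300)
    }
    assoc = propagate_annotations(GeneTermAssociations(annotations=gene_terms), dag)
    # up-regulated set: enriched for the sterol-biosynthesis module, the
    # classic androgen-response signature in LNCaP cells
    sterol_genes = [g for g, ts in assoc.annotations.items() if "T:sterol" in ts]
    other_genes = [g for g, ts in assoc.annotations.items() if "T:sterol" not in ts]
    rng.shuffle(sterol_genes)
    rng.shuffle(other_genes)
    up = set(sterol_genes[:20]) | set(other_genes[:15])
    return dag, assoc, up


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    dag, assoc, up = build_universe(args.seed)
    universe = assoc.genes()
    res = fisher_enrichment(up, universe, assoc, dag)
    res = prune_descendant_driven(res, up, universe, assoc, dag)
    OUT.mkdir(parents=True, exist_ok=True)
    res.to_csv(OUT / "enrichment.tsv", sep="\t", index=False)

    print(f"{len(up)} up-regulated genes vs {len(universe)} universe genes")
    cols = ["term_id", "name", "k", "K", "p", "q", "significant", "pruned", "pruned_by"]
    print(res[cols].to_string(index=False))
    kept = res.loc[res["significant"] & ~res["pruned"], "term_id"]
    print(f"significant after pruning: {', '.join(kept)}")
    print(f"outputs -> {OUT}")


if __name__ == "__main__":
    main()
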