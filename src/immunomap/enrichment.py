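"""Hypergeometric over-representation of core-gene sets in annotation terms.

Annotation terms are user-supplied plain gene sets (two-column TSV:
term, gene) over an explicit background universe; p-values are
upper-tail hypergeometric probabilities, BH-FDR corrected within each
module.
"""

from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .associations import bh_fdr

logger = logging.getLogger("immunomap.enrichment")


def read_annotations(path) -> dict[str, set]:
    """Read a two-column TSV (term, gene) into term -> gene-set."""
    df = pd.read_csv(Path(path), sep="\t", header=None, names=["term", "gene"])
    return {term: set(grp["gene"]) for term, grp in df.groupby("term")}


def hypergeometric_test(module_genes, term_genes, universe) -> float:
    """Upper-tail probability of at least the observed overlap between a
    module and a term under sampling without replacement from the universe."""
    universe = set(universe)
    if not universe:
        raise ValueError("universe must be non-empty")
    module_genes = set(module_genes)
    term_genes = set(term_genes)
    if not module_genes <= universe:
        raise ValueError("module genes must be a subset of the universe")
    if not term_genes <= universe:
        raise ValueError("term genes must be a subset of the universe")
    N = len(universe)
    K = len(term_genes)
    n = len(module_genes)
    k = len(module_genes & term_genes)
    return float(hypergeom.sf(k - 1, N, K, n))


def enrich_modules(core_sets: dict, annotations: dict, universe,
                   fdr_alpha: float = 0.05) -> pd.DataFrame:
    """Test every (module, term) pair, BH-adjusting within each module.

    Genes outside the universe are dropped from modules and terms; a
    module that becomes empty after intersection is an error.
    """
    if not annotations:
        raise ValueError("annotations must be non-empty")
    universe = set(universe)
    rows = []
    for module, genes in core_sets.items():
        module_genes = set(genes) & universe
        if not module_genes:
            raise ValueError(f"module {module} is disjoint from the universe")
        for term, term_genes in annotations.items():
            tg = set(term_genes) & universe
            overlap = len(module_genes & tg)
            p = hypergeometric_test(module_genes, tg, universe)
            rows.append({"module": module, "term": term, "overlap": overlap,
                         "module_size": len(module_genes), "term_size": len(tg),
                         "p": p})
    result = pd.DataFrame(rows)
    result["p_adj"] = float("nan")
    for module in core_sets:
        mask = result["module"] == module
        result.loc[mask, "p_adj"] = bh_fdr(result.loc[mask, "p"].to_numpy())
    result["significant"] = result["p_adj"] < fdr_alpha
    logger.info("enrich_modules: %d significant term-module pairs",
                int(result["significant"].sum()))
    return result
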