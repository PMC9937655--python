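"""Hypergeometric over-representation analysis of a DE gene set.

For each annotation term with at least one gene in the universe, the
upper-tail hypergeometric probability P(X >= k) of drawing k or more term
genes in a DE set of size K from a universe of size N containing n term
genes, BH-adjusted across all tested terms.  An optional per-gene weight
hook is accepted for future length-bias correction but is unweighted by
default.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from pathlib import Path

import pandas as pd
from scipy.stats import hypergeom

from .detest import bh_adjust

__all__ = ["ora", "read_annotation_tsv"]


def read_annotation_tsv(path: str | Path) -> dict[str, set[str]]:
    """Read a term->gene map from a TSV with columns term_id, gene_id
    (an optional third term_name column is ignored here)."""
    table = pd.read_csv(path, sep="\t")
    cols = list(table.columns)
    return {
        term: set(group[cols[1]])
        for term, group in table.groupby(cols[0], sort=True)
    }


def ora(
    de_genes: Iterable[str],
    annotation: Mapping[str, Iterable[str]],
    universe: Iterable[str],
    q_max: float = 0.05,
    weights: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Over-representation of every term in a DE set.

    Returns one row per term with >= 1 universe gene: term, n (term size in
    universe), k (overlap with DE set), N, K, pvalue, qvalue, significant
    (qvalue < q_max).  Rows are sorted by (qvalue, pvalue, term), which is
    stable under permutation of the input.  ``weights`` is reserved for a
    future bias-corrected null and must currently be None.
    """
    if weights is not None:
        raise NotImplementedError("weighted over-representation is not implemented")
    universe = set(universe)
    de = set(de_genes)
    stray = de - universe
    if stray:
        raise ValueError(f"DE genes absent from universe: {sorted(stray)[:10]}")
    N, K = len(universe), len(de)
    rows = []
    for term in sorted(annotation):
        term_genes = set(annotation[term]) & universe
        n = len(term_genes)
        if n == 0:
            continue
        k = len(term_genes & de)
        pvalue = float(hypergeom.sf(k - 1, N, n, K))
        rows.append({"term": term, "n": n, "k": k, "N": N, "K": K, "pvalue": pvalue})
    result = pd.DataFrame(rows, columns=["term", "n", "k", "N", "K", "pvalue"])
    result["qvalue"] = bh_adjust(result["pvalue"]) if len(result) else []
    result["significant"] = result["qvalue"] < q_max
    return result.sort_values(
        ["qvalue", "pvalue", "term"], kind="mergesort"
    ).reset_index(drop=True)
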