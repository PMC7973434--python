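"""Over-representation analysis and disease-slim mapping.

Enrichment of an interaction gene set against an annotation collection uses
the one-sided hypergeometric tail P(X >= k) within a stated background
universe (by default the post-filter screen library), BH-corrected across
the terms of the collection; terms below the FDR threshold (default 0.1)
are flagged enriched.  Disease mapping intersects the gene set with each
disease of a slim ontology; one gene may map to several diseases.
"""

from __future__ import annotations

from collections.abc import Iterable

import pandas as pd
from scipy import stats

from .differential_fitness import adjust_bh
from .screen_io import GeneSet

ENRICHMENT_COLUMNS = [
    "term_id", "term_name", "k", "K", "n", "N", "p", "q", "enriched", "genes",
]
DISEASE_COLUMNS = ["disease_id", "disease_name", "count", "genes"]


def enrich(
    query_genes: Iterable[str],
    sets: dict[str, GeneSet],
    background: Iterable[str],
    q_threshold: float = 0.1,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query_genes`` in each term.

    Gene sets and the query are intersected with the background first;
    terms empty within the background are skipped.  Rows are sorted by
    p-value.
    """
    background = set(background)
    query = set(query_genes) & background
    if not background or not set(query_genes):
        raise ValueError("query and background must be non-empty")
    N, n = len(background), len(query)
    rows = []
    for gs in sets.values():
        term_genes = gs.genes & background
        K = len(term_genes)
        if K == 0:
            continue
        overlap = sorted(term_genes & query)
        k = len(overlap)
        # one-sided upper tail P(X >= k); k = 0 gives exactly 1
        p = float(stats.hypergeom.sf(k - 1, N, K, n))
        rows.append((gs.term_id, gs.term_name, k, K, n, N, min(p, 1.0), overlap))
    table = pd.DataFrame(
        rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p", "genes"]
    )
    if table.empty:
        table["q"] = []
        table["enriched"] = []
        return table[ENRICHMENT_COLUMNS]
    table["q"] = adjust_bh(table["p"].values)
    table["enriched"] = table["q"] < q_threshold
    table = table.sort_values(["p", "term_id"], kind="mergesort").reset_index(drop=True)
    return table[ENRICHMENT_COLUMNS]


def map_diseases(query_genes: Iterable[str], slim: dict[str, GeneSet]) -> pd.DataFrame:
    """Intersect a gene set with each disease of the slim ontology.

    Diseases with an empty intersection are omitted; genes may appear under
    several diseases.
    """
    query = set(query_genes)
    rows = []
    for gs in slim.values():
        overlap = sorted(gs.genes & query)
        if overlap:
            rows.append((gs.term_id, gs.term_name, len(overlap), overlap))
    table = pd.DataFrame(rows, columns=DISEASE_COLUMNS)
    return table.sort_values(
        ["count", "disease_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True) if not table.empty else table
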