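"""Gene-set over-representation by one-sided Fisher's exact test.

An open, GMT-driven stand-in for proprietary knowledge-base pathway tools:
for each gene set the 2x2 table (overlap k, query-only n-k, set-only K-k,
rest N-n-K+k) is scored with the one-sided (enrichment) hypergeometric
tail, reported both as p and as the -log10(p) score whose conventional
significance threshold 1.3 corresponds to p <= 0.05.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from lncnet.diffexp import benjamini_hochberg
from lncnet.io import GeneSets

logger = logging.getLogger("lncnet.enrichment")

ENRICH_COLUMNS = ["set_name", "k", "K", "n", "N", "p_value", "score", "fdr", "overlap_genes"]


def fisher_enrich(query, gene_sets: GeneSets, background) -> pd.DataFrame:
    """One-sided Fisher's exact over-representation of ``query`` in each set.

    Symbols are case-folded before matching; query genes absent from the
    background are dropped with a warning and sets are intersected with the
    background.  Results are sorted by p (ties by set name), with a BH-FDR
    column across the tested sets.
    """
    background = list(dict.fromkeys(g.casefold() for g in background))
    if not background:
        raise ValueError("empty background")
    bg = set(background)
    query_cf = list(dict.fromkeys(g.casefold() for g in query))
    dropped = [g for g in query_cf if g not in bg]
    if dropped:
        logger.warning("%d query gene(s) absent from background, dropped", len(dropped))
    query_set = {g for g in query_cf if g in bg}

    N = len(bg)
    n = len(query_set)
    rows = []
    for name in gene_sets.names():
        members = {g.casefold() for g in gene_sets[name]} & bg
        K = len(members)
        overlap = sorted(members & query_set)
        k = len(overlap)
        # one-sided enrichment tail P(X >= k); k = 0 gives p = 1 exactly
        p = float(hypergeom.sf(k - 1, N, K, n))
        p = min(max(p, np.nextafter(0, 1)), 1.0)
        rows.append(
            {
                "set_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_value": p,
                "score": float(-np.log10(p)),
                "overlap_genes": ",".join(overlap),
            }
        )
    df = pd.DataFrame(rows, columns=[c for c in ENRICH_COLUMNS if c != "fdr"])
    if len(df):
        df["fdr"] = benjamini_hochberg(df["p_value"].to_numpy())
        df = df.sort_values(["p_value", "set_name"], kind="mergesort").reset_index(drop=True)
    else:
        df["fdr"] = []
    return df[ENRICH_COLUMNS]


def lncrna_pathway_projection(
    network,
    enrich_table: pd.DataFrame,
    score_threshold: float = 1.3,
    symbol_of: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Project enriched sets back onto lncRNAs through the CNC network.

    For every enriched set (score >= ``score_threshold``) and every
    contributing mRNA, list the lncRNA partners correlated with it in the
    network: one row per (set, mRNA), with the partner lncRNAs
    comma-joined.  ``symbol_of`` maps mRNA feature ids to the symbols used
    in the enrichment (defaults to identity).
    """
    cols = ["set_name", "p_value", "score", "mRNA", "lncRNAs"]
    if network.n_edges == 0 or enrich_table.empty:
        return pd.DataFrame(columns=cols)
    symbol_of = symbol_of or {}
    partners: dict[str, list[str]] = {}
    for r in network.edges.itertuples(index=False):
        partners.setdefault(r.mRNA, []).append(r.lncRNA)
    # symbol (case-folded) -> mRNA node ids
    by_symbol: dict[str, list[str]] = {}
    for mrna in partners:
        by_symbol.setdefault(symbol_of.get(mrna, mrna).casefold(), []).append(mrna)

    rows = []
    hits = enrich_table[enrich_table["score"] >= score_threshold]
    for r in hits.itertuples(index=False):
        genes = r.overlap_genes.split(",") if r.overlap_genes else []
        for g in genes:
            for mrna in by_symbol.get(g.casefold(), []):
                rows.append(
                    {
                        "set_name": r.set_name,
                        "p_value": r.p_value,
                        "score": r.score,
                        "mRNA": mrna,
                        "lncRNAs": ",".join(sorted(partners[mrna])),
                    }
                )
    return pd.DataFrame(rows, columns=cols)
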