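"""Coding/non-coding (CNC) co-expression network construction.

The network links top-ranked dysregulated lncRNAs to dysregulated mRNAs by
Pearson correlation computed across all samples pooled (both groups), the
standard CNC construction for a single correlation per pair.  Retained
edges satisfy |PCC| > 0.9, p < 0.05 and BH-FDR < 1 by default, the FDR
family being all candidate pairs in one batch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from lncnet.diffexp import benjamini_hochberg
from lncnet.io import EDGE_COLUMNS, ExpressionMatrix

logger = logging.getLogger("lncnet.cnc")


def select_top_lncrnas(de_table: pd.DataFrame, k: int = 50, p_cut: float = 0.01) -> list[str]:
    """Top-k dysregulated lncRNAs by absolute fold change.

    Among entries with p < ``p_cut``, rank by |fold change| descending and
    take ``min(k, available)``.  Ties break deterministically: smaller p
    first, then lexicographic feature id.
    """
    eligible = de_table[de_table["p_value"] < p_cut].copy()
    if eligible.empty:
        logger.warning("no lncRNAs pass p < %g; returning empty list", p_cut)
        return []
    eligible["abs_fc"] = eligible["fold_change"].abs()
    eligible = eligible.sort_values(
        ["abs_fc", "p_value", "feature_id"], ascending=[False, True, True], kind="mergesort"
    )
    return list(eligible["feature_id"].head(k))


def correlation_test(x, y) -> tuple[float, float]:
    """Pearson correlation with its two-sided p-value.

    p comes from t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom;
    |r| = 1 gives p = 0.  Requires n >= 3 paired finite observations and
    non-constant inputs.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need n >= 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if x.std() == 0.0 or y.std() == 0.0:
        raise ValueError("undefined correlation: zero variance")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    n = len(x)
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    p = 2.0 * stats.t.sf(abs(t), n - 2)
    return r, float(p)


@dataclass
class CncNetwork:
    """A bipartite lncRNA-mRNA co-expression network.

    ``edges`` has columns lncRNA, mRNA, pcc, p_value, fdr, sign; the node
    lists are exactly the endpoints of the retained edges.  ``stage_counts``
    records how many candidate pairs survived each threshold for audit.
    """

    edges: pd.DataFrame
    lnc_nodes: list[str]
    mrna_nodes: list[str]
    thresholds: dict = field(default_factory=dict)
    n_candidates: int = 0
    stage_counts: dict = field(default_factory=dict)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def to_networkx(self):
        """The network as a networkx bipartite graph (lncRNAs in part 0)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.lnc_nodes, bipartite=0, kind="lncRNA")
        g.add_nodes_from(self.mrna_nodes, bipartite=1, kind="mRNA")
        for r in self.edges.itertuples(index=False):
            g.add_edge(r.lncRNA, r.mRNA, pcc=r.pcc, p_value=r.p_value,
                       fdr=r.fdr, sign=r.sign)
        return g

    def summary(self) -> dict:
        return {
            "n_lnc_nodes": len(self.lnc_nodes),
            "n_mrna_nodes": len(self.mrna_nodes),
            "n_edges": self.n_edges,
            "n_candidates": self.n_candidates,
            **{f"pass_{k}": v for k, v in self.stage_counts.items()},
            **self.thresholds,
        }


def build_cnc(
    matrix: ExpressionMatrix,
    top_lncs,
    dysregulated_mrnas,
    pcc_threshold: float = 0.9,
    p_threshold: float = 0.05,
    fdr_threshold: float = 1.0,
    fdr_family: str = "global",
) -> CncNetwork:
    """Build the CNC network over every (lncRNA, mRNA) candidate pair.

    Correlation is computed across all samples pooled.  BH-FDR is computed
    over all candidate pairs in one batch (``fdr_family="global"``) or
    within each lncRNA's pair family (``"per_lncRNA"``).  Candidate
    features with zero variance have no defined correlation and are dropped
    with a warning.
    """
    top_lncs = [f for f in top_lncs if f not in set(dysregulated_mrnas)]
    thresholds = {
        "pcc_threshold": pcc_threshold,
        "p_threshold": p_threshold,
        "fdr_threshold": fdr_threshold,
        "fdr_family": fdr_family,
    }
    empty = pd.DataFrame(columns=EDGE_COLUMNS)
    if not top_lncs or len(dysregulated_mrnas) == 0:
        return CncNetwork(empty, [], [], thresholds, 0, {})

    X = matrix.values.loc[top_lncs].to_numpy(dtype=float)
    Y = matrix.values.loc[list(dysregulated_mrnas)].to_numpy(dtype=float)
    n = X.shape[1]
    if n < 3:
        raise ValueError("need n >= 3 samples for correlation")

    def standardize(M, ids):
        sd = M.std(axis=1, ddof=1)
        keep = sd > 0
        dropped = [i for i, k in zip(ids, keep) if not k]
        if dropped:
            logger.warning("dropped %d zero-variance feature(s) from CNC candidates",
                           len(dropped))
        Z = (M[keep] - M[keep].mean(axis=1, keepdims=True)) / sd[keep][:, None]
        return Z, [i for i, k in zip(ids, keep) if k]

    Xz, lnc_ids = standardize(X, list(top_lncs))
    Yz, mrna_ids = standardize(Y, list(dysregulated_mrnas))
    if not lnc_ids or not mrna_ids:
        return CncNetwork(empty, [], [], thresholds, 0, {})

    R = np.clip(Xz @ Yz.T / (n - 1), -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        T = R * np.sqrt(n - 2) / np.sqrt(1.0 - R * R)
    P = np.where(np.abs(R) == 1.0, 0.0, 2.0 * stats.t.sf(np.abs(T), n - 2))

    pairs = pd.DataFrame(
        {
            "lncRNA": np.repeat(lnc_ids, len(mrna_ids)),
            "mRNA": np.tile(mrna_ids, len(lnc_ids)),
            "pcc": R.ravel(),
            "p_value": P.ravel(),
        }
    )
    if fdr_family == "global":
        pairs["fdr"] = benjamini_hochberg(pairs["p_value"].to_numpy())
    elif fdr_family == "per_lncRNA":
        pairs["fdr"] = pairs.groupby("lncRNA")["p_value"].transform(
            lambda s: benjamini_hochberg(s.to_numpy())
        )
    else:
        raise ValueError(f"unknown fdr_family {fdr_family!r}")

    pass_pcc = pairs["pcc"].abs() > pcc_threshold
    pass_p = pairs["p_value"] < p_threshold
    pass_fdr = pairs["fdr"] < fdr_threshold
    stage_counts = {
        "pcc": int(pass_pcc.sum()),
        "p": int((pass_pcc & pass_p).sum()),
        "fdr": int((pass_pcc & pass_p & pass_fdr).sum()),
    }
    edges = pairs[pass_pcc & pass_p & pass_fdr].copy()
    edges["sign"] = np.where(edges["pcc"] > 0, "positive", "negative")
    edges = edges.sort_values(["lncRNA", "mRNA"], kind="mergesort").reset_index(drop=True)

    lnc_nodes = sorted(edges["lncRNA"].unique())
    mrna_nodes = sorted(edges["mRNA"].unique())
    logger.info(
        "CNC: %d candidate pairs -> %d edges (%d lncRNA, %d mRNA nodes)",
        len(pairs), len(edges), len(lnc_nodes), len(mrna_nodes),
    )
    return CncNetwork(
        edges[EDGE_COLUMNS], lnc_nodes, mrna_nodes, thresholds, len(pairs), stage_counts
    )
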