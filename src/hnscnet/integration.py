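"""Cross-layer integration: DEG direction vs miRNA-targeting pressure,
and generic gene-set over-representation.

The targeting contrast asks whether, among genes moving in one direction
in tumors, the number of targeting miRNAs from the opposite class differs
in distribution from the same class — a two-sample Kolmogorov-Smirnov
comparison of per-gene in-degree counts.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .bipartite import BipartiteNet


@dataclass
class IntegrationResult:
    direction: str  # which DEG direction the contrast conditions on
    counts: pd.DataFrame  # per-gene: direction, n_down_mirnas, n_up_mirnas
    ks_statistic: float
    ks_p: float


def ks_target_contrast(
    deg_directions: pd.Series,
    up_net: BipartiteNet,
    down_net: BipartiteNet,
    direction: str = "up",
    method: str = "asymp",
) -> IntegrationResult:
    """KS comparison of targeting counts for DEGs of one direction.

    For each gene differentially expressed in ``direction``, count the
    down-regulated and up-regulated miRNAs targeting it (0 if absent from
    a network); compare the two count distributions with the two-sample
    KS test. ``direction="down"`` runs the mirrored contrast.
    """
    if deg_directions.empty:
        raise ValueError("DEG set is empty")
    if direction not in ("up", "down"):
        raise ValueError("direction must be 'up' or 'down'")
    up_deg = up_net.in_degree
    down_deg = down_net.in_degree
    genes = sorted(deg_directions.index[deg_directions == direction])
    if not genes:
        raise ValueError(f"no DEGs with direction {direction!r}")
    counts = pd.DataFrame(
        {
            "direction": direction,
            "n_down_mirnas": [down_deg.get(g, 0) for g in genes],
            "n_up_mirnas": [up_deg.get(g, 0) for g in genes],
        },
        index=pd.Index(genes, name="gene"),
    )
    x = counts["n_down_mirnas"].to_numpy(dtype=float)
    y = counts["n_up_mirnas"].to_numpy(dtype=float)
    res = stats.ks_2samp(x, y, method=method)
    return IntegrationResult(
        direction=direction,
        counts=counts,
        ks_statistic=float(res.statistic),
        ks_p=float(res.pvalue),
    )


def hypergeom_enrich(query, gene_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of ``query`` in each
    gene set, BH-adjusted across the tested sets.

    Sets are intersected with the universe first; the query must be a
    subset of the universe. Columns: k (overlap), K (set size), n (query
    size), N (universe size), p, q.
    """
    universe = set(universe)
    query = set(query)
    if not query <= universe:
        raise ValueError("query must be a subset of the universe")
    n, big_n = len(query), len(universe)
    rows = []
    for name, members in gene_sets.items():
        members = set(members) & universe
        k = len(members & query)
        big_k = len(members)
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append({"gene_set": name, "k": k, "K": big_k, "n": n, "N": big_n, "p": p})
    out = pd.DataFrame(rows).set_index("gene_set")
    if len(out):
        out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    else:
        out["q"] = pd.Series(dtype=float)
    return out.sort_values(["p", "k"], ascending=[True, False], kind="stable")
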