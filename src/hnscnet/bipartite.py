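"""Bipartite miRNA->target networks and degree-based selection.

One network is built per miRNA direction class (up / down in tumor).
miRNAs are ranked by out-degree (genes targeted), genes by in-degree
(miRNAs targeting them); thresholds are always recomputed from the
network's own degree averages, never hard-coded.
"""
from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd


def normalize_mirna_id(name: str) -> str:
    """Case-insensitive matching with the organism prefix stripped, so
    'hsa-miR-99a', 'miR-99a' and 'mir-99a' all collide."""
    s = str(name).strip().lower()
    if s.startswith("hsa-"):
        s = s[4:]
    return s


@dataclass
class BipartiteNet:
    """Directed miRNA->gene targeting network for one direction class."""

    label: str  # "up" or "down"
    mirnas: set = field(default_factory=set)  # includes isolated DE miRNAs
    genes: set = field(default_factory=set)
    edges: set = field(default_factory=set)  # (mirna, gene)

    @property
    def out_degree(self) -> dict:
        deg = Counter(m for m, _ in self.edges)
        return {m: deg.get(m, 0) for m in self.mirnas}

    @property
    def in_degree(self) -> dict:
        deg = Counter(g for _, g in self.edges)
        return {g: deg.get(g, 0) for g in self.genes}

    @property
    def isolated_mirnas(self) -> set:
        return {m for m, d in self.out_degree.items() if d == 0}

    def validate(self) -> "BipartiteNet":
        for m, g in self.edges:
            if m not in self.mirnas or g not in self.genes:
                raise ValueError(f"edge ({m}, {g}) references unknown node")
        assert sum(self.out_degree.values()) == len(self.edges)
        assert sum(self.in_degree.values()) == len(self.edges)
        return self


@dataclass
class DegreeSelection:
    avg_out_degree: float
    avg_in_degree: float
    selected_mirnas: list  # out-degree strictly above average
    selected_genes: list  # in-degree >= multiplier * average ("most targeted")
    multiplier: float


def build_bipartite(de_mirnas: pd.Series, target_map: pd.DataFrame) -> tuple[BipartiteNet, BipartiteNet]:
    """Build the up- and down-class targeting networks.

    ``de_mirnas`` maps miRNA id -> "up"/"down"; ``target_map`` has columns
    (mirna_id, gene_id). miRNA ids are matched after normalization.
    DE miRNAs with no known target are retained with out-degree 0.
    """
    if target_map.empty:
        raise ValueError("target map is empty")
    directions = {normalize_mirna_id(m): d for m, d in de_mirnas.items()}
    nets = {"up": BipartiteNet("up"), "down": BipartiteNet("down")}
    for d in ("up", "down"):
        nets[d].mirnas = {m for m, dd in directions.items() if dd == d}
    pairs = {
        (normalize_mirna_id(m), g)
        for m, g in zip(target_map["mirna_id"], target_map["gene_id"])
    }
    for m, g in pairs:
        d = directions.get(m)
        if d is None:
            continue
        net = nets[d]
        net.genes.add(g)
        net.edges.add((m, g))
    return nets["up"].validate(), nets["down"].validate()


def rank_and_select(net: BipartiteNet, multiplier: float = 2.0) -> DegreeSelection:
    """Whole-network-average degree thresholds.

    miRNAs with out-degree strictly above the average out-degree are
    selected; genes with in-degree >= multiplier * average in-degree are
    flagged as most-targeted. Averages include degree-0 nodes.
    """
    if not net.mirnas and not net.genes:
        raise ValueError("network is empty")
    out_deg = net.out_degree
    in_deg = net.in_degree
    avg_out = sum(out_deg.values()) / len(out_deg) if out_deg else 0.0
    avg_in = sum(in_deg.values()) / len(in_deg) if in_deg else 0.0
    mirnas = sorted(
        (m for m, d in out_deg.items() if d > avg_out),
        key=lambda m: (-out_deg[m], m),
    )
    genes = sorted(
        (g for g, d in in_deg.items() if d >= multiplier * avg_in),
        key=lambda g: (-in_deg[g], g),
    )
    return DegreeSelection(avg_out, avg_in, mirnas, genes, multiplier)


def cross_class_filter(
    up_net: BipartiteNet,
    down_net: BipartiteNet,
    avg_up: float | None = None,
    avg_down: float | None = None,
    multiplier: float = 2.0,
) -> tuple[set, set]:
    """Partition target genes into class-specific sets.

    A gene is up-specific iff its in-degree in the up network is
    >= multiplier * avg_up AND its in-degree in the down network is
    < avg_down; down-specific by the mirrored rule. Genes targeted by one
    class only satisfy the other class's condition trivially (degree 0);
    genes strongly targeted by both classes are dropped. The outputs are
    disjoint by construction.
    """
    up_deg = up_net.in_degree
    down_deg = down_net.in_degree
    if avg_up is None:
        avg_up = sum(up_deg.values()) / len(up_deg) if up_deg else 0.0
    if avg_down is None:
        avg_down = sum(down_deg.values()) / len(down_deg) if down_deg else 0.0

    genes = set(up_deg) | set(down_deg)
    up_specific, down_specific = set(), set()
    for g in genes:
        du = up_deg.get(g, 0)
        dd = down_deg.get(g, 0)
        if du >= multiplier * avg_up and dd < avg_down:
            up_specific.add(g)
        elif du < avg_up and dd >= multiplier * avg_down:
            down_specific.add(g)
    return up_specific, down_specific


def degree_table(net: BipartiteNet) -> pd.DataFrame:
    """Long-format degree table for export (node, side, class, degree)."""
    rows = [
        {"node": m, "side": "mirna", "class": net.label, "degree": d}
        for m, d in sorted(net.out_degree.items())
    ] + [
        {"node": g, "side": "gene", "class": net.label, "degree": d}
        for g, d in sorted(net.in_degree.items())
    ]
    return pd.DataFrame(rows, columns=["node", "side", "class", "degree"])
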