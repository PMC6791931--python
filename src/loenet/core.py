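"""Lines-of-Evidence scoring: 1-hop extraction, breadth/depth, tiers.

The LOE method quantifies, for every gene in the genome, how much
independent evidence connects it to a curated "anchor" set of genes and
metabolites known to act in the system of interest.  Each omics layer is a
network; from each layer the 1-hop neighborhood of the anchors is
extracted, and per gene the method counts

* **depth per layer** -- the number of distinct anchor nodes the gene is
  connected to in that layer's 1-hop network,
* **breadth** -- the number of layers with depth > 0,
* **total depth** -- the sum of depths over layers, and
* **comethylation-discounted depth** -- total depth minus the comethylation
  depth (the methylation profiles rest on far fewer samples than the
  expression profiles, so comethylation connections are down-weighted in
  ranking to avoid upward bias from spurious correlations).

Genes pass the merge threshold ("high-LOE genes") when their breadth
reaches a cutoff (default 3) and, because a metabolite association is the
only direct phenotype readout, they carry at least one traditional or
rare-variant GWAS connection.  The merged LOE network is the union of the
1-hop edges among anchors and high-LOE genes, each edge keeping its source
layer(s).  High-LOE genes are then ranked into tiers:

* Tier 1: breadth >= 4, or breadth = 3 with discounted depth >= 5;
* Tier 2: breadth = 3 with discounted depth = 4;
* Tier 3: the rest (discounted depth <= 3).

Within tiers, genes sort by (breadth desc, discounted depth desc, gene id
asc); the id tie-break makes output deterministic.  Anchor genes are by
definition already known actors and are excluded from the candidate score
table (``include_anchors=True`` restores them for diagnostics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import AnchorSet, Network, canonical_pair

logger = logging.getLogger("loenet")

GWAS_LAYERS = ("gwas_traditional", "gwas_rare")


@dataclass
class OneHopNetwork:
    """1-hop anchor neighborhood of a single layer."""

    layer_name: str
    network: Network
    anchors: frozenset  # the full anchor node set, present in the layer or not

    @property
    def anchor_nodes(self) -> set:
        """Anchor nodes actually present (incident to an edge)."""
        return {n for n in self.network.nodes if n in self.anchors}

    @property
    def neighbors(self) -> set:
        """Non-anchor nodes adjacent to an anchor."""
        return {n for n in self.network.nodes if n not in self.anchors}


def extract_one_hop(net: Network, anchors: AnchorSet) -> OneHopNetwork:
    """Subnetwork of all edges incident to at least one anchor node.

    Anchor nodes with no edges are omitted; anchors absent from the layer
    are logged once with a count.
    """
    anchor_nodes = anchors.all_nodes
    out = Network(net.layer_name)
    for a, b, layer, weight, sign in net.iter_records():
        if a in anchor_nodes or b in anchor_nodes:
            out.add_edge(a, b, weight=weight, sign=sign, layer=layer)
    absent = len(anchor_nodes - set(net.graph.nodes))
    if absent:
        logger.info(
            "%s: %d anchor node(s) absent from the layer", net.layer_name, absent
        )
    return OneHopNetwork(net.layer_name, out, frozenset(anchor_nodes))


SCORE_COLUMNS = ("breadth", "depth_total", "depth_minus_cometh", "n_pos_coexpr", "n_neg_coexpr")


def compute_loe_scores(
    one_hops: list[OneHopNetwork],
    anchors: AnchorSet,
    universe,
    include_anchors: bool = False,
) -> pd.DataFrame:
    """Per-gene LOE score table from one 1-hop network per layer.

    Depth counts *distinct* anchor partners per layer.  Genes in
    ``universe`` that touch no layer score zero everywhere.  Coexpression
    connections are additionally tallied by correlation sign.  Returns a
    DataFrame indexed by gene id with one ``depth_<layer>`` column per
    layer plus breadth, depth_total, depth_minus_cometh and the signed
    coexpression counts.
    """
    layer_names = [oh.layer_name for oh in one_hops]
    if len(set(layer_names)) != len(layer_names):
        raise ValueError(f"duplicate layer names in {layer_names}")
    anchor_nodes = anchors.all_nodes

    partners: dict[str, dict[str, set]] = {name: {} for name in layer_names}
    pos_coexpr: dict[str, set] = {}
    neg_coexpr: dict[str, set] = {}
    genes: set = set()
    for oh in one_hops:
        net = oh.network
        for a, b, _layer, _weight, sign in net.iter_records():
            a_is_anchor, b_is_anchor = a in anchor_nodes, b in anchor_nodes
            for node, partner, node_anchor in (
                (a, b, a_is_anchor),
                (b, a, b_is_anchor),
            ):
                if node_anchor and not include_anchors:
                    continue
                if partner not in anchor_nodes:
                    continue
                if net.node_kind(node) != "gene":
                    continue
                partners[oh.layer_name].setdefault(node, set()).add(partner)
                genes.add(node)
                if oh.layer_name == "coexpression":
                    tally = pos_coexpr if sign == "+" else neg_coexpr
                    tally.setdefault(node, set()).add(partner)

    genes |= {g for g in universe if include_anchors or g not in anchor_nodes}
    index = pd.Index(sorted(genes), name="gene")
    table = pd.DataFrame(0, index=index, columns=[f"depth_{n}" for n in layer_names])
    for name in layer_names:
        col = f"depth_{name}"
        for gene, anchor_partners in partners[name].items():
            table.loc[gene, col] = len(anchor_partners)
    depth_cols = [f"depth_{n}" for n in layer_names]
    table["breadth"] = (table[depth_cols] > 0).sum(axis=1)
    table["depth_total"] = table[depth_cols].sum(axis=1)
    cometh = (
        table["depth_comethylation"]
        if "depth_comethylation" in table.columns
        else 0
    )
    table["depth_minus_cometh"] = table["depth_total"] - cometh
    table["n_pos_coexpr"] = [len(pos_coexpr.get(g, ())) for g in table.index]
    table["n_neg_coexpr"] = [len(neg_coexpr.get(g, ())) for g in table.index]
    return table


def threshold_and_merge(
    one_hops: list[OneHopNetwork],
    scores: pd.DataFrame,
    min_breadth: int = 3,
    require_gwas: bool = True,
) -> tuple[Network, list[str]]:
    """Threshold on breadth (+ GWAS requirement) and merge the 1-hop layers.

    A gene is high-LOE iff breadth >= ``min_breadth`` and, when
    ``require_gwas``, it has at least one traditional or rare-variant
    metabolite-GWAS connection.  The merged LOE network keeps the 1-hop
    edges whose endpoints are both anchors or high-LOE genes, each edge
    labeled with its source layer(s).
    """
    high = scores["breadth"] >= min_breadth
    if require_gwas:
        gwas_depth = sum(
            scores[f"depth_{layer}"]
            for layer in GWAS_LAYERS
            if f"depth_{layer}" in scores.columns
        )
        if np.isscalar(gwas_depth):  # no GWAS layer present at all
            gwas_depth = pd.Series(0, index=scores.index)
        high &= gwas_depth >= 1
    high_loe = sorted(scores.index[high])

    anchor_nodes = set().union(*(oh.anchors for oh in one_hops)) if one_hops else set()
    allowed = anchor_nodes | set(high_loe)
    merged = Network()
    for oh in sorted(one_hops, key=lambda o: o.layer_name):
        for a, b, layer, weight, sign in oh.network.iter_records():
            if a in allowed and b in allowed:
                merged.add_edge(a, b, weight=weight, sign=sign, layer=layer)
    return merged, high_loe


def assign_tier(breadth: int, depth_minus_cometh: int) -> int:
    if breadth >= 4 or (breadth == 3 and depth_minus_cometh >= 5):
        return 1
    if breadth == 3 and depth_minus_cometh == 4:
        return 2
    return 3


def rank_tiers(scores: pd.DataFrame, high_loe) -> pd.DataFrame:
    """Tier assignment and deterministic ordering for the high-LOE genes.

    Returns a DataFrame indexed by gene with columns ``tier``, ``breadth``
    and ``depth_minus_cometh``, sorted by (breadth desc, discounted depth
    desc, gene id asc).
    """
    missing = [g for g in high_loe if g not in scores.index]
    if missing:
        raise KeyError(f"gene {missing[0]!r} absent from the score table")
    sub = scores.loc[list(high_loe), ["breadth", "depth_minus_cometh"]].copy()
    sub["tier"] = [
        assign_tier(int(b), int(d))
        for b, d in zip(sub["breadth"], sub["depth_minus_cometh"])
    ]
    sub = sub.sort_values(
        by=["breadth", "depth_minus_cometh", "gene"],
        ascending=[False, False, True],
        kind="stable",
    )
    return sub[["tier", "breadth", "depth_minus_cometh"]]


def filter_known(tiers: pd.DataFrame, exclusion) -> tuple[pd.DataFrame, dict]:
    """Drop candidates with previously documented roles; report counts per tier.

    Order and tier assignments of the remaining candidates are preserved.
    """
    exclusion = set(exclusion)
    removed = tiers.index.isin(exclusion)
    counts = (
        tiers.loc[removed, "tier"].value_counts().sort_index().to_dict()
        if removed.any()
        else {}
    )
    return tiers.loc[~removed], {int(t): int(c) for t, c in counts.items()}


def merge_networks(nets: list[Network]) -> Network:
    """Edge union of arbitrary networks, preserving per-layer provenance.

    Conflicting node kinds (one id typed both gene and metabolite) raise.
    Union is commutative and associative up to canonical ordering.
    """
    out = Network()
    for net in nets:
        for node, kind in net.graph.nodes(data="kind"):
            out.add_node(node, kind=kind)
        for a, b, layer, weight, sign in net.iter_records():
            out.add_edge(a, b, weight=weight, sign=sign, layer=layer)
    return out
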