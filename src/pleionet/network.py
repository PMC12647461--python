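"""Trait-QTL genetic network built from the Inter-LD statistic, with hub detection.

Inter-LD quantifies LD between two clumped QTL regions relative to the LD
each region carries internally:

    Inter-LD = 1/2 * ( LD(Q1,Q2)/PmaxLD(Q1) + LD(Q1,Q2)/PmaxLD(Q2) )

where LD(Q1,Q2) is the mean r2 over all cross-region SNP pairs and
PmaxLD(Qk) the maximum pairwise r2 among members of region k (an
alternative reading — the maximum over variants of their mean r2 to
co-members — is available via ``pmax_mode="mean"``).  A single-SNP region
has no internal pair; its PmaxLD is defined as 1 (self-LD) and the edge is
flagged.

The network has trait nodes, QTL nodes, trait-QTL association edges, and
QTL-QTL edges wherever Inter-LD meets the threshold (default 0.4).  A hub
is a connected component of the QTL-QTL subgraph with at least two QTLs; a
central hub is a hub whose members associate with at least three distinct
traits.  Hubs are labeled hub-1, hub-2, ... by decreasing member count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .assoc_scan import ld_r2
from .containers import GenotypeMatrix, NetworkEdge, ParameterError, QTLRegion


def _pairwise_r2(geno: GenotypeMatrix, cols: np.ndarray) -> np.ndarray:
    """Region-scale r2 matrix via the scalar primitive (pairwise complete)."""
    m = len(cols)
    r2 = np.ones((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            try:
                r2[i, j] = r2[j, i] = ld_r2(geno, int(cols[i]), int(cols[j]))
            except ParameterError:
                r2[i, j] = r2[j, i] = np.nan
    return r2


@dataclass
class TraitNetwork:
    """Graph of trait and QTL nodes with Inter-LD-weighted QTL-QTL edges."""

    graph: nx.Graph
    qtls: dict[str, QTLRegion]
    min_inter_ld: float
    hubs: list[dict] = field(default_factory=list)

    @property
    def trait_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "trait"]

    @property
    def qtl_nodes(self) -> list[str]:
        return [n for n, d in self.graph.nodes(data=True) if d.get("kind") == "qtl"]

    def interld_subgraph(self) -> nx.Graph:
        edges = [(u, v) for u, v, d in self.graph.edges(data=True)
                 if d.get("edge_type") == "inter_ld"]
        g = nx.Graph()
        g.add_nodes_from(self.qtl_nodes)
        g.add_edges_from(edges)
        return g


def _pmax(r2: np.ndarray, mode: str) -> tuple[float, bool]:
    """Internal LD normalizer of one region; True flags the single-SNP fallback."""
    k = r2.shape[0]
    if k < 2:
        return 1.0, True
    off = r2[np.triu_indices(k, k=1)]
    off = off[np.isfinite(off)]
    if off.size == 0:
        return 1.0, True
    if mode == "max":
        return float(off.max()), False
    if mode == "mean":  # max over variants of mean r2 to co-members
        mean_to_others = (np.nansum(r2, axis=1) - np.diag(r2)) / (k - 1)
        return float(np.nanmax(mean_to_others)), False
    raise ParameterError(f"unknown pmax_mode {mode!r}")


def inter_ld(qtl1: QTLRegion, qtl2: QTLRegion, geno: GenotypeMatrix,
             pmax_mode: str = "max") -> NetworkEdge:
    """Inter-LD between two QTL regions from the genotype matrix."""
    if qtl1.n_members < 1 or qtl2.n_members < 1:
        raise ParameterError("regions must have at least one member SNP")
    cols = np.concatenate([qtl1.member_index, qtl2.member_index])
    r2 = _pairwise_r2(geno, cols)
    k1 = qtl1.n_members
    cross = r2[:k1, k1:]
    cross_ld = float(np.nanmean(cross))
    pmax1, flag1 = _pmax(r2[:k1, :k1], pmax_mode)
    pmax2, flag2 = _pmax(r2[k1:, k1:], pmax_mode)
    value = 0.5 * (cross_ld / pmax1 + cross_ld / pmax2)
    return NetworkEdge(qtl_a=qtl1.id, qtl_b=qtl2.id, cross_ld=cross_ld,
                       pmax_a=pmax1, pmax_b=pmax2, inter_ld=value,
                       single_snp_flag=flag1 or flag2)


def build_network(qtls_by_trait: dict[str, list[QTLRegion]], geno: GenotypeMatrix,
                  min_inter_ld: float = 0.4, pmax_mode: str = "max",
                  cross_chromosome: bool = True) -> TraitNetwork:
    """Assemble the trait-QTL network.

    Nodes are traits and QTL regions; trait-QTL edges record association,
    QTL-QTL edges carry Inter-LD >= ``min_inter_ld``.  Same-trait and
    cross-trait QTL pairs are both evaluated; setting
    ``cross_chromosome=False`` restricts Inter-LD edges to same-chromosome
    pairs.  Ordering is deterministic.
    """
    g = nx.Graph()
    qtls: dict[str, QTLRegion] = {}
    for trait in sorted(qtls_by_trait):
        g.add_node(trait, kind="trait")
        for q in qtls_by_trait[trait]:
            if q.id in qtls:
                raise ParameterError(f"duplicate QTL id {q.id}")
            qtls[q.id] = q
            g.add_node(q.id, kind="qtl", chrom=q.chrom, start=q.start, end=q.end,
                       trait=trait, lead_id=q.lead_id, lead_p=q.lead_p)
            g.add_edge(trait, q.id, edge_type="association", inter_ld=np.nan)

    ids = sorted(qtls)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if not cross_chromosome and qtls[a].chrom != qtls[b].chrom:
                continue
            edge = inter_ld(qtls[a], qtls[b], geno, pmax_mode=pmax_mode)
            if edge.inter_ld >= min_inter_ld:
                g.add_edge(a, b, edge_type="inter_ld", inter_ld=edge.inter_ld,
                           cross_ld=edge.cross_ld, pmax_a=edge.pmax_a,
                           pmax_b=edge.pmax_b, single_snp_flag=edge.single_snp_flag)
    net = TraitNetwork(graph=g, qtls=qtls, min_inter_ld=min_inter_ld)
    find_hubs(net)
    return net


def find_hubs(net: TraitNetwork, central_min_traits: int = 3) -> list[dict]:
    """Connected components of the Inter-LD subgraph with >= 2 QTLs.

    Each hub records its members, the distinct traits its members associate
    with, and whether it is a central hub (>= ``central_min_traits``
    traits).  Hubs are labeled hub-1, hub-2, ... by decreasing size (ties
    broken by smallest member id for determinism) and the labels written
    onto the graph nodes.
    """
    sub = net.interld_subgraph()
    comps = [sorted(c) for c in nx.connected_components(sub) if len(c) >= 2]
    comps.sort(key=lambda c: (-len(c), c[0]))
    hubs = []
    nx.set_node_attributes(net.graph, "", "hub")
    nx.set_node_attributes(net.graph, False, "central_hub")
    for k, members in enumerate(comps, start=1):
        traits = sorted({net.graph.nodes[m]["trait"] for m in members})
        central = len(traits) >= central_min_traits
        label = f"hub-{k}"
        for m in members:
            net.graph.nodes[m]["hub"] = label
            net.graph.nodes[m]["central_hub"] = central
        hubs.append({"id": label, "members": members, "traits": traits,
                     "central": central, "n_members": len(members)})
    net.hubs = hubs
    return hubs


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def _edge_table(net: TraitNetwork) -> pd.DataFrame:
    rows = []
    for u, v, d in sorted(net.graph.edges(data=True)):
        rows.append({"source": u, "target": v, "edge_type": d["edge_type"],
                     "inter_ld": d.get("inter_ld", np.nan)})
    return pd.DataFrame(rows, columns=["source", "target", "edge_type", "inter_ld"])


def _node_table(net: TraitNetwork) -> pd.DataFrame:
    rows = []
    for n, d in sorted(net.graph.nodes(data=True)):
        rows.append({"node": n, "kind": d.get("kind", ""),
                     "trait": d.get("trait", ""), "hub": d.get("hub", ""),
                     "central_hub": d.get("central_hub", False)})
    return pd.DataFrame(rows, columns=["node", "kind", "trait", "hub", "central_hub"])


def export_network(net: TraitNetwork, out_prefix: str,
                   formats: tuple[str, ...] = ("graphml", "sif", "tsv")) -> list[str]:
    """Write the network as GraphML, Cytoscape SIF and/or edge/node TSVs.

    Returns the list of files written.  GraphML round-trips through
    networkx; SIF lines are ``source<TAB>edge_type<TAB>target``.
    """
    written = []
    for fmt in formats:
        if fmt == "graphml":
            path = f"{out_prefix}.graphml"
            g = net.graph.copy()
            for _, d in g.nodes(data=True):
                for k, v in list(d.items()):
                    if isinstance(v, (np.floating, np.integer)):
                        d[k] = v.item()
            for _, _, d in g.edges(data=True):
                for k, v in list(d.items()):
                    if isinstance(v, (np.floating, np.integer)):
                        d[k] = v.item()
                    if isinstance(v, float) and np.isnan(v):
                        d[k] = 0.0
            nx.write_graphml(g, path)
            written.append(path)
        elif fmt == "sif":
            path = f"{out_prefix}.sif"
            with open(path, "w") as fh:
                for u, v, d in sorted(net.graph.edges(data=True)):
                    fh.write(f"{u}\t{d['edge_type']}\t{v}\n")
            written.append(path)
        elif fmt == "tsv":
            epath, npath = f"{out_prefix}_edges.tsv", f"{out_prefix}_nodes.tsv"
            _edge_table(net).to_csv(epath, sep="\t", index=False)
            _node_table(net).to_csv(npath, sep="\t", index=False)
            written.extend([epath, npath])
        else:
            raise ParameterError(f"unsupported export format {fmt!r}")
    return written
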