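"""Per-group heterogeneous signed networks and ATria centrality.

A heterogeneous co-occurrence network joins two omics layers: microbe
nodes (circles, colored by phylum, sized by group-mean relative
abundance) and metabolite nodes (squares, labeled by biochemical
pathway), connected by signed edges — correlations that passed the
admission threshold within the group's own samples. Green/positive
edges mark co-occurrence, red/negative edges mark avoidance.

Node importance is ranked with Ablatio Triadum (ATria): each node's
"pay" aggregates its signed influence over paths of length <= 2; the
highest-paid node is extracted, its triads are ablated (the node, its
incident edges, and every edge closing a triangle through it are
removed) and the process repeats, yielding a non-redundant ranking of
driver, villain and bridge nodes.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .correlate import CorrelationSet, LAYER_MM, LAYER_MT, LAYER_TT
from .stats import impute_pseudo_intensity, median_scale
from .tables import METABOLITE, MICROBE, FeatureTable, GroupDesign

logger = logging.getLogger(__name__)

_LAYER_KINDS = {
    LAYER_MM: (MICROBE, MICROBE),
    LAYER_TT: (METABOLITE, METABOLITE),
    LAYER_MT: (MICROBE, METABOLITE),
}


def _group_means(table: FeatureTable, design: GroupDesign | None, group: str | None):
    if table is None:
        return None
    vals = table.values
    if table.kind == METABOLITE:
        vals = median_scale(impute_pseudo_intensity(vals))
    if design is not None and group is not None:
        vals = vals[design.samples(group)]
    return vals.mean(axis=1)


def build_heteronet(
    correlations,
    group: str = "",
    microbe_table: FeatureTable | None = None,
    metabolite_table: FeatureTable | None = None,
    design: GroupDesign | None = None,
    p_threshold: float = 0.05,
    use_bh: bool = False,
) -> nx.Graph:
    """Assemble one group's signed heterogeneous network.

    ``correlations`` is a CorrelationSet (or iterable of them) computed
    on the group's samples only. Edges are admitted iff p <= threshold
    (BH-adjusted per layer when ``use_bh``); nodes appear only with at
    least one admitted edge. Node attributes carry type, phylum/pathway
    annotation, and group-mean abundance (microbes: mean relative
    abundance; metabolites: mean median-scaled intensity).
    """
    if isinstance(correlations, CorrelationSet):
        correlations = [correlations]
    admitted = pd.concat(
        [c.significant(p_threshold, use_bh=use_bh) for c in correlations],
        ignore_index=True,
    ) if correlations else pd.DataFrame()

    g = nx.Graph(group=group, p_threshold=p_threshold)
    if admitted.empty:
        warnings.warn(f"group {group!r}: no admitted edges; network is empty")
        return g

    means = {
        MICROBE: _group_means(microbe_table, design, group),
        METABOLITE: _group_means(metabolite_table, design, group),
    }
    annotations = {
        MICROBE: microbe_table.annotations if microbe_table is not None else None,
        METABOLITE: metabolite_table.annotations if metabolite_table is not None else None,
    }

    def _add_node(fid: str, kind: str) -> None:
        if g.has_node(fid):
            return
        ann = annotations[kind]
        mean = means[kind]
        g.add_node(
            fid,
            node_type=kind,
            phylum_or_pathway=str(ann.get(fid, "")) if ann is not None else "",
            mean_abundance=float(mean.get(fid, 0.0)) if mean is not None else 0.0,
            rank=0,
        )

    for rec in admitted.itertuples(index=False):
        kind_a, kind_b = _LAYER_KINDS[rec.layer]
        if rec.feature_a == rec.feature_b or g.has_edge(rec.feature_a, rec.feature_b):
            continue
        _add_node(rec.feature_a, kind_a)
        _add_node(rec.feature_b, kind_b)
        g.add_edge(
            rec.feature_a,
            rec.feature_b,
            weight=float(rec.rho),
            p_value=float(rec.p),
            layer=rec.layer,
            kegg_supported=False,
        )
    return g


# ---------------------------------------------------------------------------
# ATria centrality
# ---------------------------------------------------------------------------

@dataclass
class CentralityRanking:
    """ATria ranking: (node, pay at extraction, extraction round).

    Nodes extracted by pay come first (rounds 1, 2, ...); once every
    remaining node sits at its self-pay of 1, the residual nodes are
    appended in lexicographic order with ``round=None`` and are also
    listed separately in ``residual``.
    """

    entries: list = field(default_factory=list)  # (node, pay, round | None)
    residual: list = field(default_factory=list)

    @property
    def order(self) -> list:
        return [node for node, _, _ in self.entries]

    def rank_of(self, node) -> int:
        return self.order.index(node) + 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"rank": i + 1, "node": node, "pay": pay,
                 "extraction_round": (-1 if rnd is None else rnd)}
                for i, (node, pay, rnd) in enumerate(self.entries)
            ]
        )


def _pay_vector(nodes: list, w: np.ndarray) -> np.ndarray:
    """Pays under the <=2-path rule.

    P_ii = 1; for j != i, P_ij is the signed value of maximum magnitude
    among the direct edge w_ij and every 2-path w_ik * w_kj (absent
    terms contribute 0); pay_i = |sum_j P_ij|.
    """
    d = len(nodes)
    best = w.copy()
    for k in range(d):
        cand = np.outer(w[:, k], w[k, :])
        take = np.abs(cand) > np.abs(best)
        best = np.where(take, cand, best)
    np.fill_diagonal(best, 1.0)
    return np.abs(best.sum(axis=1))


def atria_rank(network: nx.Graph, tol: float = 1e-9) -> CentralityRanking:
    """Rank nodes by iterative pay extraction with triad ablation.

    Each round: compute pays, extract the arg-max pay node (ties broken
    by lexicographically smallest id), then ablate — delete the node,
    its incident edges, and every edge that closed a triangle with it.
    Extraction stops when every remaining node's pay equals its self-pay
    of 1; the residue is ranked last by the tie rule.
    """
    g = network.copy()
    entries: list = []
    round_no = 0
    while g.number_of_nodes():
        nodes = sorted(g.nodes())
        idx = {n: i for i, n in enumerate(nodes)}
        w = np.zeros((len(nodes), len(nodes)))
        for u, v, data in g.edges(data=True):
            w[idx[u], idx[v]] = w[idx[v], idx[u]] = float(data.get("weight", 0.0))
        pays = _pay_vector(nodes, w)
        if np.all(pays <= 1.0 + tol):
            break
        round_no += 1
        top_pay = pays.max()
        tied = [nodes[i] for i in range(len(nodes)) if pays[i] >= top_pay - tol]
        chosen = min(tied)
        entries.append((chosen, float(pays[idx[chosen]]), round_no))
        neighbors = list(g.neighbors(chosen))
        for a_i in range(len(neighbors)):
            for b_i in range(a_i + 1, len(neighbors)):
                if g.has_edge(neighbors[a_i], neighbors[b_i]):
                    g.remove_edge(neighbors[a_i], neighbors[b_i])
        g.remove_node(chosen)

    residual = sorted(g.nodes())
    nodes = residual
    idx = {n: i for i, n in enumerate(nodes)}
    w = np.zeros((len(nodes), len(nodes)))
    for u, v, data in g.edges(data=True):
        w[idx[u], idx[v]] = w[idx[v], idx[u]] = float(data.get("weight", 0.0))
    pays = _pay_vector(nodes, w) if nodes else np.array([])
    for n in residual:
        entries.append((n, float(pays[idx[n]]), None))
    return CentralityRanking(entries=entries, residual=residual)


def annotate_ranks(network: nx.Graph, ranking: CentralityRanking) -> nx.Graph:
    """Write 1-based ATria ranks onto the network's node attributes."""
    for i, node in enumerate(ranking.order):
        if network.has_node(node):
            network.nodes[node]["rank"] = i + 1
    return network


# ---------------------------------------------------------------------------
# network-specific metabolites
# ---------------------------------------------------------------------------

def network_specific_metabolites(
    networks: dict,
    metabolite_table: FeatureTable | None = None,
    design: GroupDesign | None = None,
) -> dict:
    """Metabolites participating in exactly one group's network.

    ``networks`` maps group label -> heterogeneous network. A metabolite
    is group-G-specific iff it has at least one admitted edge in G's
    network and appears in no other group's network. Each group's frame
    lists the specific metabolites with their per-group mean scaled
    intensities (when a table is given) so fold-change patterns can be
    inspected descriptively.
    """
    if len(networks) < 2:
        raise ValueError("need networks for at least 2 groups")
    members = {
        grp: {
            n for n, d in g.nodes(data=True) if d.get("node_type") == METABOLITE
        }
        for grp, g in networks.items()
    }
    group_means = None
    if metabolite_table is not None and design is not None:
        scaled = median_scale(impute_pseudo_intensity(metabolite_table.values))
        group_means = pd.DataFrame(
            {grp: scaled[design.samples(grp)].mean(axis=1) for grp in design.groups}
        )
    out = {}
    for grp, mets in members.items():
        others = set().union(*(m for g2, m in members.items() if g2 != grp))
        specific = sorted(mets - others)
        if group_means is not None:
            frame = group_means.loc[[m for m in specific if m in group_means.index]]
        else:
            frame = pd.DataFrame(index=specific)
        out[grp] = frame
    return out


# ---------------------------------------------------------------------------
# KEGG support annotation
# ---------------------------------------------------------------------------

def read_kegg_mapping(path) -> dict:
    """Read a feature -> KEGG pathway-id TSV into {feature: set(pathways)}.

    Malformed rows (fewer than two columns) are skipped with a counted
    warning.
    """
    mapping: dict[str, set] = {}
    skipped = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2 or not parts[0] or not parts[1]:
                skipped += 1
                continue
            mapping.setdefault(parts[0], set()).add(parts[1])
    if skipped:
        warnings.warn(f"KEGG mapping: skipped {skipped} malformed row(s)")
    return mapping


def kegg_support(network: nx.Graph, mapping: dict) -> nx.Graph:
    """Flag edges backed by a shared KEGG pathway.

    An edge is ``kegg_supported`` iff its correlation is positive and
    both endpoints share at least one pathway id in the mapping
    (database support is only claimed for co-occurrence, not
    avoidance). Features absent from the mapping are simply unsupported.
    """
    for u, v, data in network.edges(data=True):
        shared = set(mapping.get(u, ())) & set(mapping.get(v, ()))
        data["kegg_supported"] = bool(data.get("weight", 0.0) > 0 and shared)
    return network


# ---------------------------------------------------------------------------
# layout
# ---------------------------------------------------------------------------

def fruchterman_reingold(
    network: nx.Graph, seed: int = 0, iterations: int = 50
) -> dict:
    """Force-directed 2-D coordinates for presentation.

    Attraction acts only along positive-weight edges while every node
    pair repels, so positively correlated entities end up in close
    proximity and negative/absent correlations impose no pull.
    Deterministic for a given seed.
    """
    if network.number_of_nodes() == 0:
        return {}
    if network.number_of_nodes() == 1:
        return {next(iter(network.nodes())): np.zeros(2)}
    pos_graph = nx.Graph()
    pos_graph.add_nodes_from(network.nodes())
    pos_graph.add_weighted_edges_from(
        (u, v, d["weight"])
        for u, v, d in network.edges(data=True)
        if d.get("weight", 0.0) > 0
    )
    return nx.spring_layout(pos_graph, seed=seed, iterations=iterations, weight="weight")
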