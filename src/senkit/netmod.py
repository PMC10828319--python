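"""PPI-constrained signed co-expression graphs and dense-module detection.

Edges are Spearman rank correlations between the expression profiles of gene
pairs that interact in a reference protein-protein interaction (PPI)
network; only pairs with ``|rho|`` above a threshold (default 0.5) are kept,
with the sign recorded.  Densely connected regions of the resulting graph
are found with a re-implementation of the MCODE algorithm (k-core based
vertex weighting, seeded greedy expansion, haircut post-processing).  Signs
are ignored for module detection — modules are defined on the thresholded
topology — and signed edge counts are reported separately in the censuses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import rankdata


@dataclass
class GraphModule:
    nodes: frozenset
    score: float       # density of the module's induced subgraph
    rank: int


@dataclass
class PowerLawFit:
    gamma: float
    r_squared: float


def correlation_graph(expr: pd.DataFrame, ppi_edges: pd.DataFrame,
                      rho_min: float = 0.5,
                      gene_subset: Sequence[str] | None = None,
                      label: str | None = None) -> nx.Graph:
    """Signed Spearman co-expression graph restricted to PPI pairs.

    ``expr`` is genes x cells.  For every PPI pair with both genes in scope
    (and in ``gene_subset`` when given), Spearman's rho is computed with
    average ranks; edges with ``|rho| > rho_min`` are stored with attributes
    ``rho`` and ``sign``.  Constant genes have undefined rho; their pairs
    are skipped with a warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 cells")
    genes = set(expr.index)
    if gene_subset is not None:
        genes &= set(gene_subset)

    pairs = [(a, b) for a, b in ppi_edges.iloc[:, :2].itertuples(index=False)
             if a in genes and b in genes and a != b]
    G = nx.Graph(label=label)
    G.add_nodes_from(sorted({g for p in pairs for g in p}))
    if not pairs:
        return G

    used = sorted({g for p in pairs for g in p})
    mat = expr.loc[used].to_numpy(dtype=float)
    ranks = np.apply_along_axis(rankdata, 1, mat)
    sd = ranks.std(axis=1)
    constant = {g for g, s in zip(used, sd) if s == 0}
    if constant:
        warnings.warn(f"skipping pairs with constant genes: {sorted(constant)}")
    z = ranks - ranks.mean(axis=1, keepdims=True)
    norm = np.sqrt((z ** 2).sum(axis=1))
    idx = {g: i for i, g in enumerate(used)}

    seen = set()
    for a, b in pairs:
        key = (a, b) if a < b else (b, a)
        if key in seen or a in constant or b in constant:
            continue
        seen.add(key)
        i, j = idx[a], idx[b]
        rho = float(np.dot(z[i], z[j]) / (norm[i] * norm[j]))
        if abs(rho) > rho_min:
            G.add_edge(a, b, rho=rho, sign="+" if rho > 0 else "-")
    return G


# ----------------------------------------------------------------- MCODE

def _highest_kcore(H: nx.Graph) -> tuple[int, nx.Graph]:
    """The k-core of H with the largest k (and that k)."""
    core_num = nx.core_number(H)
    k = max(core_num.values())
    core = H.subgraph([v for v, c in core_num.items() if c >= k])
    return k, core


def mcode_vertex_weights(graph: nx.Graph) -> dict:
    """MCODE vertex weighting: k x density of the highest k-core of N[v]."""
    weights = {}
    for v in graph.nodes():
        nbrs = set(graph.neighbors(v)) | {v}
        if len(nbrs) < 2:
            weights[v] = 0.0
            continue
        H = graph.subgraph(nbrs)
        k, core = _highest_kcore(H)
        n = core.number_of_nodes()
        density = core.number_of_edges() / (n * (n - 1) / 2)
        weights[v] = float(k * density)
    return weights


def mcode_modules(graph: nx.Graph, vwp: float = 0.2, haircut: bool = True,
                  fluff: bool = False, fluff_density: float = 0.5,
                  min_core: int = 2) -> list[GraphModule]:
    """MCODE dense-module detection on the (unsigned) graph topology.

    Seeds at the highest-weight unvisited vertex and expands breadth-first,
    including neighbours whose weight is at least ``(1 - vwp)`` times the
    seed weight; visited vertices are never reused, so modules are disjoint.
    Post-processing: optional single-pass haircut (drop members with
    within-module degree < 2), optional fluff, and rejection of modules
    without a ``min_core``-core.  Modules are scored by the density of their
    induced subgraph and ranked by score.
    """
    if not (0 <= vwp <= 1):
        raise ValueError("vwp must be in [0, 1]")
    weights = mcode_vertex_weights(graph)
    order = sorted(graph.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    raw_modules = []
    for seed in order:
        if seed in visited:
            continue
        cutoff = (1.0 - vwp) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in graph.neighbors(u):
                    if w not in visited and weights[w] >= cutoff:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        raw_modules.append(members)

    modules = []
    for members in raw_modules:
        sub = graph.subgraph(members)
        if fluff:
            extra = set()
            for v in list(members):
                for w in graph.neighbors(v):
                    if w in members or w in extra:
                        continue
                    nbrs = set(graph.neighbors(w)) | {w}
                    H = graph.subgraph(nbrs)
                    n = H.number_of_nodes()
                    dens = (H.number_of_edges() / (n * (n - 1) / 2)
                            if n > 1 else 0.0)
                    if dens > fluff_density:
                        extra.add(w)
            members |= extra
            sub = graph.subgraph(members)
        if haircut:
            # haircut = 2-core of the module: iteratively drop members with
            # within-module degree < 2 (idempotent, may disconnect)
            sub = nx.k_core(sub, 2)
            members = set(sub.nodes())
        if len(members) < 2:
            continue
        # a haircut can split a module; each dense component stands alone
        for comp in nx.connected_components(sub):
            csub = sub.subgraph(comp)
            n = csub.number_of_nodes()
            if n < 2:
                continue
            if min_core and nx.k_core(csub, min_core).number_of_nodes() == 0:
                continue
            score = csub.number_of_edges() / (n * (n - 1) / 2)
            modules.append((frozenset(comp), score))
    modules.sort(key=lambda ms: (-ms[1], -len(ms[0]), sorted(map(str, ms[0]))))
    return [GraphModule(nodes=m, score=s, rank=i + 1)
            for i, (m, s) in enumerate(modules)]


# ----------------------------------------------------------- degree structure

def degree_powerlaw(graph: nx.Graph) -> PowerLawFit:
    """Log-log least-squares fit of the degree-frequency histogram.

    Replicates the network-analysis convention of fitting a straight line to
    log10(frequency) versus log10(degree) over nonzero-degree bins; gamma is
    the negated slope.  Requires at least 3 distinct positive degrees.
    """
    degrees = np.array([d for _, d in graph.degree() if d > 0])
    vals, freq = np.unique(degrees, return_counts=True)
    if len(vals) < 3:
        raise ValueError("need >= 3 distinct positive degrees")
    x, y = np.log10(vals), np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    return PowerLawFit(gamma=float(-slope), r_squared=float(r2))


def edge_census(graphs: Mapping[str, nx.Graph],
                module_map: Mapping[str, object] | None = None) -> pd.DataFrame:
    """Signed edge counts per graph label (and per module when given).

    Rows carry positive/negative edge counts and node counts; per-label
    deltas of positive and negative counts against the first label are
    appended as columns.
    """
    if module_map is not None:
        universe = set().union(*(g.nodes() for g in graphs.values()))
        unknown = set(module_map) - universe
        if unknown:
            raise ValueError(f"module_map references unknown nodes: "
                             f"{sorted(map(str, unknown))[:5]}")
    rows = []
    for label, G in graphs.items():
        groups = {"all": G.nodes()}
        if module_map is not None:
            mods = {}
            for node, mid in module_map.items():
                mods.setdefault(mid, []).append(node)
            for mid, nodes in sorted(mods.items(), key=lambda kv: str(kv[0])):
                groups[f"module_{mid}"] = nodes
        for gname, nodes in groups.items():
            sub = G.subgraph([n for n in nodes if n in G])
            pos = sum(1 for *_, d in sub.edges(data=True)
                      if d.get("sign", "+") == "+")
            neg = sub.number_of_edges() - pos
            rows.append({"label": label, "group": gname,
                         "nodes": sub.number_of_nodes(),
                         "positive_edges": pos, "negative_edges": neg})
    df = pd.DataFrame(rows)
    first = df["label"].iloc[0] if len(df) else None
    if first is not None:
        base = df[df["label"] == first].set_index("group")
        df["delta_positive"] = df.apply(
            lambda r: r["positive_edges"]
            - base.loc[r["group"], "positive_edges"], axis=1)
        df["delta_negative"] = df.apply(
            lambda r: r["negative_edges"]
            - base.loc[r["group"], "negative_edges"], axis=1)
    return df


def hub_genes(graph: nx.Graph, k: int = 10) -> list:
    """Top-k nodes by degree, ties broken lexicographically by gene id."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    return [v for v, _ in sorted(graph.degree(),
                                 key=lambda vd: (-vd[1], str(vd[0])))[:k]]


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [{"gene_a": a, "gene_b": b, "rho": d["rho"], "sign": d["sign"]}
            for a, b, d in graph.edges(data=True)]
    pd.DataFrame(rows, columns=["gene_a", "gene_b", "rho", "sign"]) \
        .to_csv(path, sep="\t", index=False)
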