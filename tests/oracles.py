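"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library's code paths (and networkx's core
routines): k-cores are found by enumerating vertex subsets with bitmasks,
so they are usable only on small graphs (<= ~12 nodes).
"""

from __future__ import annotations

import numpy as np


def adjacency_masks(nodes, edges):
    """Bitmask adjacency for subset enumeration."""
    idx = {v: i for i, v in enumerate(nodes)}
    adj = [0] * len(nodes)
    for a, b in edges:
        if a == b:
            continue
        adj[idx[a]] |= 1 << idx[b]
        adj[idx[b]] |= 1 << idx[a]
    return idx, adj


def highest_kcore_bruteforce(nodes, edges):
    """(k, node set) of the highest k-core by exhaustive subset enumeration.

    min-degree(S) is computed for every vertex subset S; the highest core
    order is the maximum over subsets, and the core is the union of all
    subsets attaining it (the union of subgraphs with min degree >= k has
    min degree >= k, and the k-core is the unique maximal one).
    """
    nodes = list(nodes)
    n = len(nodes)
    idx, adj = adjacency_masks(nodes, edges)
    best_k, best_union = 0, 0
    for S in range(1, 1 << n):
        if S & (S - 1) == 0:  # singleton: min degree 0
            continue
        mind = min(bin(adj[v] & S).count("1")
                   for v in range(n) if S >> v & 1)
        if mind > best_k:
            best_k, best_union = mind, S
        elif mind == best_k:
            best_union |= S
    if best_k == 0:
        return 0, set()
    members = {nodes[v] for v in range(n) if best_union >> v & 1}
    return best_k, members


def kcore_bruteforce(nodes, edges, k):
    """The k-core (union of all subsets with min degree >= k)."""
    nodes = list(nodes)
    n = len(nodes)
    idx, adj = adjacency_masks(nodes, edges)
    union = 0
    for S in range(1, 1 << n):
        if S & (S - 1) == 0:
            continue
        mind = min(bin(adj[v] & S).count("1")
                   for v in range(n) if S >> v & 1)
        if mind >= k:
            union |= S
    return {nodes[v] for v in range(n) if union >> v & 1}


def _density(nodes, edges, members):
    m = sum(1 for a, b in edges if a in members and b in members and a != b)
    n = len(members)
    return m / (n * (n - 1) / 2) if n > 1 else 0.0


def mcode_weights_bruteforce(nodes, edges):
    """MCODE vertex weights via the exhaustive k-core search."""
    nbrs = {v: {v} for v in nodes}
    for a, b in edges:
        if a != b:
            nbrs[a].add(b)
            nbrs[b].add(a)
    weights = {}
    for v in nodes:
        sub_nodes = nbrs[v]
        if len(sub_nodes) < 2:
            weights[v] = 0.0
            continue
        sub_edges = [(a, b) for a, b in edges
                     if a in sub_nodes and b in sub_nodes]
        k, core = highest_kcore_bruteforce(sub_nodes, sub_edges)
        weights[v] = k * _density(sub_nodes, sub_edges, core) if k else 0.0
    return weights


def mcode_modules_bruteforce(nodes, edges, vwp=0.2, min_core=2):
    """MCODE modules with haircut, built on the brute-force k-core."""
    nodes = sorted(nodes, key=str)
    nbrs = {v: set() for v in nodes}
    for a, b in edges:
        if a != b:
            nbrs[a].add(b)
            nbrs[b].add(a)
    weights = mcode_weights_bruteforce(nodes, edges)
    order = sorted(nodes, key=lambda v: (-weights[v], str(v)))
    visited = set()
    raw = []
    for seed in order:
        if seed in visited:
            continue
        cutoff = (1 - vwp) * weights[seed]
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt = []
            for u in frontier:
                for w in sorted(nbrs[u], key=str):
                    if w not in visited and weights[w] >= cutoff:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt
        raw.append(members)

    modules = []
    for members in raw:
        sub_edges = [(a, b) for a, b in edges
                     if a in members and b in members and a != b]
        members = kcore_bruteforce(members, sub_edges, 2)  # haircut
        if len(members) < 2:
            continue
        # connected components within the haircut set
        remaining = set(members)
        while remaining:
            comp = set()
            stack = [next(iter(remaining))]
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(nbrs[v] & remaining - comp)
            remaining -= comp
            if len(comp) < 2:
                continue
            comp_edges = [(a, b) for a, b in sub_edges
                          if a in comp and b in comp]
            if min_core and not kcore_bruteforce(comp, comp_edges, min_core):
                continue
            modules.append((frozenset(comp),
                            _density(comp, comp_edges, comp)))
    return modules


def ks_d_naive(y, cdf_func):
    """sup |ECDF - F| computed by direct looping over the support."""
    y = np.asarray(y)
    best = 0.0
    for x in range(int(y.max()) + 1):
        d = abs(np.mean(y <= x) - cdf_func(x))
        best = max(best, d)
    return best


def random_graph(rng, max_nodes=8):
    """A random simple graph (possibly disconnected) with <= max_nodes."""
    n = int(rng.integers(2, max_nodes + 1))
    p = float(rng.uniform(0.15, 0.85))
    nodes = [f"n{i}" for i in range(n)]
    edges = [(nodes[i], nodes[j])
             for i in range(n) for j in range(i + 1, n)
             if rng.random() < p]
    return nodes, edges
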