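"""Independent brute-force oracle for the autocorrelation kernels.

Everything here is recomputed from scratch: breadth-first search over plain
adjacency dicts (no networkx, no reuse of the package's distance code), and
explicit enumeration of every pair. Conventions match the package's documented
ones: unordered pairs counted once with the element earlier in stored order on
the origin side; depth 0 collects self-terms; metal-centered bond-bond uses
the super-bond with shell depth = line-graph distance to the nearest
metal-ligand edge.
"""

from __future__ import annotations

from collections import deque


def apply_op(op: str, a: float, b: float) -> float:
    if op == "product":
        return a * b
    if op == "deltametric":
        return a - b
    if op == "ratiometric":
        return a / b
    if op == "summetric":
        return a + b
    raise ValueError(op)


OPS = ("product", "deltametric", "ratiometric", "summetric")


def bfs(adjacency: dict, source) -> dict:
    dist = {source: 0}
    queue = deque([source])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def node_adjacency(nodes, edges) -> dict:
    adj = {n: [] for n in nodes}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    return adj


def edge_adjacency(edges) -> dict:
    adj = {e: [] for e in edges}
    for e in edges:
        for f in edges:
            if e != f and set(e) & set(f):
                adj[e].append(f)
    return adj


def atom_dist(nodes, edges, i, j) -> int:
    return bfs(node_adjacency(nodes, edges), i)[j]


def bond_dist(edges, e, f) -> int:
    return bfs(edge_adjacency(edges), e)[f]


def bond_atom_dist(nodes, edges, e, j) -> int:
    adj = node_adjacency(nodes, edges)
    return min(bfs(adj, e[0])[j], bfs(adj, e[1])[j])


def oracle_aa(nodes, edges, p: dict, op: str, origin: str, metal, D: int) -> list[float]:
    bins = [0.0] * (D + 1)
    adj = node_adjacency(nodes, edges)
    if origin == "metal_centered":
        dist = bfs(adj, metal)
        for j in nodes:
            d = dist[j]
            if d <= D:
                bins[d] += apply_op(op, p[metal], p[j])
    else:
        for a, i in enumerate(nodes):
            dist = bfs(adj, i)
            bins[0] += apply_op(op, p[i], p[i])
            for j in nodes[a + 1 :]:
                d = dist[j]
                if 1 <= d <= D:
                    bins[d] += apply_op(op, p[i], p[j])
    return bins


def oracle_bb(nodes, edges, q: dict, op: str, origin: str, metal, merge: str, D: int) -> list[float]:
    bins = [0.0] * (D + 1)
    eadj = edge_adjacency(edges)
    if origin == "metal_centered":
        ml = [e for e in edges if metal in e]
        total = sum(q[e] for e in ml)
        sb = total / len(ml) if merge == "mean" else total
        bins[0] = apply_op(op, sb, sb)
        for e in edges:
            if e in ml:
                continue
            dist = bfs(eadj, e)
            d = min(dist[m] for m in ml)
            if 1 <= d <= D:
                bins[d] += apply_op(op, sb, q[e])
    else:
        for a, e in enumerate(edges):
            dist = bfs(eadj, e)
            bins[0] += apply_op(op, q[e], q[e])
            for f in edges[a + 1 :]:
                d = dist[f]
                if 1 <= d <= D:
                    bins[d] += apply_op(op, q[e], q[f])
    return bins


def oracle_ba(nodes, edges, q: dict, p: dict, op: str, origin: str, metal, D: int) -> list[float]:
    bins = [0.0] * (D + 1)
    adj = node_adjacency(nodes, edges)
    pool = [e for e in edges if metal in e] if origin == "metal_centered" else edges
    for e in pool:
        du, dv = bfs(adj, e[0]), bfs(adj, e[1])
        for j in nodes:
            d = min(du[j], dv[j])
            if d <= D:
                bins[d] += apply_op(op, q[e], p[j])
    return bins
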