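"""Brute-force graph oracles, independent of the networkx-based code paths.

Used to verify weighted edge betweenness (with equal splitting over
co-optimal paths) and minimum-weight path enumeration by exhaustive
simple-path search on small graphs.
"""

from itertools import permutations


def all_simple_paths(adj, s, t):
    """All simple s->t paths in an adjacency dict {u: {v: w}}."""
    out = []

    def walk(node, seen, path):
        if node == t:
            out.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in seen:
                seen.add(nxt)
                path.append(nxt)
                walk(nxt, seen, path)
                path.pop()
                seen.remove(nxt)

    walk(s, {s}, [s])
    return out


def path_weight(adj, path):
    return sum(adj[u][v] for u, v in zip(path, path[1:]))


def min_weight_paths(adj, s, t, tol=1e-12):
    """(best weight, all co-optimal simple paths) by exhaustive enumeration."""
    paths = all_simple_paths(adj, s, t)
    if not paths:
        return None, []
    weights = [path_weight(adj, p) for p in paths]
    best = min(weights)
    co = [p for p, w in zip(paths, weights) if w <= best + tol * max(1.0, abs(best))]
    return best, co


def brute_edge_betweenness(adj, tol=1e-12):
    """Unnormalized weighted edge betweenness over unordered node pairs.

    For every reachable pair, each co-optimal minimum-weight path
    contributes 1/k to each of its edges (k co-optimal paths).
    """
    nodes = sorted(adj)
    bc = {}
    for u in nodes:
        for v in adj[u]:
            bc[frozenset((u, v))] = 0.0
    for i, s in enumerate(nodes):
        for t in nodes[i + 1:]:
            _best, co = min_weight_paths(adj, s, t, tol)
            if not co:
                continue
            share = 1.0 / len(co)
            for p in co:
                for e in zip(p, p[1:]):
                    bc[frozenset(e)] += share
    return bc


def adj_from_edges(edges):
    """Adjacency dict from an iterable of (u, v, w)."""
    adj = {}
    for u, v, w in edges:
        adj.setdefault(u, {})[v] = w
        adj.setdefault(v, {})[u] = w
    return adj
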