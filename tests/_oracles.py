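"""Independent brute-force oracles used to validate the fast implementations.

Everything here is deliberately naive: exhaustive path enumeration,
all-pairs distance loops, direct geometric checks. These never share code
with the package paths they validate.
"""

from __future__ import annotations

import itertools
import math
from collections import deque


def brute_force_edge_betweenness(nodes, edges):
    """Edge betweenness by explicit enumeration of all shortest paths.

    For every unordered node pair, every shortest path is listed and each
    contributes 1/(number of shortest paths) to each of its edges.
    """
    adj = {n: set() for n in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)

    def bfs_dist(src):
        dist = {src: 0}
        q = deque([src])
        while q:
            u = q.popleft()
            for w in adj[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    q.append(w)
        return dist

    def all_shortest_paths(s, t, dist):
        # DFS backwards from t following strictly decreasing distance
        paths = []

        def extend(path):
            head = path[-1]
            if head == s:
                paths.append(list(reversed(path)))
                return
            for w in adj[head]:
                if dist.get(w, math.inf) == dist[head] - 1:
                    extend(path + [w])

        extend([t])
        return paths

    scores = {tuple(sorted(e)): 0.0 for e in edges}
    for s, t in itertools.combinations(nodes, 2):
        dist = bfs_dist(s)
        if t not in dist:
            continue
        paths = all_shortest_paths(s, t, dist)
        w = 1.0 / len(paths)
        for p in paths:
            for a, b in zip(p, p[1:]):
                scores[tuple(sorted((a, b)))] += w
    return scores


def brute_force_contacts(coords, cutoff):
    """All unordered index pairs within the cutoff, by direct looping."""
    n = len(coords)
    out = set()
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(tuple(coords[i]), tuple(coords[j]))
            if d <= cutoff:
                out.add((i, j))
    return out


def brute_force_hbonds(coords, atoms, max_dist, max_angle_dev):
    """Direct evaluation of the hydrogen-bond criteria.

    Re-derives donor assignment (H to the nearest N/O within 1.2 Å) and
    checks, per donor/acceptor pair in different residues, the D–A
    distance and the D–H···A deviation from linearity.
    Returns a set of ((donor_rid, donor_name), (acc_rid, acc_name)).
    """

    def element(a):
        return (a.element or a.name.lstrip("0123456789")[:1]).upper()

    heavy = [i for i, a in enumerate(atoms) if element(a) in ("N", "O")]
    hydros = [i for i, a in enumerate(atoms) if element(a) == "H"]
    donor_h = {}
    for h in hydros:
        best, best_d = None, None
        for i in heavy:
            d = math.dist(tuple(coords[h]), tuple(coords[i]))
            if best_d is None or d < best_d:
                best, best_d = i, d
        if best is not None and best_d <= 1.2:
            donor_h.setdefault(best, []).append(h)

    found = set()
    for d_idx, h_list in donor_h.items():
        for a_idx in heavy:
            if a_idx == d_idx:
                continue
            if atoms[a_idx].residue_id == atoms[d_idx].residue_id:
                continue
            if math.dist(tuple(coords[d_idx]), tuple(coords[a_idx])) > max_dist:
                continue
            for h in h_list:
                v1 = [coords[d_idx][k] - coords[h][k] for k in range(3)]
                v2 = [coords[a_idx][k] - coords[h][k] for k in range(3)]
                n1 = math.sqrt(sum(x * x for x in v1))
                n2 = math.sqrt(sum(x * x for x in v2))
                if n1 == 0 or n2 == 0:
                    continue
                cos_t = sum(a * b for a, b in zip(v1, v2)) / (n1 * n2)
                cos_t = max(-1.0, min(1.0, cos_t))
                angle = math.degrees(math.acos(cos_t))
                if 180.0 - angle <= max_angle_dev:
                    found.add((
                        (atoms[d_idx].residue_id, atoms[d_idx].name),
                        (atoms[a_idx].residue_id, atoms[a_idx].name),
                    ))
                    break
    return found


def adjusted_rand_index(labels_a, labels_b):
    """ARI via the pair-counting formula (no sklearn dependency)."""
    n = len(labels_a)
    assert n == len(labels_b)
    from collections import Counter

    pairs = Counter(zip(labels_a, labels_b))
    a_counts = Counter(labels_a)
    b_counts = Counter(labels_b)

    def comb2(x):
        return x * (x - 1) / 2.0

    sum_pairs = sum(comb2(c) for c in pairs.values())
    sum_a = sum(comb2(c) for c in a_counts.values())
    sum_b = sum(comb2(c) for c in b_counts.values())
    total = comb2(n)
    expected = sum_a * sum_b / total if total else 0.0
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (sum_pairs - expected) / (max_index - expected)
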