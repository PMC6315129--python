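"""Independent brute-force oracles used by the tests.

Deliberately naive pure-Python implementations (loops, BFS, normal
equations) that share no code with the package, so agreement is evidence
of correctness rather than tautology.
"""

import math


def bf_histogram(values, edges):
    """O(N*B) binning: half-open bins, last bin closed. Returns (counts, members)."""
    b = len(edges) - 1
    counts = [0] * b
    members = [[] for _ in range(b)]
    for i, v in enumerate(values):
        if v < edges[0] or v > edges[-1]:
            raise ValueError("out of range")
        placed = False
        for k in range(b):
            if edges[k] <= v < edges[k + 1]:
                counts[k] += 1
                members[k].append(i)
                placed = True
                break
        if not placed:  # v == edges[-1]
            counts[b - 1] += 1
            members[b - 1].append(i)
    return counts, members


def bf_adjacency(faces):
    """Vertex adjacency sets from triangle faces."""
    adj = {}
    for f in faces:
        for a in f:
            adj.setdefault(int(a), set())
        for a, b in ((f[0], f[1]), (f[1], f[2]), (f[2], f[0])):
            adj[int(a)].add(int(b))
            adj[int(b)].add(int(a))
    return adj


def bf_components(point_set, adj):
    """BFS connected components of the induced subgraph; list of sorted lists."""
    points = set(int(p) for p in point_set)
    seen = set()
    comps = []
    for start in sorted(points):
        if start in seen:
            continue
        comp, queue = [], [start]
        seen.add(start)
        while queue:
            u = queue.pop()
            comp.append(u)
            for w in adj.get(u, ()):
                if w in points and w not in seen:
                    seen.add(w)
                    queue.append(w)
        comps.append(sorted(comp))
    return comps


def bf_psi(regions, map_a, map_ref, sigma):
    """Region-size-weighted mean standardized absolute error of one bin."""
    if not regions:
        return 0.0
    total = sum(len(r) for r in regions)
    psi = 0.0
    for r in regions:
        err = sum(abs(map_a[j] - map_ref[j]) / sigma[j] for j in r) / len(r)
        psi += (len(r) / total) * err
    return psi


def bf_directed(map_a, map_ref, sigma, adj, edges, tau):
    """One direction of the spatiogram distance, regions from the first map."""
    counts_a, members_a = bf_histogram(map_a, edges)
    counts_r, _ = bf_histogram(map_ref, edges)
    n = len(map_a)
    d = 0.0
    for b in range(len(edges) - 1):
        regions = [c for c in bf_components(members_a[b], adj) if len(c) >= tau]
        psi = bf_psi(regions, map_a, map_ref, sigma)
        w = 1.0 - math.sqrt((counts_a[b] / n) * (counts_r[b] / n))
        d += psi * w
    return d


def bf_score(map_subject, map_ref, sigma, faces, edges, tau):
    """Full symmetrized spatiogram score, from scratch."""
    adj = bf_adjacency(faces)
    return 0.5 * (bf_directed(map_subject, map_ref, sigma, adj, edges, tau)
                  + bf_directed(map_ref, map_subject, sigma, adj, edges, tau))


def bf_ols(y, X):
    """OLS via normal equations with Gaussian elimination; returns beta list."""
    n, p = len(X), len(X[0])
    A = [[sum(X[i][a] * X[i][b] for i in range(n)) for b in range(p)] for a in range(p)]
    rhs = [sum(X[i][a] * y[i] for i in range(n)) for a in range(p)]
    for col in range(p):  # partial pivoting
        piv = max(range(col, p), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        rhs[col], rhs[piv] = rhs[piv], rhs[col]
        for r in range(col + 1, p):
            f = A[r][col] / A[col][col]
            for cc in range(col, p):
                A[r][cc] -= f * A[col][cc]
            rhs[r] -= f * rhs[col]
    beta = [0.0] * p
    for r in range(p - 1, -1, -1):
        beta[r] = (rhs[r] - sum(A[r][c] * beta[c] for c in range(r + 1, p))) / A[r][r]
    return beta


def bf_bh(pvalues):
    """Step-up BH adjustment by its definition: q_(i) = min_{j>=i} p_(j) m / j."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q = [0.0] * m
    for rank_pos, i in enumerate(order):
        tail = min(pvalues[order[j]] * m / (j + 1) for j in range(rank_pos, m))
        q[i] = min(1.0, tail)
    return q
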