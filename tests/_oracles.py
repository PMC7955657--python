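"""Independent brute-force reference implementations used only by tests.

Everything here is written with plain Python loops and no code shared with
the package's vectorised implementations, so agreement between the two is
a meaningful check.
"""

from __future__ import annotations


def brute_region_distance(a, b) -> float:
    inter = max(0, min(a.end, b.end) - max(a.start, b.start) + 1)
    la = a.end - a.start + 1
    lb = b.end - b.start + 1
    return 1.0 - inter / (la + lb - inter)


def brute_primary_dpc(alignments, mu1, delta_exp, g_max):
    """Full per-query DPC by exhaustive loops.

    Returns (rho, delta, ranked_indices, peak_indices, assignment) where
    assignment maps alignment index -> peak index (or None if discarded).
    Tie rules: the lowest-index density maximum is the designated top with
    delta = 1 and outranks everything; gamma ties rank by input index;
    nearest-peak ties go to the higher-ranked peak; a peak always belongs
    to itself.
    """
    n = len(alignments)
    regions = [a.query_region for a in alignments]
    d = [[brute_region_distance(regions[i], regions[j]) for j in range(n)]
         for i in range(n)]
    rho = [sum(1 for j in range(n) if d[i][j] < mu1) for i in range(n)]
    delta = []
    for i in range(n):
        cands = [d[i][j] for j in range(n)
                 if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        delta.append(min(cands) if cands else 1.0)
    gamma = [rho[i] * delta[i] for i in range(n)]
    ranked = sorted(range(n), key=lambda i: (-gamma[i], i))
    pos = [i for i in ranked if gamma[i] > 0]
    g = None
    for k in range(len(pos) - 1, 0, -1):
        if gamma[pos[k - 1]] / gamma[pos[k]] >= 10.0 ** delta_exp:
            g = k + 1  # 1-based gap index
            break
    peaks = []
    if len(pos) == 1:
        peaks = [pos[0]]  # lone positive gamma: infinite gap to the zeros
    elif g is not None and g <= g_max:
        peaks = pos[: min(g - 1, g_max)]
    assignment = {}
    for i in range(n):
        if i in peaks:
            assignment[i] = i
            continue
        best, best_d = None, None
        for p in peaks:
            if best_d is None or d[i][p] < best_d:
                best, best_d = p, d[i][p]
        assignment[i] = best if (best is not None and best_d < mu1) else None
    return rho, delta, ranked, peaks, assignment


def _max_matching(adj, n_left, n_right):
    """Hungarian-style augmenting-path maximum bipartite matching."""
    match_r = [-1] * n_right

    def try_kuhn(u, seen):
        for v in adj[u]:
            if v in seen:
                continue
            seen.add(v)
            if match_r[v] == -1 or try_kuhn(match_r[v], seen):
                match_r[v] = u
                return True
        return False

    size = 0
    for u in range(n_left):
        if try_kuhn(u, set()):
            size += 1
    return size


def brute_cluster_distance(c, c0, mu_d) -> float:
    """Matching-based distance between two primary clusters, by loops."""
    left = c.members
    right = c0.members
    adj = []
    for m in left:
        row = []
        for j, n_ in enumerate(right):
            if m.search_id == n_.search_id and brute_region_distance(
                m.search_region, n_.search_region
            ) < mu_d:
                row.append(j)
        adj.append(row)
    matched = _max_matching(adj, len(left), len(right))
    d = 1.0 - matched / min(len(left), len(right))
    return min(max(d, 0.0), 1.0)


def brute_metacluster_dpc(clusters, mu_d, mu2):
    """Densities, deltas, peaks and assignment in primary-cluster space."""
    n = len(clusters)
    d = [[0.0 if i == j else brute_cluster_distance(clusters[i], clusters[j], mu_d)
          for j in range(n)] for i in range(n)]
    rho = [sum(1 for j in range(n) if j != i and d[i][j] < mu2) for i in range(n)]
    delta = []
    for i in range(n):
        cands = [d[i][j] for j in range(n)
                 if rho[j] > rho[i] or (rho[j] == rho[i] and j < i)]
        delta.append(min(cands) if cands else 1.0)
    peaks = [i for i in range(n) if delta[i] >= 1.0 - 1e-12 and rho[i] > 1]
    assignment = {}
    for i in range(n):
        best, best_d = None, None
        for p in peaks:
            if best_d is None or d[i][p] < best_d:
                best, best_d = p, d[i][p]
        assignment[i] = best if (best is not None and best_d < mu2) else None
    return d, rho, delta, peaks, assignment


def brute_merge_components(mc_sets, d, threshold):
    """Connected components of metaclusters under mean cross distance.

    *mc_sets* lists, per metacluster, the indices of its primary clusters
    into the distance table *d*.
    """
    n = len(mc_sets)
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            cross = [d[a][b] for a in mc_sets[i] for b in mc_sets[j]]
            if sum(cross) / len(cross) < threshold:
                edges.append((i, j))
    comp = list(range(n))

    def root(x):
        while comp[x] != x:
            x = comp[x]
        return x

    for i, j in edges:
        ri, rj = root(i), root(j)
        if ri != rj:
            comp[ri] = rj
    groups = {}
    for i in range(n):
        groups.setdefault(root(i), set()).add(i)
    return sorted((frozenset(g) for g in groups.values()), key=sorted)
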