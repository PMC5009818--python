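"""Independent reference implementations used only to check the package.

Everything here recomputes results from first principles — naive
agglomeration that rebuilds the full linkage matrix every round, a
quadratic affine-gap local-alignment DP, weighted-medoid argmin by direct
enumeration — deliberately sharing no code with the implementation paths
they verify.
"""

from __future__ import annotations

import math
from typing import Mapping

from Bio.Align import substitution_matrices

CAP = 1.0


def capped_matrix(ids, edges, t) -> dict[tuple[str, str], float]:
    """Pairwise capped distances and relatedness from an edge map."""
    from protoclust.core import is_related

    d = {}
    rel = {}
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            key = (a, b) if a <= b else (b, a)
            hit = edges.get(key)
            if hit is not None and is_related(hit, t):
                d[key] = min(1.0 - hit.identity_pct / 100.0, CAP)
                rel[key] = True
            else:
                d[key] = CAP
                rel[key] = False
    return d, rel


def naive_agglomerate(ids, edges, t, linkage="average", seed_ids=frozenset()):
    """Reference agglomerator: recompute every linkage from scratch per round.

    Each cluster tracks the member subset used for distance determination
    ("effective" members); under the seed-protecting rule a seed+nonseed
    merge keeps only the seed side's effective members.
    """
    ids = sorted(set(ids))
    dmat, rel = capped_matrix(ids, edges, t)
    cutoff = 1.0 - t.min_identity_pct / 100.0

    def pd(a, b):
        return dmat[(a, b) if a <= b else (b, a)]

    def pr(a, b):
        return rel[(a, b) if a <= b else (b, a)]

    # cluster: (members, effective_members, has_seed)
    clusters = [([i], [i], i in seed_ids) for i in ids]
    while True:
        best = None
        for x in range(len(clusters)):
            for y in range(x + 1, len(clusters)):
                ma, ea, _ = clusters[x]
                mb, eb, _ = clusters[y]
                if not any(pr(a, b) for a in ea for b in eb):
                    continue
                ds = [pd(a, b) for a in ea for b in eb]
                if linkage == "average":
                    link = sum(ds) / len(ds)
                elif linkage == "complete":
                    link = max(ds)
                else:
                    link = min(ds)
                if link > cutoff + 1e-12:
                    continue
                key = (link, *sorted((min(ma), min(mb))))
                if best is None or key < best[0]:
                    best = (key, x, y)
        if best is None:
            break
        _, x, y = best
        ma, ea, sa = clusters[x]
        mb, eb, sb = clusters[y]
        if sa != sb:
            eff = ea if sa else eb
        else:
            eff = ea + eb
        merged = (sorted(ma + mb), eff, sa or sb)
        clusters = [c for k, c in enumerate(clusters) if k not in (x, y)] + [merged]
    out = [set(m) for m, _, _ in clusters]
    out.sort(key=min)
    return out


def weighted_medoid(members, weights: Mapping[str, int], dist) -> str:
    """Direct enumeration argmin of the weighted average distance."""
    members = sorted(members)
    if len(members) == 1:
        return members[0]
    best = None
    for p in members:
        num = sum(weights.get(q, 1) * min(dist(p, q), CAP) for q in members if q != p)
        den = sum(weights.get(q, 1) for q in members if q != p)
        key = (num / den, -weights.get(p, 1), p)
        if best is None or key < best:
            best, pick = key, p
    return pick


def sw_affine(seq_a: str, seq_b: str, open_=-11.0, extend=-1.0, matrix_name="BLOSUM62"):
    """Quadratic Smith-Waterman with affine gaps; returns (score, alignment).

    The alignment is a list of (i, j) matched coordinate pairs (0-based) of
    the single optimal local path, with ties resolved toward the diagonal.
    """
    m = substitution_matrices.load(matrix_name)
    na, nb = len(seq_a), len(seq_b)
    NEG = -math.inf
    M = [[0.0] * (nb + 1) for _ in range(na + 1)]
    Ix = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in seq_b (up)
    Iy = [[NEG] * (nb + 1) for _ in range(na + 1)]  # gap in seq_a (left)
    best = (0.0, 0, 0)
    for i in range(1, na + 1):
        for j in range(1, nb + 1):
            Ix[i][j] = max(M[i - 1][j] + open_, Ix[i - 1][j] + extend)
            Iy[i][j] = max(M[i][j - 1] + open_, Iy[i][j - 1] + extend)
            sub = m[seq_a[i - 1], seq_b[j - 1]]
            M[i][j] = max(0.0, sub + max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1]))
            if M[i][j] > best[0]:
                best = (M[i][j], i, j)
    score, i, j = best
    pairs = []
    state = "M"
    while i > 0 and j > 0:
        if state == "M":
            if M[i][j] == 0.0:
                break
            sub = m[seq_a[i - 1], seq_b[j - 1]]
            pairs.append((i - 1, j - 1))
            prev = M[i][j] - sub
            if abs(prev - M[i - 1][j - 1]) < 1e-9:
                state = "M"
            elif abs(prev - Ix[i - 1][j - 1]) < 1e-9:
                state = "Ix"
            else:
                state = "Iy"
            i, j = i - 1, j - 1
        elif state == "Ix":
            if abs(Ix[i][j] - (M[i - 1][j] + open_)) < 1e-9:
                state = "M"
            i -= 1
        else:
            if abs(Iy[i][j] - (M[i][j - 1] + open_)) < 1e-9:
                state = "M"
            j -= 1
    pairs.reverse()
    return score, pairs


def components_bfs(edges, universe):
    """Connected components via networkx, labeled by smallest member."""
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(universe)
    g.add_edges_from(edges)
    out = {}
    for comp in nx.connected_components(g):
        label = min(comp)
        for n in comp:
            out[n] = label
    return out
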