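"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from first principles, with no
imports from the package's computational internals, so it can serve as an
independent cross-check: exhaustive SSR enumeration, recursive NG86 path
counting (translation via Biopython's Seq, not the package's table),
Gotoh affine-gap alignment scoring, brute-force mutual-best-hit search,
and additive distance matrices from random trees.
"""

from __future__ import annotations

import numpy as np
from Bio.Seq import Seq

# ------------------------------------------------------------- SSR brute force

SSR_MIN = {2: 6, 3: 5, 4: 5, 5: 5, 6: 5}


def _primitive(unit: str) -> bool:
    return all(
        unit != unit[:d] * (len(unit) // d)
        for d in range(1, len(unit))
        if len(unit) % d == 0
    )


def brute_force_ssrs(sequence: str, thresholds=None) -> set[tuple[int, int, str]]:
    """Every maximal, primitive, threshold-passing tandem run, found by
    enumerating each (start, unit length) and extending greedily; then
    motifs contained in a motif of shorter-or-equal unit are dropped.
    Returns {(start 1-based, end inclusive, unit)}."""
    thresholds = dict(SSR_MIN if thresholds is None else thresholds)
    seq = sequence.upper()
    raw: set[tuple[int, int, str]] = set()
    for k, min_rep in thresholds.items():
        for start in range(len(seq) - k * min_rep + 1):
            unit = seq[start : start + k]
            if any(c not in "ACGT" for c in unit) or not _primitive(unit):
                continue
            # greedy extension to the right, full units only
            reps = 1
            while True:
                nxt = seq[start + reps * k : start + (reps + 1) * k]
                if nxt == unit:
                    reps += 1
                else:
                    break
            if reps < min_rep:
                continue
            # partial-unit and full-unit left-extension means not maximal
            if start >= 1 and seq[start - 1] == seq[start - 1 + k]:
                continue
            raw.add((start + 1, start + reps * k, unit))
    out = set()
    for s, e, u in raw:
        contained = any(
            (s2, e2, u2) != (s, e, u)
            and len(u2) <= len(u)
            and s2 <= s
            and e <= e2
            for s2, e2, u2 in raw
        )
        if not contained:
            out.add((s, e, u))
    return out


# ---------------------------------------------------------------- NG86 oracle

def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_codon_sites(codon: str) -> float:
    """Synonymous site count of one codon (stop-creating changes count as
    nonsynonymous)."""
    syn = 0
    for pos in range(3):
        for alt in "ACGT":
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1 :]
            if _aa(mut) != "*" and _aa(mut) == _aa(codon):
                syn += 1
    return syn / 3.0


def oracle_pair_diffs(ca: str, cb: str) -> tuple[float, float]:
    """Average synonymous/nonsynonymous step counts over all minimal
    mutational paths, excluding paths through stop codons (falling back to
    all paths, stop steps nonsynonymous, if none survive)."""

    def paths(cur: str, remaining: list[int], allow_stops: bool):
        if not remaining:
            yield (0.0, 0.0)
            return
        for i, pos in enumerate(remaining):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if _aa(nxt) == "*" and not allow_stops:
                continue
            step_syn = (
                _aa(cur) != "*" and _aa(nxt) != "*" and _aa(cur) == _aa(nxt)
            )
            for sd, nd in paths(nxt, remaining[:i] + remaining[i + 1 :], allow_stops):
                yield (sd + step_syn, nd + (not step_syn))

    diff = [i for i in range(3) if ca[i] != cb[i]]
    found = list(paths(ca, diff, False))
    if not found:
        found = list(paths(ca, diff, True))
    n = len(found)
    return sum(p[0] for p in found) / n, sum(p[1] for p in found) / n


def oracle_ng86(cds_a: str, cds_b: str) -> tuple[float, float, float, float]:
    S = N = Sd = Nd = 0.0
    for i in range(0, len(cds_a), 3):
        ca, cb = cds_a[i : i + 3], cds_b[i : i + 3]
        sa, sb = oracle_codon_sites(ca), oracle_codon_sites(cb)
        S += (sa + sb) / 2
        N += 3 - (sa + sb) / 2
        sd, nd = oracle_pair_diffs(ca, cb)
        Sd += sd
        Nd += nd
    return S, N, Sd, Nd


# --------------------------------------------------------- affine DP alignment

def gotoh_score(
    a: str,
    b: str,
    matrix,
    open_score: float = -10.0,
    extend_score: float = -0.5,
) -> float:
    """Optimal global alignment score with affine gaps (a gap of length L
    scores open + (L-1) x extend), end gaps penalized."""
    NEG = float("-inf")
    n, m = len(a), len(b)
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consume a)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consume b)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = open_score + (i - 1) * extend_score
    for j in range(1, m + 1):
        Y[0][j] = open_score + (j - 1) * extend_score
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = matrix[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
        for j in range(0, m + 1):
            if i >= 1:
                X[i][j] = max(
                    M[i - 1][j] + open_score,
                    X[i - 1][j] + extend_score,
                    Y[i - 1][j] + open_score,
                )
            if j >= 1:
                Y[i][j] = max(
                    M[i][j - 1] + open_score,
                    Y[i][j - 1] + extend_score,
                    X[i][j - 1] + open_score,
                )
    return max(M[n][m], X[n][m], Y[n][m])


# ------------------------------------------------------------------ RBH oracle

def brute_force_rbh(ids: list[str], scores: dict) -> set[tuple[str, str]]:
    """All (a, b) with a < b where each is the other's unique-after-tie-break
    best partner; ties broken toward the smallest id."""

    def sym(x, y):
        key = (x, y) if x < y else (y, x)
        return scores.get(key)

    def best(g):
        cand = [(other, sym(g, other)) for other in ids
                if other != g and sym(g, other) is not None]
        if not cand:
            return None
        top = max(s for _, s in cand)
        return min(o for o, s in cand if s == top)

    out = set()
    for g in ids:
        h = best(g)
        if h is not None and best(h) == g:
            out.add((g, h) if g < h else (h, g))
    return out


# ------------------------------------------------------------- additive trees

def random_additive_tree(
    rng: np.random.Generator, n_taxa: int
) -> tuple[list[str], np.ndarray, set[frozenset[str]]]:
    """Random unrooted binary tree with positive branch lengths; returns
    labels, the leaf-leaf path-distance matrix, and non-trivial splits."""
    labels = [f"t{i:02d}" for i in range(n_taxa)]
    # start from a star over 3 leaves, attach remaining leaves to random edges
    nodes = {i: labels[i] for i in range(n_taxa)}
    edges: list[list] = []  # [u, v, length]
    nxt = n_taxa
    center = nxt
    nxt += 1
    for i in range(3):
        edges.append([i, center, float(rng.uniform(0.1, 1.0))])
    for leaf in range(3, n_taxa):
        ei = int(rng.integers(0, len(edges)))
        u, v, L = edges.pop(ei)
        mid = nxt
        nxt += 1
        f = float(rng.uniform(0.25, 0.75))
        edges.append([u, mid, L * f])
        edges.append([mid, v, L * (1 - f)])
        edges.append([leaf, mid, float(rng.uniform(0.1, 1.0))])
    # distances by BFS over the tree
    adj: dict[int, list[tuple[int, float]]] = {}
    for u, v, L in edges:
        adj.setdefault(u, []).append((v, L))
        adj.setdefault(v, []).append((u, L))
    d = np.zeros((n_taxa, n_taxa))
    for src in range(n_taxa):
        dist = {src: 0.0}
        stack = [src]
        while stack:
            x = stack.pop()
            for y, L in adj[x]:
                if y not in dist:
                    dist[y] = dist[x] + L
                    stack.append(y)
        for dst in range(n_taxa):
            d[src, dst] = dist[dst]
    # splits: remove each internal edge, collect leaves on one side
    splits = set()
    anchor = min(labels)
    for u, v, _ in edges:
        comp = _component(adj, u, v)
        side = frozenset(labels[i] for i in comp if i < n_taxa)
        if 1 < len(side) < n_taxa - 1:
            if anchor in side:
                side = frozenset(labels) - side
            splits.add(side)
    return labels, d, splits


def _component(adj, start, banned) -> set[int]:
    seen = {start}
    stack = [start]
    while stack:
        x = stack.pop()
        for y, _ in adj[x]:
            if y != banned and y not in seen:
                seen.add(y)
                stack.append(y)
    return seen
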