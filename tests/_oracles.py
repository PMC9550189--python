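"""Independent oracles used by the test suite.

Everything here is deliberately written from first principles (breadth-
first search, per-bp bitmaps, rank enumeration) and shares no code with
the package implementation it checks.
"""

from __future__ import annotations

import heapq
from collections import deque


# ---------------------------------------------------------------------------
# Reversal distance oracles
# ---------------------------------------------------------------------------


def bfs_reversal_distances(n: int) -> dict[tuple[int, ...], int]:
    """Distance from the identity to every signed permutation of size n."""
    ident = tuple(range(1, n + 1))
    dist = {ident: 0}
    queue = deque([ident])
    while queue:
        p = queue.popleft()
        d = dist[p]
        for i in range(n):
            for j in range(i + 1, n + 1):
                c = p[:i] + tuple(-x for x in reversed(p[i:j])) + p[j:]
                if c not in dist:
                    dist[c] = d + 1
                    queue.append(c)
    return dist


def _cycles_lower_bound(perm: tuple[int, ...]) -> int:
    """(n + 1) - cycles of the breakpoint graph: a lower bound on the
    reversal distance (each reversal changes the cycle count by <= 1)."""
    n = len(perm)
    ext = [0]
    for x in perm:
        ext.extend((2 * x - 1, 2 * x) if x > 0 else (-2 * x, -2 * x - 1))
    ext.append(2 * n + 1)
    pos = {v: i for i, v in enumerate(ext)}
    seen = [False] * (2 * n + 2)
    cycles = 0
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        cycles += 1
        p = start
        while not seen[p]:
            seen[p] = True
            q = p ^ 1
            seen[q] = True
            p = pos[ext[q] ^ 1]
    return (n + 1) - cycles


def astar_reversal_distance(perm: tuple[int, ...]) -> int:
    """Exact reversal distance by A* with the admissible cycle bound."""
    n = len(perm)
    ident = tuple(range(1, n + 1))
    if perm == ident:
        return 0
    open_heap = [(_cycles_lower_bound(perm), 0, perm)]
    best = {perm: 0}
    while open_heap:
        f, g, p = heapq.heappop(open_heap)
        if p == ident:
            return g
        if g > best.get(p, 1 << 30):
            continue
        for i in range(n):
            for j in range(i + 1, n + 1):
                c = p[:i] + tuple(-x for x in reversed(p[i:j])) + p[j:]
                g2 = g + 1
                if g2 < best.get(c, 1 << 30):
                    best[c] = g2
                    heapq.heappush(
                        open_heap, (g2 + _cycles_lower_bound(c), g2, c)
                    )
    raise RuntimeError("unreachable")


# ---------------------------------------------------------------------------
# Multichromosomal distance oracle (inversions, fusions, fissions)
# ---------------------------------------------------------------------------


def _canonical(chroms) -> tuple:
    out = []
    for ch in chroms:
        fwd = tuple(ch)
        rev = tuple(-x for x in reversed(fwd))
        out.append(min(fwd, rev))
    return tuple(sorted(out))


def _genome_neighbors(state):
    out = set()
    chroms = [list(c) for c in state]
    for ci, ch in enumerate(chroms):
        m = len(ch)
        for i in range(m):
            for j in range(i + 1, m + 1):
                if i == 0 and j == m:
                    continue
                new = ch[:i] + [-x for x in reversed(ch[i:j])] + ch[j:]
                out.add(_canonical(chroms[:ci] + [new] + chroms[ci + 1 :]))
        for cut in range(1, m):
            out.add(_canonical(chroms[:ci] + chroms[ci + 1 :] + [ch[:cut], ch[cut:]]))
    for ci in range(len(chroms)):
        for cj in range(ci + 1, len(chroms)):
            rest = [c for k, c in enumerate(chroms) if k not in (ci, cj)]
            for a in (chroms[ci], [-x for x in reversed(chroms[ci])]):
                for b in (chroms[cj], [-x for x in reversed(chroms[cj])]):
                    out.add(_canonical(rest + [a + b]))
    return out


def genome_distance_bfs(chroms_a, chroms_b) -> int:
    """Minimum {inversion, fusion, fission} count by bidirectional BFS."""
    s, t = _canonical(chroms_a), _canonical(chroms_b)
    if s == t:
        return 0
    front_s, front_t = {s: 0}, {t: 0}
    qs, qt = deque([s]), deque([t])
    while qs and qt:
        q, f, other = (qs, front_s, front_t) if len(qs) <= len(qt) else (qt, front_t, front_s)
        for _ in range(len(q)):
            u = q.popleft()
            for v in _genome_neighbors(u):
                if v in other:
                    return f[u] + 1 + other[v]
                if v not in f:
                    f[v] = f[u] + 1
                    q.append(v)
    raise RuntimeError("graph is connected; unreachable")


# ---------------------------------------------------------------------------
# Per-bp interval oracles
# ---------------------------------------------------------------------------


def bitmap_cover(intervals, length: int):
    """Boolean coverage bitmap of [0, length)."""
    cover = [False] * length
    for s, e in intervals:
        for i in range(max(0, s), min(length, e)):
            cover[i] = True
    return cover


def bitmap_intersection_blocks(sets, length: int):
    """Maximal runs covered in every interval set, as (start, end) pairs."""
    common = [True] * length
    for ivs in sets:
        cov = bitmap_cover(ivs, length)
        common = [a and b for a, b in zip(common, cov)]
    out = []
    start = None
    for i in range(length + 1):
        if i < length and common[i]:
            if start is None:
                start = i
        elif start is not None:
            out.append((start, i))
            start = None
    return out


# ---------------------------------------------------------------------------
# Rank-sum statistic by enumeration
# ---------------------------------------------------------------------------


def rank_sum_u(xs, ys) -> float:
    """Mann-Whitney U statistic of xs vs ys by direct pair counting."""
    u = 0.0
    for x in xs:
        for y in ys:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u
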