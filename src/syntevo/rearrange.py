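"""Signed-permutation rearrangement algebra.

Distances and explicit scenarios between block karyotypes using the
three event types observable at synteny-block resolution: inversions,
chromosome fusions, and chromosome fissions.

* :func:`reversal_distance` implements the exact Hannenhalli–Pevzner
  formula ``d = (n + 1) - c + h + f`` for a single chromosome, with full
  hurdle and fortress accounting on the breakpoint graph.
* :func:`multichromosomal_scenario` searches for a minimum-length event
  sequence directly in the {inversion, fusion, fission} operation set,
  using iterative-deepening A* guided by the (admissible) DCJ distance.
  Every inversion, fusion and fission is a single double-cut-and-join
  operation, so the DCJ distance never overestimates the restricted
  distance and the search result is provably minimal.  A reciprocal
  translocation never appears as a primitive; where one would be
  parsimonious the search emits the fission+fusion pair instead.
* :func:`fraction_rearranged` quantifies how much of an ancestral
  chromosome was moved between chromosomes (inter) or shuffled within
  its majority chromosome (intra) in a descendant.
* :func:`classify_orthology` labels ancestral chromosomes as 1:1,
  1:n-complete, or partial against another karyotype.

Chromosomes are orientation-free objects: a chromosome read backwards
with all signs flipped is the same chromosome.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .core import BlockGenome, ValidationError

# ---------------------------------------------------------------------------
# Signed permutations
# ---------------------------------------------------------------------------

Chromosome = tuple[int, ...]
GenomeState = tuple[Chromosome, ...]


@dataclass(frozen=True)
class SignedPermutation:
    """A genome relabelled so a comparison genome reads as the identity.

    ``chromosomes`` holds the focal genome's chromosomes as signed
    integers 1..n; the comparison genome corresponds to chromosomes
    ``(1..k), (k+1..m), ...`` all with positive signs.
    """

    chromosomes: tuple[Chromosome, ...]
    target_chromosomes: tuple[Chromosome, ...]
    block_of_label: dict[int, int] = field(compare=False, hash=False, default_factory=dict)

    @property
    def n(self) -> int:
        return sum(len(c) for c in self.chromosomes)


def canonical_chromosome(chrom: Sequence[int]) -> Chromosome:
    """Pick the lexicographically smaller of the two readings of a chromosome."""
    fwd = tuple(chrom)
    rev = tuple(-x for x in reversed(fwd))
    return min(fwd, rev)


def canonical_state(chromosomes: Iterable[Sequence[int]]) -> GenomeState:
    return tuple(sorted(canonical_chromosome(c) for c in chromosomes))


def to_signed_permutation(a: BlockGenome, b: BlockGenome) -> SignedPermutation:
    """Relabel blocks so that ``b`` reads as identity chromosomes.

    Blocks are renumbered 1..n following ``b``'s chromosome order (in
    sorted chromosome-name order for determinism); ``a`` is expressed in
    that labelling with composed signs.
    """
    if a.blocks != b.blocks:
        missing = sorted(a.blocks ^ b.blocks)
        raise ValidationError(f"block sets differ; symmetric difference: {missing}")
    label: dict[int, int] = {}
    sign: dict[int, int] = {}
    target: list[Chromosome] = []
    nxt = 1
    for chrom in sorted(b.chromosomes):
        row = []
        for blk in b.chromosomes[chrom]:
            label[abs(blk)] = nxt
            sign[abs(blk)] = 1 if blk > 0 else -1
            row.append(nxt)
            nxt += 1
        target.append(tuple(row))
    chroms: list[Chromosome] = []
    for chrom in sorted(a.chromosomes):
        chroms.append(
            tuple(
                (1 if blk > 0 else -1) * sign[abs(blk)] * label[abs(blk)]
                for blk in a.chromosomes[chrom]
            )
        )
    inv = {v: k for k, v in label.items()}
    return SignedPermutation(tuple(chroms), tuple(target), inv)


# ---------------------------------------------------------------------------
# Hannenhalli–Pevzner reversal distance (single chromosome)
# ---------------------------------------------------------------------------


def _breakpoint_graph(perm: Sequence[int]):
    """Cycles of the breakpoint graph in the unsigned doubling of ``perm``.

    Returns (cycles, positions-per-cycle, desire-edges-per-cycle).  Each
    desire edge is a position pair (i, j), i < j; an edge is oriented iff
    i and j have the same parity.
    """
    n = len(perm)
    a = [0]
    for x in perm:
        if x > 0:
            a.extend((2 * x - 1, 2 * x))
        else:
            a.extend((-2 * x, -2 * x - 1))
    a.append(2 * n + 1)
    pos = [0] * (2 * n + 2)
    for i, v in enumerate(a):
        pos[v] = i
    seen = [False] * (2 * n + 2)
    cycles = []
    for start in range(2 * n + 2):
        if seen[start]:
            continue
        positions = []
        edges = []
        p = start
        while not seen[p]:
            seen[p] = True
            q = p ^ 1  # reality edge: positions are paired (0,1), (2,3), ...
            seen[q] = True
            positions.extend((p, q))
            r = pos[a[q] ^ 1]  # desire edge: values are paired (0,1), (2,3), ...
            edges.append((min(q, r), max(q, r)))
            p = r
        cycles.append((positions, edges))
    return cycles


def _hurdle_set(seq: list[int]) -> set[int]:
    """Hurdles among unoriented components.

    ``seq`` lists, in circular position order, the component id of every
    breakpoint-graph position belonging to an unoriented component.  A
    component is a hurdle iff its occurrences form one contiguous run on
    that circle (it does not separate two other unoriented components).
    """
    T = len(seq)
    comps = set(seq)
    hurdles = set()
    for c in comps:
        boundaries = sum(
            1 for i in range(T) if seq[i] == c and seq[(i + 1) % T] != c
        )
        if boundaries <= 1:
            hurdles.add(c)
    return hurdles


def _hurdles_and_fortress(cycles) -> tuple[int, int]:
    """Count hurdles and detect a fortress from breakpoint-graph cycles."""
    nontrivial = [
        (positions, edges) for positions, edges in cycles if len(positions) > 2
    ]
    if not nontrivial:
        return 0, 0
    oriented_cycle = [
        any((i % 2) == (j % 2) for i, j in edges) for _, edges in nontrivial
    ]
    # union cycles whose desire edges interleave
    k = len(nontrivial)
    parent = list(range(k))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for u in range(k):
        for v in range(u + 1, k):
            if find(u) == find(v):
                continue
            linked = False
            for i1, j1 in nontrivial[u][1]:
                for i2, j2 in nontrivial[v][1]:
                    if (i1 < i2 < j1 < j2) or (i2 < i1 < j2 < j1):
                        linked = True
                        break
                if linked:
                    break
            if linked:
                parent[find(u)] = find(v)
    comp_oriented: dict[int, bool] = {}
    comp_positions: dict[int, list[int]] = {}
    for idx, (positions, _) in enumerate(nontrivial):
        root = find(idx)
        comp_oriented[root] = comp_oriented.get(root, False) or oriented_cycle[idx]
        comp_positions.setdefault(root, []).extend(positions)
    unoriented = [c for c, ori in comp_oriented.items() if not ori]
    if not unoriented:
        return 0, 0
    tagged = sorted(
        (p, c) for c in unoriented for p in comp_positions[c]
    )
    seq = [c for _, c in tagged]
    hurdles = _hurdle_set(seq)
    h = len(hurdles)
    # fortress: an odd number of hurdles, all of which are superhurdles
    # (deleting the hurdle would turn a currently non-hurdle component
    # into a hurdle).
    f = 0
    if h % 2 == 1 and h > 0:
        all_super = True
        for c in hurdles:
            reduced = [x for x in seq if x != c]
            if not reduced:
                all_super = False
                break
            new_hurdles = _hurdle_set(reduced) - hurdles
            if not new_hurdles:
                all_super = False
                break
        if all_super:
            f = 1
    return h, f


def reversal_distance(perm: Sequence[int]) -> int:
    """Exact minimum number of reversals sorting ``perm`` to +1..+n.

    Implements ``d = (n + 1) - c + h + f`` with breakpoint-graph cycles
    ``c``, hurdles ``h`` and fortress indicator ``f``.
    """
    perm = list(perm)
    n = len(perm)
    if sorted(abs(x) for x in perm) != list(range(1, n + 1)):
        raise ValidationError("permutation must contain each magnitude 1..n once")
    if n == 0:
        return 0
    cycles = _breakpoint_graph(perm)
    c = len(cycles)
    h, f = _hurdles_and_fortress(cycles)
    return (n + 1) - c + h + f


# ---------------------------------------------------------------------------
# DCJ lower bound for multichromosomal genomes
# ---------------------------------------------------------------------------


def _state_objects(state: GenomeState):
    """Adjacency and telomere objects of a genome state.

    Objects are frozensets of extremities ``(block, side)`` with side 0 =
    tail, 1 = head.  Returns (objects, extremity -> object index).
    """
    objs: list[tuple] = []
    where: dict[tuple[int, int], int] = {}

    def right_end(x: int) -> tuple[int, int]:
        return (abs(x), 1 if x > 0 else 0)

    def left_end(x: int) -> tuple[int, int]:
        return (abs(x), 0 if x > 0 else 1)

    for chrom in state:
        ends = [left_end(chrom[0])]
        for x, y in zip(chrom, chrom[1:]):
            objs.append((right_end(x), left_end(y)))
        ends.append(right_end(chrom[-1]))
        for e in ends:
            objs.append((e,))
    for i, ob in enumerate(objs):
        for e in ob:
            where[e] = i
    return objs, where


def dcj_distance(state_a: GenomeState, state_b: GenomeState) -> int:
    """Double-cut-and-join distance between two genome states.

    ``d = n - (C + I/2)`` with C cycles and I odd paths in the adjacency
    graph.  Serves as an admissible lower bound for the restricted
    {inversion, fusion, fission} distance.
    """
    n = sum(len(c) for c in state_a)
    objs_a, where_a = _state_objects(state_a)
    objs_b, where_b = _state_objects(state_b)
    visited_a = [False] * len(objs_a)
    visited_b = [False] * len(objs_b)
    C = 0
    I = 0
    for start in range(len(objs_a)):
        if visited_a[start]:
            continue
        # traverse the alternating component containing this A-object
        stack = [(0, start)]
        verts = []
        edge_count = 0
        seen_edges = set()
        while stack:
            side, idx = stack.pop()
            visited = visited_a if side == 0 else visited_b
            if visited[idx]:
                continue
            visited[idx] = True
            verts.append((side, idx))
            obj = (objs_a if side == 0 else objs_b)[idx]
            other_where = where_b if side == 0 else where_a
            for e in obj:
                j = other_where[e]
                key = (min(side, 1 - side), (idx, j) if side == 0 else (j, idx), e)
                if key not in seen_edges:
                    seen_edges.add(key)
                    edge_count += 1
                stack.append((1 - side, j))
        V = len(verts)
        if edge_count == V:
            C += 1
        else:  # path with V - 1 edges
            if (V - 1) % 2 == 1:
                I += 1
    return n - C - I // 2


# ---------------------------------------------------------------------------
# Event application and scenario search
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Event:
    """A rearrangement event expressed on a canonical genome state.

    Chromosome indices refer to the state's sorted canonical chromosome
    order at the moment the event applies; cut positions are junction
    indices within the canonical reading of the chromosome.
    """

    kind: str  # 'inversion' | 'fusion' | 'fission'
    payload: tuple

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.kind}{self.payload}"


def apply_event(state: GenomeState, event: Event) -> GenomeState:
    chroms = list(state)
    if event.kind == "inversion":
        ci, i, j = event.payload
        ch = chroms[ci]
        chroms[ci] = ch[:i] + tuple(-x for x in reversed(ch[i:j])) + ch[j:]
    elif event.kind == "fission":
        ci, cut = event.payload
        ch = chroms.pop(ci)
        chroms.extend((ch[:cut], ch[cut:]))
    elif event.kind == "fusion":
        ci, cj, flip_i, flip_j = event.payload
        a, b = chroms[ci], chroms[cj]
        if flip_i:
            a = tuple(-x for x in reversed(a))
        if flip_j:
            b = tuple(-x for x in reversed(b))
        chroms = [c for k, c in enumerate(chroms) if k not in (ci, cj)]
        chroms.append(a + b)
    else:  # pragma: no cover - guarded by Event construction sites
        raise ValidationError(f"unknown event kind {event.kind!r}")
    return canonical_state(chroms)


def _moves(state: GenomeState) -> list[Event]:
    """All candidate events in deterministic lexicographic order.

    Order is (event type alphabetically, chromosome index, cut
    positions): fission < fusion < inversion.
    """
    out: list[Event] = []
    for ci, ch in enumerate(state):
        for cut in range(1, len(ch)):
            out.append(Event("fission", (ci, cut)))
    for ci in range(len(state)):
        for cj in range(ci + 1, len(state)):
            for flip_i in (0, 1):
                for flip_j in (0, 1):
                    out.append(Event("fusion", (ci, cj, flip_i, flip_j)))
    for ci, ch in enumerate(state):
        m = len(ch)
        for i in range(m):
            for j in range(i + 1, m + 1):
                if i == 0 and j == m:
                    continue  # whole-chromosome flip is not an event
                out.append(Event("inversion", (ci, i, j)))
    return out


class _SearchCap(Exception):
    pass


def _ida_star(start: GenomeState, goal: GenomeState, node_cap: int):
    """Iterative-deepening A* with the DCJ lower bound.

    Children are explored in lexicographic event order, so the first
    scenario found at the optimal depth is the lexicographically least
    minimum-length scenario under that ordering.
    """
    h_cache: dict[GenomeState, int] = {}

    def h_of(state: GenomeState) -> int:
        h = h_cache.get(state)
        if h is None:
            h = dcj_distance(state, goal)
            h_cache[state] = h
        return h

    bound = h_of(start)
    counter = {"nodes": 0}

    def dfs(state, g, bound, path_states, events):
        counter["nodes"] += 1
        if counter["nodes"] > node_cap:
            raise _SearchCap
        f = g + h_of(state)
        if f > bound:
            return f
        if state == goal:
            return "FOUND"
        nxt = np.inf
        for ev in _moves(state):
            child = apply_event(state, ev)
            if child in path_states:
                continue
            path_states.add(child)
            events.append(ev)
            t = dfs(child, g + 1, bound, path_states, events)
            if t == "FOUND":
                return t
            events.pop()
            path_states.discard(child)
            nxt = min(nxt, t)
        return nxt

    while True:
        events: list[Event] = []
        t = dfs(start, 0, bound, {start}, events)
        if t == "FOUND":
            return events
        if t == np.inf:
            raise ValidationError("search exhausted without reaching target")
        bound = int(t)


def _constructive_scenario(start: GenomeState, goal: GenomeState) -> list[Event]:
    """Valid (near-parsimonious) scenario for instances too large to search.

    Three phases: fission every junction joining blocks of different
    target chromosomes; fuse the pieces of each target chromosome
    (choosing the join orientation that most lowers the DCJ distance);
    then sort each chromosome internally with an exact greedy reversal
    descent (always applies a reversal lowering the exact HP distance by
    one, which always exists).
    """
    target_chrom: dict[int, int] = {}
    for t, ch in enumerate(goal):
        for x in ch:
            target_chrom[abs(x)] = t
    events: list[Event] = []
    state = start
    # phase 1: fissions at mixed junctions
    while True:
        cut_ev = None
        for ci, ch in enumerate(state):
            for cut in range(1, len(ch)):
                if target_chrom[abs(ch[cut - 1])] != target_chrom[abs(ch[cut])]:
                    cut_ev = Event("fission", (ci, cut))
                    break
            if cut_ev:
                break
        if cut_ev is None:
            break
        events.append(cut_ev)
        state = apply_event(state, cut_ev)
    # phase 2: fusions of same-target pieces
    while True:
        groups: dict[int, list[int]] = {}
        for ci, ch in enumerate(state):
            groups.setdefault(target_chrom[abs(ch[0])], []).append(ci)
        pick = None
        for t in sorted(groups):
            if len(groups[t]) > 1:
                pick = sorted(groups[t])[:2]
                break
        if pick is None:
            break
        best = None
        for flip_i in (0, 1):
            for flip_j in (0, 1):
                ev = Event("fusion", (pick[0], pick[1], flip_i, flip_j))
                h = dcj_distance(apply_event(state, ev), goal)
                if best is None or h < best[0]:
                    best = (h, ev)
        events.append(best[1])
        state = apply_event(state, best[1])
    # phase 3: exact reversal sorting per chromosome
    def perm_of(ch: Chromosome) -> list[int]:
        t = target_chrom[abs(ch[0])]
        lo = min(abs(x) for x in goal[t])
        return [x - lo + 1 if x > 0 else x + lo - 1 for x in ch]

    def chrom_distance(ch: Chromosome) -> int:
        fwd = perm_of(ch)
        rev = [-x for x in reversed(fwd)]
        return min(reversal_distance(fwd), reversal_distance(rev))

    while state != goal:
        progressed = False
        for ci, ch in enumerate(state):
            d0 = chrom_distance(ch)
            if d0 == 0:
                continue
            m = len(ch)
            for i in range(m):
                for j in range(i + 1, m + 1):
                    if i == 0 and j == m:
                        continue
                    ev = Event("inversion", (ci, i, j))
                    new_state = apply_event(state, ev)
                    new_d = sum(chrom_distance(c) for c in new_state)
                    if new_d < sum(chrom_distance(c) for c in state):
                        events.append(ev)
                        state = new_state
                        progressed = True
                        break
                if progressed:
                    break
            if progressed:
                break
        if not progressed:  # pragma: no cover - HP theory guarantees progress
            raise ValidationError("reversal descent stalled")
    return events


@dataclass
class EventCount:
    """Typed per-branch rearrangement counts."""

    branch: str
    n_inversions: int = 0
    n_fusions: int = 0
    n_fissions: int = 0
    n_breakpoints: int | None = None

    def __post_init__(self) -> None:
        if self.n_breakpoints is None:
            self.n_breakpoints = 2 * self.n_inversions + self.n_fissions

    @property
    def n_events(self) -> int:
        return self.n_inversions + self.n_fusions + self.n_fissions


def multichromosomal_scenario(
    a: BlockGenome,
    b: BlockGenome,
    node_cap: int = 100_000,
) -> tuple[EventCount, list[Event]]:
    """A parsimonious {inversion, fusion, fission} scenario from ``a`` to ``b``.

    The scenario is searched exactly (IDA* with the DCJ lower bound) and
    is minimum-length whenever the search completes within ``node_cap``
    node expansions; otherwise a constructive near-parsimonious fallback
    is used.  Replaying the returned events on ``a`` (relabelled against
    ``b``) reproduces ``b`` exactly.
    """
    sp = to_signed_permutation(a, b)
    start = canonical_state(sp.chromosomes)
    goal = canonical_state(sp.target_chromosomes)
    try:
        events = _ida_star(start, goal, node_cap)
    except _SearchCap:
        events = _constructive_scenario(start, goal)
    counts = EventCount(
        branch=f"{a.name}->{b.name}",
        n_inversions=sum(1 for e in events if e.kind == "inversion"),
        n_fusions=sum(1 for e in events if e.kind == "fusion"),
        n_fissions=sum(1 for e in events if e.kind == "fission"),
    )
    return counts, events


def replay_scenario(a: BlockGenome, b: BlockGenome, events: Iterable[Event]) -> bool:
    """True iff replaying ``events`` transforms ``a`` into ``b`` exactly."""
    sp = to_signed_permutation(a, b)
    state = canonical_state(sp.chromosomes)
    for ev in events:
        state = apply_event(state, ev)
    return state == canonical_state(sp.target_chromosomes)


def infer_branch_events(
    lineage: Sequence[BlockGenome], node_cap: int = 100_000
) -> list[EventCount]:
    """Typed event counts for each branch of an ordered root-to-tip lineage."""
    out = []
    for parent, child in zip(lineage, lineage[1:]):
        if parent.blocks != child.blocks:
            raise ValidationError(
                f"block universes differ between {parent.name!r} and {child.name!r}"
            )
        counts, _ = multichromosomal_scenario(parent, child, node_cap=node_cap)
        counts.branch = child.name
        out.append(counts)
    return out


# ---------------------------------------------------------------------------
# Fraction of a chromosome affected by rearrangements
# ---------------------------------------------------------------------------


def fraction_rearranged(
    ancestor: BlockGenome, chrom: str, other: BlockGenome
) -> tuple[float, float]:
    """(inter, intra) rearranged fractions of one ancestral chromosome.

    ``inter`` is the fraction of the chromosome's mapped length lying
    outside the single chromosome of ``other`` that carries the largest
    share.  ``intra`` is computed on that majority chromosome as one
    minus the fraction of length in the maximum-weight signed-colinear
    subsequence (blocks appearing in ancestral order and orientation, or
    entirely in reversed order with flipped orientation).
    """
    anc_blocks = ancestor.chromosomes[chrom]
    order = {abs(b): i for i, b in enumerate(anc_blocks)}
    sign = {abs(b): (1 if b > 0 else -1) for b in anc_blocks}
    lengths = ancestor.block_lengths
    share: dict[str, int] = {}
    placement: dict[int, tuple[str, int, int]] = {}
    for oc, blocks in other.chromosomes.items():
        for idx, b in enumerate(blocks):
            if abs(b) in order:
                share[oc] = share.get(oc, 0) + lengths[abs(b)]
                placement[abs(b)] = (oc, idx, 1 if b > 0 else -1)
    if not share:
        raise ValidationError(f"no blocks of {chrom!r} map to genome {other.name!r}")
    total = sum(share.values())
    major = min((c for c in share), key=lambda c: (-share[c], c))
    inter = 1.0 - share[major] / total
    # blocks of the ancestral chromosome in their order along the majority
    # chromosome, as (ancestral position, relative orientation, length)
    placed = sorted(
        (idx, order[blk], placement[blk][2] * sign[blk], lengths[blk])
        for blk, (oc, idx, s) in placement.items()
        if oc == major
    )
    seq = [(p, o, ln) for _, p, o, ln in placed]
    best = max(_max_colinear_weight(seq), _max_colinear_weight(_flip(seq)))
    intra = 1.0 - best / share[major]
    return inter, intra


def _flip(seq):
    return [(p, -o, ln) for p, o, ln in reversed(seq)]


def _max_colinear_weight(seq) -> int:
    """Maximum-weight subsequence with increasing positions and + orientation."""
    best: list[int] = []
    for i, (p, o, ln) in enumerate(seq):
        if o != 1:
            best.append(0)
            continue
        w = ln
        for j in range(i):
            if best[j] > 0 and seq[j][0] < p:
                w = max(w, best[j] + ln)
        best.append(w)
    return max(best, default=0)


# ---------------------------------------------------------------------------
# Orthology classification
# ---------------------------------------------------------------------------


def classify_orthology(
    correspondence: pd.DataFrame, completeness_tol: float = 0.95
) -> pd.DataFrame:
    """Label each chromosome of karyotype A against karyotype B.

    ``correspondence`` needs one row per orthologous segment with columns
    ``chrom_a``, ``chrom_b``, ``frac_a`` (fraction of chrom_a in the
    segment) and ``frac_b`` (fraction of chrom_b).  Labels:

    * ``1:1`` — A maps only to one B chromosome and vice versa, both
      covered to at least ``completeness_tol`` of their length;
    * ``1:n complete`` — A maps to n > 1 B chromosomes, each of which
      maps entirely (>= tol) back to A alone;
    * ``partial`` — anything else.
    """
    required = {"chrom_a", "chrom_b", "frac_a", "frac_b"}
    if correspondence.empty:
        raise ValidationError("empty correspondence map")
    if not required <= set(correspondence.columns):
        raise ValidationError(f"correspondence needs columns {sorted(required)}")
    by_a = correspondence.groupby("chrom_a")
    partners_of_b = correspondence.groupby("chrom_b")["chrom_a"].agg(
        lambda s: sorted(set(s))
    )
    rows = []
    for chrom_a, seg in by_a:
        partners = sorted(set(seg["chrom_b"]))
        a_complete = seg["frac_a"].sum() >= completeness_tol
        back_complete = all(
            partners_of_b[p] == [chrom_a]
            and seg.loc[seg["chrom_b"] == p, "frac_b"].sum() >= completeness_tol
            for p in partners
        )
        if len(partners) == 1 and a_complete and back_complete:
            label = "1:1"
        elif len(partners) > 1 and a_complete and back_complete:
            label = f"1:{len(partners)} complete"
        else:
            label = "partial"
        rows.append(
            {"chrom_a": chrom_a, "label": label, "partners": "+".join(map(str, partners))}
        )
    return pd.DataFrame(rows)
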