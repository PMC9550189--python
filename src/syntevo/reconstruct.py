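"""Ancestral chromosome-fragment reconstruction.

From per-species orthology block tables, the pipeline

1. cuts the reference coordinate axis wherever any genome interrupts
   colinearity and keeps maximal uncut segments at or above the chosen
   resolution as *syntenic fragments* (SFs);
2. scores every SF adjacency observed in at least one genome at a
   target ancestral node, weighting each genome by the inverse of its
   patristic distance (in My) to the target;
3. chains high-scoring adjacencies greedily into *reconstructed
   ancestral chromosome fragments* (RACFs), with deterministic
   tie-breaking;
4. optionally concatenates RACFs into ancestral chromosomes by a
   majority vote over descendant genomes (an automated stand-in for
   manual curation), logging every merge decision.

The adjacency scoring rule (inverse-distance weights, a 0.5 acceptance
threshold, and the requirement of support on both sides of the target
node) is this package's concretization of adjacency-probability
reconstruction; it is isolated behind the ``rule`` parameter of
:func:`assemble_racfs` so alternatives can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

from .core import (
    Adjacency,
    BlockGenome,
    DatedTree,
    HEAD,
    TAIL,
    Interval,
    ValidationError,
)

# ---------------------------------------------------------------------------
# Syntenic fragments
# ---------------------------------------------------------------------------


@dataclass
class SyntenicFragment:
    """A reference interval colinear in every genome of the analysis set."""

    id: int
    reference: Interval
    blocks: list[int]
    placements: dict[str, Interval]

    @property
    def length(self) -> int:
        return self.reference.length


def _species_order(table: pd.DataFrame, species: str):
    """Per-block position, chromosome and orientation in one species."""
    t = table.sort_values(["tgt_chrom", "tgt_start"], ignore_index=True)
    prev_end: dict[str, int] = {}
    for row in t.itertuples():
        if row.tgt_start < prev_end.get(row.tgt_chrom, 0):
            raise ValidationError(
                f"overlapping intervals in orthology table of {species!r} "
                f"on {row.tgt_chrom} at {row.tgt_start}"
            )
        prev_end[row.tgt_chrom] = row.tgt_end
    pos = {row.block: i for i, row in enumerate(t.itertuples())}
    chrom = dict(zip(t["block"], t["tgt_chrom"]))
    orient = dict(zip(t["block"], t["orientation"]))
    coords = {row.block: (row.tgt_start, row.tgt_end) for row in t.itertuples()}
    return pos, chrom, orient, coords


def detect_sfs(
    orthology: Mapping[str, pd.DataFrame], resolution: int
) -> tuple[list[SyntenicFragment], list[Interval]]:
    """Cut the reference axis into syntenic fragments.

    Returns (fragments, unplaced): maximal runs of reference blocks that
    every genome keeps colinear (same target chromosome, consecutive
    order, consistent orientation), kept if at least ``resolution`` bp
    on the reference; shorter runs are reported as unplaced intervals.
    """
    if resolution <= 0:
        raise ValidationError("resolution must be > 0")
    if not orthology:
        raise ValidationError("need at least one orthology table")
    first = next(iter(orthology.values()))
    ref = first.sort_values(["ref_chrom", "ref_start"], ignore_index=True)
    species_data = {
        sp: _species_order(tab, sp) for sp, tab in orthology.items()
    }

    def junction_intact(u: int, v: int) -> bool:
        for pos, chrom, orient, _ in species_data.values():
            if chrom[u] != chrom[v] or orient[u] != orient[v]:
                return False
            step = pos[v] - pos[u]
            if orient[u] == 1 and step != 1:
                return False
            if orient[u] == -1 and step != -1:
                return False
        return True

    runs: list[list] = []
    current: list = []
    prev = None
    for row in ref.itertuples():
        if prev is not None and (
            row.ref_chrom != prev.ref_chrom or not junction_intact(prev.block, row.block)
        ):
            runs.append(current)
            current = []
        current.append(row)
        prev = row
    if current:
        runs.append(current)

    sfs: list[SyntenicFragment] = []
    unplaced: list[Interval] = []
    nxt = 1
    for run in runs:
        start, end = run[0].ref_start, run[-1].ref_end
        iv = Interval(run[0].ref_chrom, start, end)
        if iv.length < resolution:
            unplaced.append(iv)
            continue
        placements: dict[str, Interval] = {}
        for sp, (pos, chrom, orient, coords) in species_data.items():
            cs = [coords[r.block] for r in run]
            strand = int(orient[run[0].block])
            placements[sp] = Interval(
                chrom[run[0].block],
                min(s for s, _ in cs),
                max(e for _, e in cs),
                strand,
            )
        sfs.append(
            SyntenicFragment(nxt, iv, [r.block for r in run], placements)
        )
        nxt += 1
    return sfs, unplaced


def sf_level_genome(
    sfs: Sequence[SyntenicFragment], species: str, name: str | None = None
) -> BlockGenome:
    """Express one genome of the analysis set as ordered signed SFs."""
    order = sorted(
        sfs, key=lambda s: (s.placements[species].chromosome, s.placements[species].start)
    )
    chroms: dict[str, list[int]] = {}
    for sf in order:
        p = sf.placements[species]
        chroms.setdefault(p.chromosome, []).append(sf.id * p.strand)
    return BlockGenome(
        name or species, chroms, {sf.id: sf.length for sf in sfs}
    )


def project_sf_genome(
    sfs: Sequence[SyntenicFragment],
    table: pd.DataFrame,
    name: str,
) -> BlockGenome:
    """Project SFs into any genome given its orthology block table.

    Used to express internal-node genomes (known in simulations) on the
    SF universe; the SF's orientation is taken from its first block.
    """
    t = table.set_index("block")
    entries = []
    for sf in sfs:
        rows = t.loc[sf.blocks]
        chroms = set(rows["tgt_chrom"])
        if len(chroms) != 1:
            raise ValidationError(f"SF {sf.id} is not contiguous in {name!r}")
        entries.append(
            (
                rows["tgt_chrom"].iloc[0],
                int(rows["tgt_start"].min()),
                sf.id * int(rows["orientation"].iloc[0]),
            )
        )
    chroms_out: dict[str, list[int]] = {}
    for chrom, _, signed in sorted(entries):
        chroms_out.setdefault(chrom, []).append(signed)
    return BlockGenome(name, chroms_out, {sf.id: sf.length for sf in sfs})


# ---------------------------------------------------------------------------
# Adjacency scoring
# ---------------------------------------------------------------------------


@dataclass
class AdjacencyScore:
    """Phylogeny-weighted support for one SF adjacency at a target node.

    ``sided`` is True when support exists on both sides of the target:
    at least one descendant tip plus either an outgroup tip or tips from
    both child subtrees of the target.
    """

    adjacency: Adjacency
    score: float
    supporters: list[str]
    sided: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0 + 1e-12:
            raise ValidationError(f"score must lie in [0, 1], got {self.score}")


def observed_adjacencies(
    sfs: Sequence[SyntenicFragment], species: str
) -> set[Adjacency]:
    """SF adjacencies realized in one genome."""
    genome = sf_level_genome(sfs, species)
    from .core import adjacencies_of

    return adjacencies_of(genome)


def score_adjacencies(
    sfs: Sequence[SyntenicFragment],
    tree: DatedTree,
    target: str,
) -> list[AdjacencyScore]:
    """Score every SF adjacency observed in at least one analysis genome."""
    if tree.is_tip(target):
        raise ValidationError("target node must be internal")
    species = sorted(set(next(iter(sfs)).placements) & set(tree.tips())) if sfs else []
    if not species:
        raise ValidationError("no placed genomes correspond to tree tips")
    weights = {sp: 1.0 / tree.patristic(sp, target) for sp in species}
    wsum = sum(weights.values())
    support: dict[Adjacency, list[str]] = {}
    for sp in species:
        for adj in observed_adjacencies(sfs, sp):
            support.setdefault(adj, []).append(sp)
    child_a, child_b = tree.children(target)
    out = []
    for adj in sorted(support):
        sup = sorted(support[adj])
        score = sum(weights[sp] for sp in sup) / wsum
        in_a = any(tree.is_descendant(sp, child_a) for sp in sup)
        in_b = any(tree.is_descendant(sp, child_b) for sp in sup)
        outgroup = any(not tree.is_descendant(sp, target) for sp in sup)
        sided = (in_a or in_b) and (outgroup or (in_a and in_b))
        out.append(AdjacencyScore(adj, score, sup, sided))
    return out


# ---------------------------------------------------------------------------
# RACF assembly
# ---------------------------------------------------------------------------


@dataclass
class RACF:
    """An ordered, oriented chain of SFs forming an ancestral fragment."""

    id: int
    sfs: list[int]  # signed SF ids, left to right
    target: str | None = None

    def adjacencies(self) -> set[Adjacency]:
        out = set()
        for x, y in zip(self.sfs, self.sfs[1:]):
            out.add(
                Adjacency(
                    (abs(x), HEAD if x > 0 else TAIL),
                    (abs(y), TAIL if y > 0 else HEAD),
                )
            )
        return out

    @property
    def ends(self) -> tuple[tuple[int, str], tuple[int, str]]:
        first, last = self.sfs[0], self.sfs[-1]
        return (
            (abs(first), TAIL if first > 0 else HEAD),
            (abs(last), HEAD if last > 0 else TAIL),
        )


def default_acceptance_rule(score: AdjacencyScore) -> bool:
    """Accept an adjacency on two-sided support.

    Support from at least one descendant of the target plus either an
    outgroup genome or the second child clade implies, under a
    Dollo-style view of adjacencies (broken junctions are effectively
    never re-formed), that the adjacency existed at the target node.
    The weighted score is not thresholded here; it orders candidates in
    the greedy chaining, so conflicting adjacencies resolve toward the
    better-supported one.  A pure weighted-majority cutoff is available
    as :func:`weighted_majority_rule`, but it mis-dates breaks occurring
    just below nodes whose child clades are of very different sizes (the
    depleted clade outvotes the intact side).
    """
    return score.sided


def weighted_majority_rule(score: AdjacencyScore) -> bool:
    """Accept iff the inverse-distance weighted support exceeds 0.5 and
    the adjacency has two-sided support."""
    return score.score > 0.5 and score.sided


def _chain_paths(
    members: Iterable[int], accepted: Iterable[Adjacency]
) -> list[list[int]]:
    """Assemble vertex-disjoint paths of signed elements from adjacencies."""
    link: dict[tuple[int, str], tuple[int, str]] = {}
    for adj in accepted:
        a, b = adj.ends()
        link[a] = b
        link[b] = a
    paths = []
    placed: set[int] = set()
    for start in sorted(members):
        if start in placed:
            continue
        # walk to one end of the path containing `start`
        end = (start, TAIL)
        seen = {start}
        while link.get(end) is not None:
            nxt_sf = link[end][0]
            if nxt_sf in seen:  # safety; accepted edges never form cycles
                break
            seen.add(nxt_sf)
            other = HEAD if link[end][1] == TAIL else TAIL
            end = (nxt_sf, other)
        # traverse from that end
        seq = []
        cur_sf, cur_ext = end
        while True:
            placed.add(cur_sf)
            seq.append(cur_sf if cur_ext == TAIL else -cur_sf)
            out_ext = HEAD if cur_ext == TAIL else TAIL
            nxt = link.get((cur_sf, out_ext))
            if nxt is None or nxt[0] in placed:
                break
            cur_sf, cur_ext = nxt
        rev = [-x for x in reversed(seq)]
        # canonical reading: prefer the direction starting at the smaller
        # fragment id, forward strand first
        paths.append(min(seq, rev, key=lambda s: (abs(s[0]), s[0] < 0, s)))
    return paths


def assemble_racfs(
    scores: Sequence[AdjacencyScore],
    rule: Callable[[AdjacencyScore], bool] = default_acceptance_rule,
    sf_ids: Iterable[int] | None = None,
    target: str | None = None,
) -> list[RACF]:
    """Greedy path-growing over scored adjacencies.

    Adjacencies are visited by (score desc, sided first, adjacency id)
    and accepted iff both extremities are still free and the acceptance
    rule passes.  Every SF ends up in exactly one RACF (singletons
    allowed); ties resolve to the lexicographically smaller adjacency,
    so output is identical across runs.
    """
    used: set[tuple[int, str]] = set()
    accepted: list[Adjacency] = []
    for sc in sorted(scores, key=lambda s: (-s.score, not s.sided, s.adjacency)):
        if not rule(sc):
            continue
        a, b = sc.adjacency.ends()
        if a in used or b in used:
            continue
        used.update((a, b))
        accepted.append(sc.adjacency)
    members = set(sf_ids) if sf_ids is not None else {
        end[0] for sc in scores for end in sc.adjacency.ends()
    }
    paths = _chain_paths(members, accepted)
    paths.sort(key=lambda p: min(abs(x) for x in p))
    return [RACF(i + 1, p, target) for i, p in enumerate(paths)]


def racf_adjacencies(racfs: Iterable[RACF]) -> set[Adjacency]:
    out: set[Adjacency] = set()
    for r in racfs:
        out |= r.adjacencies()
    return out


# ---------------------------------------------------------------------------
# RACF ordering into ancestral chromosomes
# ---------------------------------------------------------------------------


def order_racfs(
    racfs: Sequence[RACF],
    descendant_genomes: Mapping[str, BlockGenome],
    sf_lengths: Mapping[int, int],
    majority: float = 2 / 3,
    name: str = "ancestor",
) -> tuple[BlockGenome, list[dict]]:
    """Concatenate RACFs into chromosomes by descendant majority vote.

    ``descendant_genomes`` are SF-level genomes of descendants of the
    target node.  A junction between two RACF ends is accepted when it
    is realized, in consistent orientation, in at least ``majority`` of
    the descendants; ties and minority junctions leave the RACFs
    unmerged.  Returns the ancestral genome (chromosomes of signed SF
    ids) and a log of every candidate merge decision.
    """
    racf_of: dict[int, RACF] = {}
    for r in racfs:
        for s in r.sfs:
            racf_of[abs(s)] = r
    votes: dict[Adjacency, int] = {}
    n_desc = len(descendant_genomes)
    for g in descendant_genomes.values():
        for blocks in g.chromosomes.values():
            runs: list[tuple[RACF, list[int]]] = []
            for s in blocks:
                r = racf_of[abs(s)]
                if runs and runs[-1][0] is r:
                    runs[-1][1].append(s)
                else:
                    runs.append((r, [s]))
            for (r1, seq1), (r2, seq2) in zip(runs, runs[1:]):
                if r1 is r2:
                    continue
                # right end of r1's occurrence must align with a terminal SF
                right: tuple[int, str] | None = None
                if seq1[-1] == r1.sfs[-1]:
                    right = r1.ends[1]
                elif seq1[-1] == -r1.sfs[0]:
                    right = r1.ends[0]
                left: tuple[int, str] | None = None
                if seq2[0] == r2.sfs[0]:
                    left = r2.ends[0]
                elif seq2[0] == -r2.sfs[-1]:
                    left = r2.ends[1]
                if right is None or left is None:
                    continue
                adj = Adjacency(
                    (r1.id, right[1]), (r2.id, left[1])
                )
                votes[adj] = votes.get(adj, 0) + 1
    used: set[tuple[int, str]] = set()
    accepted: list[Adjacency] = []
    decisions: list[dict] = []
    for adj in sorted(votes, key=lambda a: (-votes[a], a)):
        ok = votes[adj] / n_desc >= majority
        a, b = adj.ends()
        free = a not in used and b not in used
        decisions.append(
            {
                "junction": repr(adj),
                "votes": votes[adj],
                "n_descendants": n_desc,
                "accepted": bool(ok and free),
            }
        )
        if ok and free:
            used.update((a, b))
            accepted.append(adj)
    paths = _chain_paths({r.id for r in racfs}, accepted)
    paths.sort(key=lambda p: min(abs(x) for x in p))
    chroms: dict[str, list[int]] = {}
    by_id = {r.id: r for r in racfs}
    for i, path in enumerate(paths):
        seq: list[int] = []
        for signed_racf in path:
            r = by_id[abs(signed_racf)]
            seq.extend(r.sfs if signed_racf > 0 else [-x for x in reversed(r.sfs)])
        chroms[f"anc{i + 1}"] = seq
    genome = BlockGenome(name, chroms, dict(sf_lengths))
    return genome, decisions


# ---------------------------------------------------------------------------
# Consistency between reconstructions
# ---------------------------------------------------------------------------


def compare_reconstructions(
    recon_a: Sequence[RACF],
    recon_b: Sequence[RACF],
    sfs: Sequence[SyntenicFragment],
) -> tuple[pd.DataFrame, float]:
    """Classify A's SF adjacencies against reconstruction B.

    maintained: present in both; extra: absent from B with both flanking
    extremities free there (fragment ends); inconsistent: contradicted
    by a different adjacency in B.  The returned fraction is the
    cumulative reference length of SFs flanking inconsistent adjacencies
    over the total reconstruction length.
    """
    sf_a = {abs(s) for r in recon_a for s in r.sfs}
    sf_b = {abs(s) for r in recon_b for s in r.sfs}
    if sf_a != sf_b:
        raise ValidationError("reconstructions use different SF universes")
    adj_a = racf_adjacencies(recon_a)
    adj_b = racf_adjacencies(recon_b)
    used_b: set[tuple[int, str]] = set()
    for adj in adj_b:
        used_b.update(adj.ends())
    rows = []
    bad_sfs: set[int] = set()
    for adj in sorted(adj_a):
        if adj in adj_b:
            cls = "maintained"
        elif all(end not in used_b for end in adj.ends()):
            cls = "extra"
        else:
            cls = "inconsistent"
            bad_sfs.update(end[0] for end in adj.ends())
        rows.append({"adjacency": repr(adj), "class": cls})
    lengths = {sf.id: sf.length for sf in sfs}
    total = sum(lengths[i] for i in sf_a)
    frac = sum(lengths[i] for i in bad_sfs) / total if total else 0.0
    return pd.DataFrame(rows), frac
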