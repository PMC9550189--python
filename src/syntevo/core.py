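"""Domain types shared by every pipeline stage.

The universal currency of the pipeline is the :class:`BlockGenome`: a
karyotype expressed as ordered, signed synteny blocks per chromosome,
with block lengths in bp.  Orientation is carried as the sign of the
block identifier, so permutation algebra (rearrangement distances) and
adjacency algebra (reconstruction, breakpoint detection) share one
representation.

All coordinates are 0-based, half-open.  Chromosomes are unordered
within a genome; any ordering in output files is display-only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

HEAD = "head"
TAIL = "tail"


class ValidationError(ValueError):
    """Raised when a domain object violates its invariants."""


# ---------------------------------------------------------------------------
# Intervals
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """A 0-based, half-open genomic interval.

    ``strand`` is +1/-1 for oriented intervals and 0 when orientation is
    not meaningful (annotation tracks, windows).
    """

    chromosome: str
    start: int
    end: int
    strand: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValidationError(
                f"invalid interval [{self.start}, {self.end}) on {self.chromosome}"
            )
        if self.strand not in (-1, 0, 1):
            raise ValidationError(f"strand must be -1, 0 or +1, got {self.strand}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return interval_overlap(self, other) > 0


def interval_overlap(a: Interval, b: Interval) -> int:
    """Overlap length in bp between two intervals (0 if different chromosomes)."""
    if a.chromosome != b.chromosome:
        return 0
    return max(0, min(a.end, b.end) - max(a.start, b.start))


def merge_intervals(intervals: Iterable[Interval]) -> list[Interval]:
    """Union of intervals as a sorted list of maximal disjoint intervals."""
    by_chrom: dict[str, list[Interval]] = {}
    for iv in intervals:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    out: list[Interval] = []
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom], key=lambda v: v.start)
        cur_s, cur_e = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_e:
                cur_e = max(cur_e, iv.end)
            else:
                out.append(Interval(chrom, cur_s, cur_e))
                cur_s, cur_e = iv.start, iv.end
        out.append(Interval(chrom, cur_s, cur_e))
    return out


def intersect_interval_sets(
    a: Iterable[Interval], b: Iterable[Interval]
) -> list[Interval]:
    """Intersection of two interval sets (each merged first)."""
    am = merge_intervals(a)
    bm = merge_intervals(b)
    out: list[Interval] = []
    by_chrom: dict[str, list[Interval]] = {}
    for iv in bm:
        by_chrom.setdefault(iv.chromosome, []).append(iv)
    for iv in am:
        for other in by_chrom.get(iv.chromosome, []):
            s, e = max(iv.start, other.start), min(iv.end, other.end)
            if s < e:
                out.append(Interval(iv.chromosome, s, e))
    return sorted(out)


def complement_intervals(
    intervals: Iterable[Interval], chrom_lengths: Mapping[str, int]
) -> list[Interval]:
    """Regions of each chromosome not covered by ``intervals``."""
    merged = merge_intervals(intervals)
    by_chrom: dict[str, list[Interval]] = {c: [] for c in chrom_lengths}
    for iv in merged:
        if iv.chromosome in by_chrom:
            by_chrom[iv.chromosome].append(iv)
    out: list[Interval] = []
    for chrom in sorted(chrom_lengths):
        pos = 0
        for iv in by_chrom[chrom]:
            if iv.start > pos:
                out.append(Interval(chrom, pos, iv.start))
            pos = max(pos, iv.end)
        if pos < chrom_lengths[chrom]:
            out.append(Interval(chrom, pos, chrom_lengths[chrom]))
    return out


def total_span(intervals: Iterable[Interval]) -> int:
    """Total bp covered by a set of intervals (after merging overlaps)."""
    return sum(iv.length for iv in merge_intervals(intervals))


# ---------------------------------------------------------------------------
# Adjacencies
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Adjacency:
    """An unordered pair of block extremities joined on a chromosome.

    ``Adjacency((1, HEAD), (2, TAIL))`` and ``Adjacency((2, TAIL), (1, HEAD))``
    compare equal; the constructor stores the two ends in sorted order.
    """

    left: tuple[int, str]
    right: tuple[int, str]

    def __init__(self, left: tuple[int, str], right: tuple[int, str]):
        for end in (left, right):
            if end[1] not in (HEAD, TAIL):
                raise ValidationError(f"extremity must be head/tail, got {end[1]}")
        if left == right:
            raise ValidationError("adjacency must join two distinct extremities")
        a, b = sorted((tuple(left), tuple(right)))
        object.__setattr__(self, "left", a)
        object.__setattr__(self, "right", b)

    def ends(self) -> tuple[tuple[int, str], tuple[int, str]]:
        return (self.left, self.right)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"({self.left[0]}.{self.left[1]}--{self.right[0]}.{self.right[1]})"


def _right_end(block: int) -> tuple[int, str]:
    """Extremity presented on the right side of a signed block."""
    return (abs(block), HEAD if block > 0 else TAIL)


def _left_end(block: int) -> tuple[int, str]:
    """Extremity presented on the left side of a signed block."""
    return (abs(block), TAIL if block > 0 else HEAD)


# ---------------------------------------------------------------------------
# Block genomes
# ---------------------------------------------------------------------------


@dataclass
class BlockGenome:
    """A karyotype as ordered, signed synteny blocks per chromosome.

    Parameters
    ----------
    name:
        Species or ancestral-node label.
    chromosomes:
        Mapping chromosome label -> ordered sequence of signed block ids.
        A block with a negative sign lies in reverse orientation.
    block_lengths:
        Mapping block id (unsigned) -> length in bp.
    """

    name: str
    chromosomes: dict[str, list[int]]
    block_lengths: dict[int, int]

    def __post_init__(self) -> None:
        self.chromosomes = {c: list(v) for c, v in self.chromosomes.items()}
        self.block_lengths = dict(self.block_lengths)
        self.validate()

    def validate(self) -> None:
        seen: set[int] = set()
        for chrom, blocks in self.chromosomes.items():
            if not blocks:
                raise ValidationError(f"chromosome {chrom!r} of {self.name!r} is empty")
            for b in blocks:
                if b == 0:
                    raise ValidationError("block id 0 is not allowed")
                if abs(b) in seen:
                    raise ValidationError(
                        f"block {abs(b)} appears more than once in genome {self.name!r}"
                    )
                seen.add(abs(b))
                if abs(b) not in self.block_lengths:
                    raise ValidationError(f"missing length for block {abs(b)}")
        for b, ln in self.block_lengths.items():
            if ln <= 0:
                raise ValidationError(f"block {b} has non-positive length {ln}")

    # -- basic accessors ---------------------------------------------------

    @property
    def blocks(self) -> set[int]:
        return {abs(b) for blocks in self.chromosomes.values() for b in blocks}

    @property
    def n_blocks(self) -> int:
        return sum(len(v) for v in self.chromosomes.values())

    @property
    def n_chromosomes(self) -> int:
        return len(self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(self.block_lengths[abs(b)] for bl in self.chromosomes.values() for b in bl)

    def chromosome_length(self, chrom: str) -> int:
        return sum(self.block_lengths[abs(b)] for b in self.chromosomes[chrom])

    def layout(self) -> dict[int, Interval]:
        """Place every block on this genome's own coordinate frame.

        Blocks tile each chromosome contiguously in listed order; strand
        reflects the block sign.
        """
        out: dict[int, Interval] = {}
        for chrom, blocks in self.chromosomes.items():
            pos = 0
            for b in blocks:
                ln = self.block_lengths[abs(b)]
                out[abs(b)] = Interval(chrom, pos, pos + ln, 1 if b > 0 else -1)
                pos += ln
        return out

    def chromosome_lengths(self) -> dict[str, int]:
        return {c: self.chromosome_length(c) for c in self.chromosomes}

    def copy(self, name: str | None = None) -> "BlockGenome":
        return BlockGenome(
            name if name is not None else self.name,
            {c: list(v) for c, v in self.chromosomes.items()},
            dict(self.block_lengths),
        )


def adjacencies_of(genome: BlockGenome) -> set[Adjacency]:
    """The set of internal block adjacencies of a genome.

    One adjacency per pair of consecutive blocks on each chromosome; the
    extremity presented at the junction follows the block sign (a block
    with sign -1 presents tail first).  Chromosome ends contribute no
    telomeric adjacency, so ``|adjacencies| = B - C`` for B blocks on C
    chromosomes.
    """
    out: set[Adjacency] = set()
    for blocks in genome.chromosomes.values():
        for x, y in zip(blocks, blocks[1:]):
            out.add(Adjacency(_right_end(x), _left_end(y)))
    return out


# ---------------------------------------------------------------------------
# Dated phylogeny
# ---------------------------------------------------------------------------


class DatedTree:
    """A rooted binary phylogeny with unique node labels and branch lengths in My.

    Thin wrapper around a :class:`dendropy.Tree` exposing the lookups the
    pipeline needs: parent/children, branch durations, patristic
    distances from tips to internal nodes, and root-to-tip lineages.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._nodes: dict[str, dendropy.Node] = {}
        for node in tree.preorder_node_iter():
            label = node.taxon.label if node.taxon is not None else node.label
            if label is None:
                raise ValidationError("every node needs a label (tips and internals)")
            label = str(label)
            if label in self._nodes:
                raise ValidationError(f"duplicate node label {label!r}")
            node.label = label
            self._nodes[label] = node
            if node.parent_node is not None:
                if node.edge.length is None or node.edge.length <= 0:
                    raise ValidationError(
                        f"branch above {label!r} must have positive length"
                    )
        root = tree.seed_node
        for node in tree.preorder_node_iter():
            kids = node.child_nodes()
            if kids and len(kids) != 2:
                raise ValidationError(
                    f"tree must be binary; node {node.label!r} has {len(kids)} children"
                )
        self._depth: dict[str, float] = {}
        self._parent: dict[str, str | None] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                self._depth[node.label] = 0.0
                self._parent[node.label] = None
            else:
                self._depth[node.label] = (
                    self._depth[node.parent_node.label] + node.edge.length
                )
                self._parent[node.label] = node.parent_node.label
        self.root = root.label

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_newick(cls, newick: str) -> "DatedTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", suppress_internal_node_taxa=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    # -- queries -----------------------------------------------------------

    @property
    def labels(self) -> list[str]:
        return list(self._nodes)

    def tips(self) -> list[str]:
        return [n.label for n in self._tree.leaf_node_iter()]

    def internal_labels(self) -> list[str]:
        return [n.label for n in self._tree.preorder_node_iter() if not n.is_leaf()]

    def is_tip(self, label: str) -> bool:
        return self._nodes[label].is_leaf()

    def parent(self, label: str) -> str | None:
        return self._parent[label]

    def children(self, label: str) -> list[str]:
        return [c.label for c in self._nodes[label].child_nodes()]

    def branch_length(self, label: str) -> float:
        """Duration in My of the branch ending at ``label``."""
        node = self._nodes[label]
        if node.parent_node is None:
            raise ValidationError("the root has no branch above it")
        return float(node.edge.length)

    def branches(self) -> list[tuple[str, str, float]]:
        """All (parent, child, duration) branches in preorder."""
        out = []
        for node in self._tree.preorder_node_iter():
            if node.parent_node is not None:
                out.append((node.parent_node.label, node.label, float(node.edge.length)))
        return out

    def lineage(self, label: str) -> list[str]:
        """Node labels from the root down to ``label`` (inclusive)."""
        path = [label]
        while self._parent[path[-1]] is not None:
            path.append(self._parent[path[-1]])
        return path[::-1]

    def is_descendant(self, label: str, ancestor: str) -> bool:
        """True if ``label`` lies strictly below ``ancestor`` (or equals it)."""
        return ancestor in self.lineage(label)

    def mrca(self, a: str, b: str) -> str:
        la, lb = self.lineage(a), self.lineage(b)
        last = la[0]
        for x, y in zip(la, lb):
            if x != y:
                break
            last = x
        return last

    def patristic(self, a: str, b: str) -> float:
        """Path length in My between two nodes."""
        m = self.mrca(a, b)
        return self._depth[a] + self._depth[b] - 2 * self._depth[m]

    def descendant_tips(self, label: str) -> list[str]:
        return [t for t in self.tips() if self.is_descendant(t, label)]

    def validate_tips(self, genome_names: Iterable[str]) -> None:
        names = set(genome_names)
        tips = set(self.tips())
        if not names <= set(self.labels):
            missing = sorted(names - set(self.labels))
            raise ValidationError(f"genome names not in tree: {missing}")
        if not tips <= names and not names <= tips:
            # informational only; pipelines may restrict to a subset of tips
            pass
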