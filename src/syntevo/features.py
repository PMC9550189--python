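"""Evolutionary breakpoint regions and multispecies synteny blocks.

EBRs are called only within reconstructed fragments: a reference-frame
junction whose SF adjacency is intact in a branch's parent but broken
in its child yields one EBR spanning the reference gap between the
flanking SFs, assigned to the first branch where the break appears.
Breakpoint reuse is assessed for EBRs below a size gate (default
300 kbp, chosen to avoid misclassifying chained EBRs as reuse) against
EBRs from independent lineages — lineages whose defining branches share
no edge on the tree.

msHSBs are maximal reference intervals covered colinearly in *every*
genome of the analysis set (strict intersection of per-species covered
sets), filtered to a minimum length that shares one configuration knob
with the SF resolution (default 300 kbp).  The expected maximum msHSB
length under an exponential length model is ``mu * H_n`` (harmonic sum),
and the tail probability of the observed maximum is
``1 - (1 - exp(-x/mu))**n``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    Adjacency,
    BlockGenome,
    DatedTree,
    Interval,
    ValidationError,
    interval_overlap,
    merge_intervals,
)
from .reconstruct import RACF, SyntenicFragment, racf_adjacencies

# ---------------------------------------------------------------------------
# EBR detection
# ---------------------------------------------------------------------------


@dataclass
class EBR:
    """An evolutionary breakpoint region on the reference frame."""

    interval: Interval
    branch: str
    placeholder: bool = False  # zero-width gap widened to 1 bp
    reuse: bool = False
    reuse_lineages: list[str] = field(default_factory=list)
    centromere_associated: bool = False


def detect_ebrs(
    lineage: Sequence[tuple[str, set[Adjacency] | Sequence[RACF] | BlockGenome]],
    sfs: Sequence[SyntenicFragment],
    centromeres: Iterable[Interval] = (),
) -> list[EBR]:
    """Call EBRs along an ordered root-to-tip lineage of reconstructions.

    ``lineage`` pairs node labels with that node's SF-level structure
    (a set of adjacencies, a list of RACFs, or an SF-level genome); the
    first entry is the baseline ancestor.  Junctions are classified only
    within fragments: a baseline adjacency intact in the parent and
    absent from the child yields an EBR on the branch to the child.
    """
    if len(lineage) < 2:
        raise ValidationError("lineage needs a baseline plus at least one node")
    adj_sets: list[tuple[str, set[Adjacency]]] = []
    for label, obj in lineage:
        if isinstance(obj, BlockGenome):
            from .core import adjacencies_of

            adj_sets.append((label, adjacencies_of(obj)))
        elif isinstance(obj, set):
            adj_sets.append((label, obj))
        else:
            adj_sets.append((label, racf_adjacencies(obj)))
    by_id = {sf.id: sf for sf in sfs}
    baseline_label, baseline = adj_sets[0]
    centromeres = list(centromeres)
    out: list[EBR] = []
    broken: set[Adjacency] = set()
    for (p_label, parent), (c_label, child) in zip(adj_sets, adj_sets[1:]):
        for adj in sorted(baseline):
            if adj in broken or adj not in parent or adj in child:
                continue
            broken.add(adj)
            (ia, _), (ib, _) = adj.ends()
            sa, sb = by_id[ia].reference, by_id[ib].reference
            if sa.chromosome == sb.chromosome:
                left, right = sorted((sa, sb), key=lambda v: v.start)
                if right.start > left.end:
                    iv, ph = Interval(sa.chromosome, left.end, right.start), False
                else:
                    iv, ph = Interval(sa.chromosome, left.end, left.end + 1), True
            else:
                # breakage between SFs on different reference chromosomes can
                # only arise from a non-reference baseline; anchor at the end
                # of the lower-id flank
                iv, ph = Interval(sa.chromosome, sa.end, sa.end + 1), True
            cen = any(interval_overlap(iv, c) > 0 for c in centromeres)
            out.append(EBR(iv, c_label, placeholder=ph, centromere_associated=cen))
    return out


def classify_reuse(
    ebrs: Iterable[EBR], tree: DatedTree, max_len: int = 300_000
) -> list[EBR]:
    """Flag breakpoint reuse across independent lineages.

    An EBR shorter than ``max_len`` is reuse iff its interval overlaps a
    same-gated EBR whose branch lies on a different root-to-tip path
    (neither branch ancestral to the other).  Larger EBRs are never
    classified as reuse (EBR chaining would inflate the call).
    """
    ebrs = list(ebrs)
    gated = [e for e in ebrs if e.interval.length < max_len]

    def independent(b1: str, b2: str) -> bool:
        if b1 == b2:
            return False
        return not (
            tree.is_descendant(b1, b2) or tree.is_descendant(b2, b1)
        )

    for e in ebrs:
        e.reuse = False
        e.reuse_lineages = []
    for e in gated:
        partners = sorted(
            {
                o.branch
                for o in gated
                if independent(e.branch, o.branch)
                and interval_overlap(e.interval, o.interval) > 0
            }
        )
        if partners:
            e.reuse = True
            e.reuse_lineages = partners
    return ebrs


# ---------------------------------------------------------------------------
# msHSB detection
# ---------------------------------------------------------------------------


@dataclass
class MsHSB:
    """A reference interval conserved un-rearranged in every analysis genome."""

    interval: Interval
    placement_lengths: dict[str, int] = field(default_factory=dict)


def detect_mshsbs(
    coverage: Mapping[str, Sequence[Interval]],
    min_len: int = 300_000,
    orthology: Mapping[str, pd.DataFrame] | None = None,
) -> list[MsHSB]:
    """Maximal intervals covered colinearly in all species.

    ``coverage`` maps each species to its colinearly covered reference
    intervals (typically SF reference intervals from a pairwise run
    against that species alone).  The strict intersection across all
    species, filtered to ``min_len``, gives the msHSBs.  When orthology
    tables are supplied, per-species placement lengths are measured
    through them.
    """
    if not coverage:
        raise ValidationError("need at least one species coverage set")
    for sp, ivs in coverage.items():
        if not ivs:
            raise ValidationError(f"species {sp!r} has empty coverage")
    species = sorted(coverage)
    common = merge_intervals(coverage[species[0]])
    for sp in species[1:]:
        from .core import intersect_interval_sets

        common = intersect_interval_sets(common, coverage[sp])
        if not common:
            break
    out = []
    for iv in common:
        if iv.length < min_len:
            continue
        placements: dict[str, int] = {}
        if orthology is not None:
            for sp, tab in orthology.items():
                ln = 0
                for row in tab.itertuples():
                    ov = interval_overlap(
                        iv, Interval(row.ref_chrom, row.ref_start, row.ref_end)
                    )
                    ln += ov
                placements[sp] = ln
        out.append(MsHSB(iv, placements))
    return out


# ---------------------------------------------------------------------------
# Exponential maximum-length test
# ---------------------------------------------------------------------------


def max_mshsb_test(lengths: Sequence[float]) -> tuple[float, float]:
    """Expected maximum under an exponential length model, and the
    tail probability of the observed maximum.

    With mean length mu and n blocks, the expected maximum of n i.i.d.
    exponentials is ``mu * H_n`` with ``H_n = sum_{k=1..n} 1/k``, and
    ``P(max >= x_obs) = 1 - (1 - exp(-x_obs/mu))**n``.
    """
    lengths = np.asarray(lengths, float)
    if lengths.size == 0 or np.any(lengths <= 0):
        raise ValidationError("lengths must be positive and non-empty")
    n = lengths.size
    mu = lengths.mean()
    h_n = sum(1.0 / k for k in range(1, n + 1))
    expected_max = mu * h_n
    x = lengths.max()
    p = 1.0 - (1.0 - math.exp(-x / mu)) ** n
    return float(expected_max), float(p)


# ---------------------------------------------------------------------------
# Region preparation for enrichment analyses
# ---------------------------------------------------------------------------


def prepare_region_sets(
    ebrs: Sequence[EBR],
    mshsbs: Sequence[MsHSB],
    chrom_lengths: Mapping[str, int],
    min_ebr_width: int = 300_000,
) -> tuple[list[EBR], list[Interval]]:
    """Disjoint region sets for window classification.

    EBR calls are point-like on a contiguous block frame, so each
    non-centromeric EBR is expanded symmetrically to at least
    ``min_ebr_width`` (default 300 kbp, the upper end of typical EBR
    extents, wide enough for gene-scale windows to sit fully inside)
    before window containment tests; overlaps between expanded EBRs are
    split at the midpoint, and msHSB intervals are trimmed wherever an
    expanded EBR claims the space.  Centromere-associated EBRs are
    excluded entirely.
    """
    kept = [e for e in ebrs if not e.centromere_associated]
    expanded: list[EBR] = []
    for e in sorted(kept, key=lambda x: (x.interval.chromosome, x.interval.start)):
        iv = e.interval
        pad = max(0, min_ebr_width - iv.length)
        s = max(0, iv.start - pad // 2)
        en = min(chrom_lengths.get(iv.chromosome, iv.end + pad), s + max(iv.length, min_ebr_width))
        e2 = EBR(
            Interval(iv.chromosome, s, en),
            e.branch,
            placeholder=e.placeholder,
            reuse=e.reuse,
            reuse_lineages=list(e.reuse_lineages),
        )
        expanded.append(e2)
    # resolve overlaps between consecutive expanded EBRs at the midpoint
    resolved: list[EBR] = []
    for e in expanded:
        if resolved and resolved[-1].interval.chromosome == e.interval.chromosome:
            prev = resolved[-1]
            if e.interval.start < prev.interval.end:
                mid = (e.interval.start + prev.interval.end) // 2
                mid = max(prev.interval.start + 1, min(mid, e.interval.end - 1))
                prev.interval = Interval(
                    prev.interval.chromosome, prev.interval.start, mid
                )
                e.interval = Interval(e.interval.chromosome, mid, e.interval.end)
        resolved.append(e)
    ebr_ivs = [e.interval for e in resolved]
    trimmed: list[Interval] = []
    for m in mshsbs:
        pieces = [m.interval]
        for cut in ebr_ivs:
            nxt = []
            for p in pieces:
                if interval_overlap(p, cut) == 0:
                    nxt.append(p)
                    continue
                if cut.start > p.start:
                    nxt.append(Interval(p.chromosome, p.start, cut.start))
                if cut.end < p.end:
                    nxt.append(Interval(p.chromosome, cut.end, p.end))
            pieces = nxt
        trimmed.extend(pieces)
    return resolved, sorted(trimmed)
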