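"""Window-based enrichment statistics over genomic region classes.

The genome is tiled into fixed-width windows (10 kbp for repeat/TAD/
compartment tallies, 100 kbp for gene tallies — the latter approximates
the median breakpoint-region length).  Windows with more than half
their length in assembly gaps or any centromere overlap are removed;
remaining windows are classified by *full containment* into msHSB,
EBR (with reuse/non-reuse and recent/ancient sub-labels) or other, and
per-window feature tallies feed the comparisons:

* pairwise two-sided Wilcoxon rank-sum tests on gene lengths and
  per-window densities, Bonferroni corrected over the pairs;
* Pearson chi-squared tests of independence (no continuity correction)
  on binary per-window feature presence, with cross-product odds ratios
  (Haldane–Anscombe 0.5 correction on zero cells, flagged);
* leave-one-out t-tests of per-chromosome gene density against the
  karyotype average, FDR corrected.

Genes are counted in the window holding their start (so a gene spanning
two windows is counted once); gene bases are split across windows.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core import Interval, ValidationError, interval_overlap
from .features import EBR, MsHSB
from .rates import leave_one_out_t
from statsmodels.stats.multitest import multipletests

# ---------------------------------------------------------------------------
# Window construction
# ---------------------------------------------------------------------------


@dataclass
class WindowTable:
    """Fixed-width windows with region classes and feature tallies."""

    width: int
    df: pd.DataFrame

    def retained(self) -> pd.DataFrame:
        return self.df[self.df["retained"]]


def _per_chrom(intervals: Iterable[Interval]) -> dict[str, list[Interval]]:
    out: dict[str, list[Interval]] = {}
    for iv in intervals:
        out.setdefault(iv.chromosome, []).append(iv)
    return out


def _window_bases(
    ivs: Sequence[Interval], n_win: int, width: int, length: int
) -> np.ndarray:
    arr = np.zeros(n_win)
    for iv in ivs:
        s, e = max(0, iv.start), min(length, iv.end)
        if e <= s:
            continue
        w0, w1 = s // width, (e - 1) // width
        if w0 == w1:
            arr[w0] += e - s
        else:
            arr[w0] += (w0 + 1) * width - s
            arr[w1] += e - w1 * width
            if w1 > w0 + 1:
                arr[w0 + 1 : w1] += width
    return arr


def _window_counts_overlap(
    ivs: Sequence[Interval], n_win: int, width: int, length: int
) -> np.ndarray:
    arr = np.zeros(n_win, dtype=int)
    for iv in ivs:
        s, e = max(0, iv.start), min(length, iv.end)
        if e <= s:
            continue
        arr[s // width : (e - 1) // width + 1] += 1
    return arr


def make_windows(
    chrom_lengths: Mapping[str, int],
    width: int,
    gaps: Iterable[Interval] = (),
    centromeres: Iterable[Interval] = (),
) -> WindowTable:
    """Tile each chromosome into windows and apply the gap/centromere filter.

    The last, partial window of a chromosome is kept but flagged.
    Windows with more than 50% of their length in gaps, or overlapping a
    centromere by at least 1 bp, are marked not retained.
    """
    if width <= 0:
        raise ValidationError("window width must be > 0")
    gap_by = _per_chrom(gaps)
    cen_by = _per_chrom(centromeres)
    frames = []
    for chrom in sorted(chrom_lengths):
        L = chrom_lengths[chrom]
        n_win = (L + width - 1) // width
        starts = np.arange(n_win) * width
        ends = np.minimum(starts + width, L)
        gap_bases = _window_bases(gap_by.get(chrom, []), n_win, width, L)
        cen_hits = _window_counts_overlap(cen_by.get(chrom, []), n_win, width, L)
        lengths = ends - starts
        retained = (gap_bases <= 0.5 * lengths) & (cen_hits == 0)
        frames.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "start": starts,
                    "end": ends,
                    "partial": ends - starts < width,
                    "gap_bases": gap_bases.astype(int),
                    "centromere_overlap": cen_hits > 0,
                    "retained": retained,
                }
            )
        )
    return WindowTable(width, pd.concat(frames, ignore_index=True))


# ---------------------------------------------------------------------------
# Region classification
# ---------------------------------------------------------------------------


def _check_disjoint(intervals: Sequence[Interval]) -> None:
    by = _per_chrom(intervals)
    for chrom, ivs in by.items():
        ivs = sorted(ivs, key=lambda v: v.start)
        for a, b in zip(ivs, ivs[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"region intervals overlap on {chrom} at {b.start}"
                )


def classify_windows(
    wt: WindowTable,
    mshsbs: Sequence[Interval],
    ebrs: Sequence[EBR] = (),
    recent_branches: Iterable[str] = (),
) -> WindowTable:
    """Assign a region class to every window by full containment.

    Windows straddling a region boundary stay 'other'.  EBR windows
    additionally carry reuse/nonreuse and recent/ancient sub-labels
    (recent = the EBR's branch is in ``recent_branches``).
    """
    ebr_ivs = [e.interval for e in ebrs]
    _check_disjoint(list(mshsbs) + ebr_ivs)
    recent = set(recent_branches)
    df = wt.df.copy()
    df["region_class"] = "other"
    df["reuse_class"] = ""
    df["age_class"] = ""
    for chrom, sub in df.groupby("chrom"):
        idx = sub.index.to_numpy()
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        for iv in mshsbs:
            if iv.chromosome != chrom:
                continue
            inside = (starts >= iv.start) & (ends <= iv.end)
            df.loc[idx[inside], "region_class"] = "msHSB"
        for e in ebrs:
            iv = e.interval
            if iv.chromosome != chrom:
                continue
            inside = (starts >= iv.start) & (ends <= iv.end)
            df.loc[idx[inside], "region_class"] = "EBR"
            df.loc[idx[inside], "reuse_class"] = "reuse" if e.reuse else "nonreuse"
            df.loc[idx[inside], "age_class"] = (
                "recent" if e.branch in recent else "ancient"
            )
    return WindowTable(wt.width, df)


# ---------------------------------------------------------------------------
# Feature tallies
# ---------------------------------------------------------------------------


def tally_features(wt: WindowTable, bundle) -> WindowTable:
    """Per-window feature tallies from an annotation bundle.

    Adds gene start counts and gene bases, per-repeat-subclass bases,
    TAD count/presence/bases, and a compartment label in
    {A, B, A/B, ND} (A/B marks windows intersected by both compartment
    types).
    """
    df = wt.df.copy()
    width = wt.width
    genes_by = _per_chrom(bundle.genes)
    tads_by = _per_chrom(bundle.tads)
    comp_a = _per_chrom([iv for iv, lab in bundle.compartments if lab == "A"])
    comp_b = _per_chrom([iv for iv, lab in bundle.compartments if lab == "B"])
    new_cols: dict[str, np.ndarray] = {
        "gene_count": np.zeros(len(df), int),
        "gene_bases": np.zeros(len(df)),
        "tad_count": np.zeros(len(df), int),
        "tad_bases": np.zeros(len(df)),
    }
    for name in bundle.repeats:
        new_cols[f"{name}_bases"] = np.zeros(len(df))
    compartment = np.full(len(df), "ND", dtype=object)
    for chrom, sub in df.groupby("chrom"):
        idx = sub.index.to_numpy()
        n_win = len(idx)
        L = int(sub["end"].max())
        genes = genes_by.get(chrom, [])
        starts = np.array([g.start for g in genes], int)
        if starts.size:
            cnt = np.zeros(n_win, int)
            np.add.at(cnt, starts // width, 1)
            new_cols["gene_count"][idx] = cnt
        new_cols["gene_bases"][idx] = _window_bases(genes, n_win, width, L)
        tads = tads_by.get(chrom, [])
        new_cols["tad_count"][idx] = _window_counts_overlap(tads, n_win, width, L)
        new_cols["tad_bases"][idx] = _window_bases(tads, n_win, width, L)
        for name, ivs in bundle.repeats.items():
            sel = [iv for iv in ivs if iv.chromosome == chrom]
            new_cols[f"{name}_bases"][idx] = _window_bases(sel, n_win, width, L)
        a_b = _window_bases(comp_a.get(chrom, []), n_win, width, L)
        b_b = _window_bases(comp_b.get(chrom, []), n_win, width, L)
        lab = np.full(n_win, "ND", dtype=object)
        lab[(a_b > 0) & (b_b == 0)] = "A"
        lab[(b_b > 0) & (a_b == 0)] = "B"
        lab[(a_b > 0) & (b_b > 0)] = "A/B"
        compartment[idx] = lab
    for col, arr in new_cols.items():
        df[col] = arr
    df["tad_present"] = df["tad_count"] > 0
    df["compartment"] = compartment
    return WindowTable(width, df)


# ---------------------------------------------------------------------------
# Group comparisons
# ---------------------------------------------------------------------------


@dataclass
class GroupComparison:
    """Result of one pairwise test between region classes."""

    group_a: str
    group_b: str
    statistic_name: str
    statistic: float
    p_value: float
    p_corrected: float
    odds_ratio: float | None = None
    or_corrected: bool = False  # Haldane-Anscombe 0.5 applied
    median_a: float | None = None
    median_b: float | None = None
    n_a: int = 0
    n_b: int = 0
    skipped: bool = False


def comparisons_frame(comparisons: Sequence[GroupComparison]) -> pd.DataFrame:
    return pd.DataFrame([vars(c) for c in comparisons])


def assign_gene_regions(
    genes: Sequence[Interval],
    mshsbs: Sequence[Interval],
    ebrs: Sequence[EBR] = (),
    split_reuse: bool = False,
) -> dict[str, list[int]]:
    """Group complete gene lengths by the region fully containing them."""
    groups: dict[str, list[int]] = {}
    ebr_list = [(e.interval, "reuse-EBR" if e.reuse else "nonreuse-EBR") for e in ebrs]
    for g in genes:
        label = "other"
        for iv in mshsbs:
            if (
                iv.chromosome == g.chromosome
                and g.start >= iv.start
                and g.end <= iv.end
            ):
                label = "msHSB"
                break
        if label == "other":
            for iv, lab in ebr_list:
                if (
                    iv.chromosome == g.chromosome
                    and g.start >= iv.start
                    and g.end <= iv.end
                ):
                    label = lab if split_reuse else "EBR"
                    break
        groups.setdefault(label, []).append(g.length)
    return groups


def compare_gene_lengths(
    groups: Mapping[str, Sequence[float]]
) -> list[GroupComparison]:
    """Pairwise two-sided Wilcoxon rank-sum tests, Bonferroni corrected."""
    names = sorted(groups)
    if len(names) < 2:
        raise ValidationError("need at least two groups")
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        xa, xb = np.asarray(groups[a], float), np.asarray(groups[b], float)
        if xa.size < 2 or xb.size < 2:
            out.append(
                GroupComparison(a, b, "wilcoxon", math.nan, math.nan, math.nan,
                                n_a=xa.size, n_b=xb.size, skipped=True)
            )
            continue
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        out.append(
            GroupComparison(
                a, b, "wilcoxon", float(res.statistic), float(res.pvalue),
                min(1.0, float(res.pvalue) * m),
                median_a=float(np.median(xa)), median_b=float(np.median(xb)),
                n_a=xa.size, n_b=xb.size,
            )
        )
    return out


def association_test(
    presence: Mapping[str, np.ndarray]
) -> list[GroupComparison]:
    """Pairwise Pearson chi-squared tests on binary presence per window.

    The odds ratio is the cross-product (a*d)/(b*c) of the 2x2 table
    [[absent_a, present_a], [absent_b, present_b]], i.e. the odds of
    feature *absence* in group A relative to group B; with any zero cell
    the Haldane–Anscombe 0.5 correction applies (flagged).
    """
    names = sorted(presence)
    pairs = list(itertools.combinations(names, 2))
    m = len(pairs)
    out = []
    for ga, gb in pairs:
        xa = np.asarray(presence[ga], bool)
        xb = np.asarray(presence[gb], bool)
        if xa.size == 0 or xb.size == 0:
            out.append(
                GroupComparison(ga, gb, "chi2", math.nan, math.nan, math.nan,
                                n_a=xa.size, n_b=xb.size, skipped=True)
            )
            continue
        a, b = int((~xa).sum()), int(xa.sum())
        c, d = int((~xb).sum()), int(xb.sum())
        table = np.array([[a, b], [c, d]], float)
        if min(a, b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
            corrected = True
        else:
            aa, bb, cc, dd = a, b, c, d
            corrected = False
        oratio = (aa * dd) / (bb * cc)
        if table.sum(axis=1).min() > 0 and table.sum(axis=0).min() > 0:
            chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        else:
            chi2, p = math.nan, math.nan
        out.append(
            GroupComparison(
                ga, gb, "chi2", float(chi2), float(p),
                min(1.0, float(p) * m) if not math.isnan(p) else math.nan,
                odds_ratio=float(oratio), or_corrected=corrected,
                n_a=xa.size, n_b=xb.size,
            )
        )
    return out


def gene_density_per_mam(
    gene_counts: Mapping[str, int], lengths_bp: Mapping[str, int], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-chromosome gene density with leave-one-out t-test and FDR.

    Density is complete genes per Mbp; each chromosome is tested against
    the mean and spread of the remaining chromosomes' densities.
    """
    chroms = sorted(gene_counts)
    if len(chroms) < 3:
        raise ValidationError("need at least 3 chromosomes")
    for c in chroms:
        if lengths_bp[c] <= 0:
            raise ValidationError(f"chromosome {c!r} has zero length")
    dens = [gene_counts[c] / (lengths_bp[c] / 1e6) for c in chroms]
    pvals = leave_one_out_t(dens)
    defined = [i for i, p in enumerate(pvals) if not math.isnan(p)]
    qvals = [math.nan] * len(pvals)
    if defined:
        _, q, _, _ = multipletests([pvals[i] for i in defined], method="fdr_bh")
        for i, qi in zip(defined, q):
            qvals[i] = float(qi)
    return pd.DataFrame(
        {
            "chrom": chroms,
            "n_genes": [gene_counts[c] for c in chroms],
            "length_mbp": [lengths_bp[c] / 1e6 for c in chroms],
            "density_per_mbp": dens,
            "p_value": pvals,
            "fdr_q": qvals,
            "significant": [
                (not math.isnan(q)) and q < alpha for q in qvals
            ],
        }
    )


def reportable_repeat_classes(
    wt: WindowTable, min_mean_bases: float = 100.0
) -> list[str]:
    """Repeat subclasses worth reporting.

    A subclass is suppressed when its mean bases per window stays below
    ``min_mean_bases`` in every region class.
    """
    df = wt.retained()
    out = []
    for col in df.columns:
        if not col.endswith("_bases") or col in ("gene_bases", "tad_bases", "gap_bases"):
            continue
        name = col[: -len("_bases")]
        means = df.groupby("region_class")[col].mean()
        if (means >= min_mean_bases).any():
            out.append(name)
    return sorted(out)
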