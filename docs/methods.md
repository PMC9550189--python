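# Methods

`syntevo` analyses chromosome evolution at synteny-block resolution. A
genome is an ordered set of signed blocks per chromosome (a
`BlockGenome`); orientation is the sign of the block id, chromosomes are
orientation-free (a chromosome read backwards with flipped signs is the
same chromosome), and all coordinates are 0-based half-open. This single
representation feeds every stage: simulation, reconstruction, breakpoint
calling, rearrangement algebra and window statistics.

## Evolution simulator

`simulate_history` evolves a root karyotype along a rooted, dated binary
tree. Event counts per branch are Poisson with mean `rate × Δt`
(`rate` in events/My, `Δt` in My); each event is an inversion, fusion or
fission drawn from the configured mix. Defaults follow the magnitudes
reported for mammalian genomes: mix 0.80/0.10/0.10 (inversions dominate
chromosome evolution, roughly 76–85% of typed events), rate 2 events/My,
lognormal block lengths with mean 880 kbp.

Modelling choices:

* **Breakpoints fall only between blocks.** Block granularity is the
  resolution of the simulation; sub-block breakage is represented by
  configuring finer blocks.
* **Inversion and fission cuts use internal junctions only** (an
  inversion cuts two junctions of one chromosome, a fission one), so an
  inversion always breaks exactly two adjacencies and a fission one.
  Terminal-block inversions are invisible at block resolution and are
  not simulated.
* **New-breakpoint bookkeeping.** A cut is recorded with its ancestral
  (root-frame) coordinate only when the cut junction still corresponds
  to an intact root adjacency; cutting a derived junction re-breaks
  coordinates that are already breakpoints and adds nothing new. Hence
  an inversion contributes up to 2 new reference-frame breakpoints, a
  fission up to 1, a fusion 0.
* **Impossible events are resampled** (fission of a single-block
  chromosome, fusion with one chromosome left) and logged.
* One `numpy` RNG stream keyed by a single integer seed drives a run;
  draws occur in documented order (preorder over branches; per branch the
  event count, then each event's type and placement), so identical seeds
  give identical histories.
* An optional fragile-site mode gives a configured fraction of ancestral
  junctions elevated cut odds, to emulate breakpoint reuse; it is off by
  default.

Translocations are not a primitive: the observable event vocabulary at
this resolution is inversions, fusions and fissions, and a reciprocal
translocation is representable as fission + fusion.

## Synthetic annotation tracks

`generate_annotations` lays tracks on the ancestral coordinate frame,
planting enrichment structure in *breakpoint neighbourhoods*: every true
breakpoint extended by ±150 kbp (300-kbp neighbourhoods; the width sits
at the upper end of reported EBR extents, and a 100-kbp gene window must
be able to sit fully inside a desk-scale EBR region). Defaults plant the
reported effect sizes:

| track | outside | inside neighbourhoods |
|---|---|---|
| gene density | 1 / 100 kbp | 2 / 100 kbp |
| gene length (median, lognormal) | 36 kbp | 19 kbp |
| Alu coverage | 10% | ×1.6 |
| P(10-kbp tile lacks TAD) | 0.10 | odds ×8.5 |
| P(100-kbp tile in A compartment) | 0.40 | odds ×2.4 |

Repeat subclasses are homogeneous Poisson processes of elements with
exponential lengths; genes a Poisson process with lognormal lengths; TAD
coverage independent Bernoulli per 10-kbp tile (adjacent covered tiles
merge into one TAD interval); compartments categorical per 100-kbp tile.
One assembly gap and one centromere per chromosome exercise the window
filters. Setting every multiplier/odds to 1 (`AnnotationParams.null()`)
removes all planted structure and is the null configuration used for
calibration tests.

What the generator does **not** emulate: alignment artefacts and
coverage gaps, GC/replication-timing covariation among tracks, tandem
and segmental duplication mechanics, lineage-specific repeat expansions,
and any sequence-level signal. Passing tests therefore demonstrate that
the pipeline recovers structure *of the kind assumed by the model*, not
that real genomes satisfy those assumptions.

## Reconstruction

`detect_sfs` cuts the reference coordinate axis at every position where
any genome interrupts colinearity (change of target chromosome, order,
or orientation) and keeps maximal uncut runs at or above the resolution
(default 300 kbp) as syntenic fragments (SFs); shorter runs are reported
as unplaced so coverage statistics can be computed.

`score_adjacencies` scores every SF adjacency observed in at least one
genome at a target internal node:
`score = Σ_{supporting} w_g / Σ_{all} w_g` with `w_g = 1/(patristic
distance tip→target in My)`, and records *sidedness*: support from at
least one descendant of the target plus either an outgroup genome or
both child clades.

`assemble_racfs` grows RACFs greedily: adjacencies sorted by (score
descending, sided first, lexicographic adjacency id) are accepted when
both SF extremities are free and the acceptance rule passes. The
**default acceptance rule is sidedness alone**. Under a Dollo-style view
of adjacencies (a broken junction is effectively never re-formed),
two-sided support implies presence at the target node, and the weighted
score is left to order conflicting candidates. A pure weighted-majority
cutoff (`weighted_majority_rule`, score > 0.5 and sided) is provided but
not default: when a target node has child clades of very different tip
counts, a break just below the node on the populous side leaves support
only in the small clade plus outgroups, the weighted majority fails, and
the break is dated one branch too early — on the 6-tip demo tree this
mis-dated roughly half of all EBR calls. Both rules are injectable via
the `rule` parameter.

`order_racfs` concatenates RACFs into chromosomes when a junction
between two RACF ends is realized, in consistent orientation, in at
least 2/3 of descendant genomes (ties and minority junctions never
merge); every candidate decision is logged. This automates a step that
is manual curation at genome scale, and is validated only against
simulation truth.

`compare_reconstructions` classifies each SF adjacency of one
reconstruction against another as maintained / extra (absent with both
flanks free) / inconsistent (contradicted), and reports the cumulative
length fraction of SFs flanking inconsistencies.

## EBRs and msHSBs

EBRs are called only within fragments: along an ordered root-to-tip
lineage, a baseline junction whose adjacency is intact in a branch's
parent reconstruction and absent from the child yields one EBR spanning
the reference gap between the flanking SFs, assigned to the first branch
where the break appears. Zero-width gaps (abutting SFs) get a flagged
1-bp placeholder. Placeholders may abut conserved sequence by
construction, so the EBR/msHSB disjointness property is stated for
non-placeholder calls; for window analyses every non-centromeric EBR is
expanded symmetrically to at least 300 kbp, overlaps between expanded
EBRs are split at the midpoint, and msHSBs are trimmed wherever an
expanded EBR claims the space. EBRs overlapping a centromere are
retained in tables but masked from enrichment analyses.

Breakpoint reuse is assessed only for EBRs shorter than 300 kbp (larger
calls are likely chains of adjacent breaks): an EBR is reuse when it
overlaps a same-gated EBR from an independent lineage, where two
branches are independent if neither is ancestral to the other.

msHSBs are maximal reference intervals covered colinearly in every
genome of the analysis set: per-species coverage comes from a pairwise
SF run against that species alone, the strict intersection across
species is taken, and intervals of at least 300 kbp are kept (the msHSB
length floor shares one configuration knob with the SF resolution).
Under an exponential length model with mean `μ` and `n` blocks the
expected maximum is `μ·H_n` (harmonic number) and
`P(max ≥ x) = 1 − (1 − e^{−x/μ})^n`.

## Rearrangement algebra

`reversal_distance` implements the exact Hannenhalli–Pevzner formula
`d = (n+1) − c + h + f` on the breakpoint graph of a signed permutation,
with full hurdle and fortress accounting (components of interleaving
cycles; a hurdle is an unoriented component whose positions form one
contiguous circular run; a fortress is an odd number of hurdles, all
protected). It matches breadth-first search exhaustively to n = 7.

`multichromosomal_scenario` searches for a minimum-length event sequence
directly in the {inversion, fusion, fission} operation set with
iterative-deepening A*, using the DCJ distance as the admissible lower
bound (each of the three operations is a single DCJ). Children are
expanded in lexicographic event order (fission < fusion < inversion,
then chromosome index and cut positions), so the scenario returned is
the lexicographically least optimal one and runs are reproducible.
Replaying the events always reproduces the target exactly. Past a node
cap the search falls back to a constructive three-phase scenario
(fission mixed junctions, fuse same-target pieces, then exact greedy
reversal descent per chromosome), which is valid though not always
minimal. Because the search never uses a translocation primitive, no
decomposition step is needed; where a translocation would be
parsimonious the scenario simply contains its fission+fusion pair.

`fraction_rearranged` reports, per ancestral chromosome: the *inter*
fraction (length mapped outside the majority chromosome of the
descendant) and the *intra* fraction (one minus the maximum-weight
signed-colinear subsequence on the majority chromosome, maximised over
the two chromosome orientations).

`classify_orthology` labels chromosome-scale orthology as 1:1,
1:n-complete or partial with a 95% completeness tolerance; the packaged
ancestral-karyotype-to-chicken table (transcribed once from the printed
table and frozen with a SHA-256 checksum) encodes the printed
complete/partial calls as coverage fractions 1.0 / 0.5.

## Rates and enrichment statistics

Branch rates are counts divided by branch duration (My). Each branch is
tested against the others with a leave-one-out one-sample t statistic in
prediction-interval form, `t = (r_i − mean(rest)) / (sd(rest)·√(1+1/k))`
with `k = m−1` and `m−2` degrees of freedom — chosen so an extreme
branch cannot inflate its own null — followed by Benjamini–Hochberg FDR
across branches, flagged at q < 0.05. Zero residual variance yields NaN
p-values, reported as undefined rather than significant. Per-lineage
testing is the default; callers may pool lineages by passing the pooled
rate list.

Windows (10 kbp for repeats/TADs/compartments, 100 kbp for genes) tile
each chromosome; the final partial window is kept but flagged; windows
with >50% gap bases or ≥1 bp centromere overlap are removed. Region
class requires full containment; straddling windows stay "other". Genes
are counted in the window containing their start (counted once) with
bases split across windows; TAD presence is ≥1 bp overlap; a window
intersected by both compartment labels is an "A/B" transition. Pairwise
gene-length and density comparisons use the two-sided Wilcoxon rank-sum
test with Bonferroni correction over the pairs; binary presence uses
Pearson's chi-squared without continuity correction, with the
cross-product odds ratio and the Haldane–Anscombe 0.5 correction
(flagged) on zero cells. Repeat subclasses averaging under 100 bp per
10-kbp window in every region class are suppressed from reports.

A geometric caveat, measured during calibration: assigning *genes* to
regions by full containment under-samples long genes in short EBR
regions, so the gene-length comparison is slightly anti-conservative
even with no planted effect (~8% rejection at α = 0.05 in the null
configuration). Per-window tallies carry no such bias (both the
chi-squared and the repeat-density Wilcoxon calibrate to nominal α); the
planted gene-length effect (19 vs 36 kbp) is far larger than the bias.

## Desk-scale study conditions

Simulated demonstrations use a 6-tip tree spanning ~7.5 My in total with
40–500 blocks. A real mammalian synteny map has ~2,557 segments over
~180 My; at 1/60 of the segment count, branch durations are scaled down
comparably so that the expected breakage per junction stays in the
realistic regime (far from saturation). Recovery numbers quoted by the
test suite (≥90% of true mid-tree adjacencies; ≥80% of EBR calls
overlapping a true breakpoint of the assigned branch) are aggregates
over seeds 1–20 under those conditions.

## Known limitations

* The adjacency scorer is a heuristic concretization of
  probability-weighted adjacency reconstruction, not a reimplementation
  of any published tool; genome-scale catalogues (EBR/msHSB counts,
  branch rates, odds ratios) from real assemblies are out of scope.
* Breakpoint reuse in the simulator arises only by chance collisions
  unless the fragile-site mode is enabled.
* EBR extents on a contiguous block frame are point-like; window
  analyses depend on the configured expansion width.
* `order_racfs` reproduces majority structure, not curation judgment;
  with fewer than three informative descendants it merges nothing.
* The constructive scenario fallback is near-parsimonious only; the
  event list is still always replay-exact.
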