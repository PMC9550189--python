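"""End-to-end pipeline: simulate, reconstruct, call features, test.

Wires the library stages together for a self-contained run on
synthetic data: simulate a rearrangement history on the configured
dated tree, detect syntenic fragments, reconstruct RACFs at every
internal node, call EBRs along each root-to-tip lineage (with reuse
classification), call msHSBs from per-species pairwise coverage, run
branch-rate tests, and produce window-based enrichment reports.

Every output is a TSV/BED file under the chosen directory, plus a run
manifest; identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .core import (
    DatedTree,
    Interval,
    adjacencies_of,
    complement_intervals,
)
from .enrichment import (
    assign_gene_regions,
    association_test,
    classify_windows,
    compare_gene_lengths,
    comparisons_frame,
    gene_density_per_mam,
    make_windows,
    reportable_repeat_classes,
    tally_features,
)
from .features import classify_reuse, detect_ebrs, detect_mshsbs, max_mshsb_test, prepare_region_sets
from .io import (
    RunConfig,
    write_bed,
    write_block_table,
    write_ebr_bed,
    write_manifest,
    write_mshsb_bed,
    write_orthology_table,
    write_tree,
)
from .rates import compute_rates, test_rates
from .rearrange import infer_branch_events
from .reconstruct import (
    assemble_racfs,
    detect_sfs,
    racf_adjacencies,
    score_adjacencies,
    sf_level_genome,
)
from .simulate import (
    AnnotationParams,
    SimulationConfig,
    generate_annotations,
    make_orthology_maps,
    simulate_history,
    true_breakpoints,
)

log = logging.getLogger("syntevo")


def run_full_pipeline(
    config: RunConfig,
    out_dir: str | Path,
    annotation_params: AnnotationParams | None = None,
) -> dict[str, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    tree = DatedTree.from_newick(config.tree_newick)

    # ---- simulate ------------------------------------------------------
    sim_cfg = SimulationConfig(
        n_blocks=config.n_blocks,
        n_chromosomes=config.n_chromosomes,
        mean_block_length=config.mean_block_length,
        block_length_sigma=config.block_length_sigma,
        min_block_length=config.min_block_length,
        rate=config.rate,
        mix=config.mix,
        seed=config.seed,
    )
    genomes, ev_log = simulate_history(tree, sim_cfg)
    log.info("simulated %d events on %d branches", len(ev_log.events), len(ev_log.branches))
    write_tree(tree, out / "tree.nwk")
    write_block_table(
        [genomes[k] for k in sorted(genomes)], out / "genomes.tsv"
    )
    maps = make_orthology_maps(genomes, config.reference)
    orth_dir = out / "orthology"
    orth_dir.mkdir(exist_ok=True)
    for name in sorted(maps):
        write_orthology_table(maps[name], orth_dir / f"{name}.tsv")
    ev_rows = [
        {
            "branch": e.branch,
            "kind": e.kind,
            "detail": repr(e.detail),
            "breakpoints": ";".join(
                "." if bp is None else f"{bp[0]}:{bp[1]}" for bp in e.breakpoints
            ),
        }
        for e in ev_log.events
    ]
    pd.DataFrame(ev_rows, columns=["branch", "kind", "detail", "breakpoints"]).to_csv(
        out / "event_log.tsv", sep="\t", index=False
    )
    tb = [
        (iv, br)
        for br in sorted(ev_log.branches)
        for iv in sorted(true_breakpoints(ev_log, br))
    ]
    write_bed(tb, out / "true_breakpoints.bed")

    ann = annotation_params or AnnotationParams()
    bundle = generate_annotations(genomes[config.reference], ev_log, ann, seed=config.seed)
    tracks = out / "tracks"
    tracks.mkdir(exist_ok=True)
    write_bed(bundle.genes, tracks / "genes.bed")
    write_bed(bundle.tads, tracks / "tads.bed")
    for name, ivs in bundle.repeats.items():
        write_bed(ivs, tracks / f"repeat_{name}.bed")
    write_bed([(iv, lab) for iv, lab in bundle.compartments], tracks / "compartments.bed")
    write_bed(bundle.gaps, tracks / "gaps.bed")
    write_bed(bundle.centromeres, tracks / "centromeres.bed")

    # ---- reconstruction ------------------------------------------------
    tips = {t: maps[t] for t in tree.tips()}
    sfs, unplaced = detect_sfs(tips, config.resolution)
    log.info("detected %d SFs (%d unplaced spans)", len(sfs), len(unplaced))
    sf_rows = [
        {
            "sf": sf.id,
            "ref_chrom": sf.reference.chromosome,
            "ref_start": sf.reference.start,
            "ref_end": sf.reference.end,
            "blocks": ",".join(map(str, sf.blocks)),
        }
        for sf in sfs
    ]
    pd.DataFrame(sf_rows).to_csv(out / "sfs.tsv", sep="\t", index=False)
    if unplaced:
        write_bed(unplaced, out / "unplaced.bed")

    racfs_per_node = {}
    racf_rows = []
    for node in tree.internal_labels():
        if node == tree.root:
            continue
        scores = score_adjacencies(sfs, tree, node)
        racfs = assemble_racfs(scores, sf_ids=[s.id for s in sfs], target=node)
        racfs_per_node[node] = racfs
        for r in racfs:
            racf_rows.append(
                {"node": node, "racf": r.id, "sfs": ",".join(map(str, r.sfs))}
            )
    pd.DataFrame(racf_rows, columns=["node", "racf", "sfs"]).to_csv(
        out / "racfs.tsv", sep="\t", index=False
    )

    # ---- EBRs along every root-to-tip lineage --------------------------
    ref_sorted = sorted(sfs, key=lambda s: (s.reference.chromosome, s.reference.start))
    # baseline: reference-frame SF order
    baseline_chroms: dict[str, list[int]] = {}
    for sf in ref_sorted:
        baseline_chroms.setdefault(sf.reference.chromosome, []).append(sf.id)
    from .core import BlockGenome

    baseline_genome = BlockGenome(
        config.reference, baseline_chroms, {s.id: s.length for s in sfs}
    )
    all_ebrs = []
    for tip in tree.tips():
        lineage = [(config.reference, adjacencies_of(baseline_genome))]
        for node in tree.lineage(tip)[1:-1]:
            lineage.append((node, racfs_per_node[node]))
        lineage.append((tip, adjacencies_of(sf_level_genome(sfs, tip))))
        all_ebrs.extend(detect_ebrs(lineage, sfs, bundle.centromeres))
    # deduplicate identical (branch, interval) calls shared between lineages
    seen = set()
    ebrs = []
    for e in all_ebrs:
        key = (e.branch, e.interval)
        if key not in seen:
            seen.add(key)
            ebrs.append(e)
    ebrs = classify_reuse(ebrs, tree, config.reuse_size_gate)
    write_ebr_bed(sorted(ebrs, key=lambda e: (e.interval, e.branch)), out / "ebrs.bed")
    log.info("called %d EBRs (%d reuse)", len(ebrs), sum(e.reuse for e in ebrs))

    # ---- msHSBs --------------------------------------------------------
    coverage = {}
    for sp in tree.tips():
        sp_sfs, _ = detect_sfs({sp: maps[sp]}, config.resolution)
        coverage[sp] = [s.reference for s in sp_sfs]
    mshsbs = detect_mshsbs(coverage, config.min_mshsb_length, orthology=tips)
    write_mshsb_bed(mshsbs, out / "mshsbs.bed")
    if mshsbs:
        exp_max, p_max = max_mshsb_test([m.interval.length for m in mshsbs])
        pd.DataFrame(
            [
                {
                    "n": len(mshsbs),
                    "mean_length": np.mean([m.interval.length for m in mshsbs]),
                    "observed_max": max(m.interval.length for m in mshsbs),
                    "expected_max": exp_max,
                    "p_observed_max": p_max,
                }
            ]
        ).to_csv(out / "mshsb_max_test.tsv", sep="\t", index=False)

    # ---- branch rates --------------------------------------------------
    ebr_counts: dict[str, int] = {}
    for e in ebrs:
        ebr_counts[e.branch] = ebr_counts.get(e.branch, 0) + 1
    re_counts: dict[str, int] = {}
    for tip in tree.tips():
        lineage_nodes = tree.lineage(tip)
        lineage_genomes = [baseline_genome]
        for node in lineage_nodes[1:-1]:
            adj = racf_adjacencies(racfs_per_node[node])
            # express reconstruction as an SF-level genome via its RACF chains
            chroms = {
                f"r{r.id}": r.sfs for r in racfs_per_node[node]
            }
            lineage_genomes.append(
                BlockGenome(node, chroms, {s.id: s.length for s in sfs})
            )
        lineage_genomes.append(sf_level_genome(sfs, tip))
        try:
            for ec in infer_branch_events(lineage_genomes, node_cap=30_000):
                re_counts.setdefault(ec.branch, ec.n_events)
        except Exception:  # pragma: no cover - rate table stays partial
            log.warning("rearrangement typing failed for lineage to %s", tip)
    counts = {
        br: (ebr_counts.get(br, 0), re_counts.get(br, 0))
        for br in sorted(ebr_counts | re_counts.keys())
    }
    if len(counts) >= 3:
        rates = test_rates(compute_rates(counts, tree))
        pd.DataFrame([vars(r) for r in rates]).to_csv(
            out / "branch_rates.tsv", sep="\t", index=False
        )

    # ---- enrichment ----------------------------------------------------
    chrom_lengths = genomes[config.reference].chromosome_lengths()
    ebrs_x, mshsb_trim = prepare_region_sets(
        ebrs, mshsbs, chrom_lengths, config.min_ebr_width
    )
    recent = set(tree.tips())
    comp_rows = []
    for width in config.window_widths:
        wt = make_windows(chrom_lengths, width, bundle.gaps, bundle.centromeres)
        wt = classify_windows(wt, mshsb_trim, ebrs_x, recent_branches=recent)
        wt = tally_features(wt, bundle)
        wt.df.to_csv(out / f"windows_{width // 1000}kbp.tsv", sep="\t", index=False)
        r = wt.retained()
        have = {c for c in ("EBR", "msHSB", "other") if (r["region_class"] == c).any()}
        if len(have) >= 2:
            pres = {
                c: r.loc[r["region_class"] == c, "tad_present"].to_numpy()
                for c in sorted(have)
            }
            for gc in association_test(pres):
                gc.statistic_name = f"chi2_tad_absence_{width // 1000}kbp"
                comp_rows.append(gc)
            for cls in reportable_repeat_classes(wt):
                groups = {
                    c: r.loc[r["region_class"] == c, f"{cls}_bases"].to_numpy()
                    for c in sorted(have)
                }
                for gc in compare_gene_lengths(groups):
                    gc.statistic_name = f"wilcoxon_{cls}_{width // 1000}kbp"
                    comp_rows.append(gc)
    gene_groups = assign_gene_regions(bundle.genes, mshsb_trim, ebrs_x)
    if len(gene_groups) >= 2:
        for gc in compare_gene_lengths(gene_groups):
            gc.statistic_name = "wilcoxon_gene_length"
            comp_rows.append(gc)
    if comp_rows:
        comparisons_frame(comp_rows).to_csv(
            out / "comparisons.tsv", sep="\t", index=False
        )

    # per-chromosome gene density on the ancestral karyotype
    gene_counts = {c: 0 for c in chrom_lengths}
    for g in bundle.genes:
        if g.chromosome in gene_counts:
            gene_counts[g.chromosome] += 1
    if len(gene_counts) >= 3:
        gene_density_per_mam(gene_counts, chrom_lengths).to_csv(
            out / "gene_density_per_chromosome.tsv", sep="\t", index=False
        )

    write_manifest(out, config)
    for p in sorted(out.rglob("*")):
        if p.is_file():
            paths[str(p.relative_to(out))] = p
    return paths
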