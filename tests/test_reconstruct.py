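import pytest

from syntevo.core import (
    Adjacency,
    BlockGenome,
    HEAD,
    TAIL,
    Interval,
    ValidationError,
    adjacencies_of,
)
from syntevo.reconstruct import (
    AdjacencyScore,
    RACF,
    assemble_racfs,
    compare_reconstructions,
    detect_sfs,
    order_racfs,
    project_sf_genome,
    racf_adjacencies,
    score_adjacencies,
    sf_level_genome,
)
from syntevo.simulate import make_orthology_maps


def maps_for(genomes, reference="ref"):
    return make_orthology_maps(genomes, reference)


def three_block_genomes(middle_len, invert_middle=True):
    lengths = {1: 400_000, 2: middle_len, 3: 400_000}
    ref = BlockGenome("ref", {"c": [1, 2, 3]}, lengths)
    other = BlockGenome(
        "sp", {"c": [1, -2 if invert_middle else 2, 3]}, lengths
    )
    return ref, other


class TestDetectSfs:
    def test_identical_genomes_one_sf_per_chromosome(self):
        lengths = {1: 500_000, 2: 500_000}
        ref = BlockGenome("ref", {"c": [1, 2]}, lengths)
        sp = BlockGenome("sp", {"c": [1, 2]}, lengths)
        maps = maps_for({"ref": ref, "sp": sp})
        sfs, unplaced = detect_sfs({"sp": maps["sp"]}, 300_000)
        assert len(sfs) == 1 and not unplaced
        assert sfs[0].reference == Interval("c", 0, 1_000_000)

    def test_interior_inversion_cuts_into_three(self):
        ref, other = three_block_genomes(400_000)
        maps = maps_for({"ref": ref, "sp": other})
        sfs, unplaced = detect_sfs({"sp": maps["sp"]}, 300_000)
        assert [sf.reference.length for sf in sfs] == [400_000, 400_000, 400_000]
        strands = [sf.placements["sp"].strand for sf in sfs]
        assert strands == [1, -1, 1]
        assert not unplaced

    def test_sub_resolution_segment_reported_unplaced(self):
        ref, other = three_block_genomes(200_000)
        maps = maps_for({"ref": ref, "sp": other})
        sfs, unplaced = detect_sfs({"sp": maps["sp"]}, 300_000)
        assert len(sfs) == 2
        assert [iv.length for iv in unplaced] == [200_000]

    def test_partition_property_on_simulation(self, small_history):
        tree, genomes, _, maps = small_history
        sfs, unplaced = detect_sfs({t: maps[t] for t in tree.tips()}, 300_000)
        ordered = sorted(sfs, key=lambda s: (s.reference.chromosome, s.reference.start))
        for a, b in zip(ordered, ordered[1:]):
            if a.reference.chromosome == b.reference.chromosome:
                assert a.reference.end <= b.reference.start

    def test_overlapping_rows_rejected(self):
        ref, other = three_block_genomes(400_000)
        maps = maps_for({"ref": ref, "sp": other})
        bad = maps["sp"].copy()
        bad.loc[1, "tgt_start"] = 0  # overlaps the first block's interval
        with pytest.raises(ValidationError, match="overlap"):
            detect_sfs({"sp": bad}, 300_000)


def make_sfs_two(placements_by_species):
    """Two 1-Mbp SFs with per-species placements given as chrom/order/strand."""
    from syntevo.reconstruct import SyntenicFragment

    sfs = []
    for sf_id in (1, 2):
        placements = {}
        for sp, layout in placements_by_species.items():
            chrom, order, strand = layout[sf_id - 1]
            placements[sp] = Interval(chrom, order * 1_000_000, (order + 1) * 1_000_000, strand)
        sfs.append(
            SyntenicFragment(
                sf_id,
                Interval("c", (sf_id - 1) * 1_000_000, sf_id * 1_000_000),
                [sf_id],
                placements,
            )
        )
    return sfs


class TestScoring:
    def test_universal_adjacency_scores_one(self, balanced_tree):
        sfs = make_sfs_two(
            {sp: [("c", 0, 1), ("c", 1, 1)] for sp in "ABCD"}
        )
        scores = score_adjacencies(sfs, balanced_tree, "T")
        assert len(scores) == 1
        assert scores[0].score == pytest.approx(1.0)
        assert scores[0].sided

    def test_one_ingroup_one_outgroup_scores_half(self, balanced_tree):
        # adjacency realized in A (distance 10) and C (distance 30) only
        sfs = make_sfs_two(
            {
                "A": [("c", 0, 1), ("c", 1, 1)],
                "C": [("c", 0, 1), ("c", 1, 1)],
                "B": [("c1", 0, 1), ("c2", 0, 1)],
                "D": [("c1", 0, 1), ("c2", 0, 1)],
            }
        )
        scores = score_adjacencies(sfs, balanced_tree, "T")
        assert len(scores) == 1
        assert scores[0].score == pytest.approx(0.5)
        assert scores[0].sided
        assert scores[0].supporters == ["A", "C"]

    def test_unobserved_adjacency_absent(self, balanced_tree):
        sfs = make_sfs_two({sp: [("c1", 0, 1), ("c2", 0, 1)] for sp in "ABCD"})
        assert score_adjacencies(sfs, balanced_tree, "T") == []

    def test_tip_target_rejected(self, balanced_tree):
        sfs = make_sfs_two({sp: [("c", 0, 1), ("c", 1, 1)] for sp in "ABCD"})
        with pytest.raises(ValidationError):
            score_adjacencies(sfs, balanced_tree, "A")


def adj(a, ea, b, eb):
    return Adjacency((a, ea), (b, eb))


class TestAssembly:
    def test_greedy_prefers_higher_score(self):
        s1 = AdjacencyScore(adj(1, HEAD, 2, TAIL), 0.8, ["A"], True)
        s2 = AdjacencyScore(adj(1, HEAD, 3, TAIL), 0.6, ["B"], True)
        racfs = assemble_racfs([s2, s1], sf_ids=[1, 2, 3])
        adjacencies = racf_adjacencies(racfs)
        assert s1.adjacency in adjacencies
        assert s2.adjacency not in adjacencies

    def test_tie_breaks_lexicographically_and_deterministically(self):
        s1 = AdjacencyScore(adj(2, HEAD, 3, TAIL), 0.7, ["A"], True)
        s2 = AdjacencyScore(adj(2, HEAD, 4, TAIL), 0.7, ["B"], True)
        out1 = assemble_racfs([s1, s2], sf_ids=[2, 3, 4])
        out2 = assemble_racfs([s2, s1], sf_ids=[2, 3, 4])
        assert [r.sfs for r in out1] == [r.sfs for r in out2]
        assert adj(2, HEAD, 3, TAIL) in racf_adjacencies(out1)

    def test_every_sf_in_exactly_one_racf(self, small_history):
        tree, genomes, _, maps = small_history
        sfs, _ = detect_sfs({t: maps[t] for t in tree.tips()}, 300_000)
        scores = score_adjacencies(sfs, tree, "ABCD")
        racfs = assemble_racfs(scores, sf_ids=[s.id for s in sfs])
        seen = [abs(s) for r in racfs for s in r.sfs]
        assert sorted(seen) == sorted(s.id for s in sfs)

    def test_unsided_adjacency_rejected_by_default_rule(self):
        s = AdjacencyScore(adj(1, HEAD, 2, TAIL), 0.9, ["A"], False)
        racfs = assemble_racfs([s], sf_ids=[1, 2])
        assert racf_adjacencies(racfs) == set()


def sf_genome(name, chroms, lengths=None):
    blocks = {abs(b) for c in chroms.values() for b in c}
    return BlockGenome(name, chroms, lengths or {b: 1_000_000 for b in blocks})


class TestOrdering:
    def test_single_racf_single_chromosome(self):
        r = RACF(1, [1, 2])
        genome, decisions = order_racfs(
            [r], {"A": sf_genome("A", {"c": [1, 2]})}, {1: 10, 2: 10}
        )
        assert list(genome.chromosomes) == ["anc1"]
        assert genome.chromosomes["anc1"] == [1, 2]

    def test_majority_merges_in_consistent_orientation(self):
        r1, r2 = RACF(1, [1, 2]), RACF(2, [3, 4])
        descendants = {
            "A": sf_genome("A", {"c": [1, 2, 3, 4]}),
            "B": sf_genome("B", {"c": [1, 2, 3, 4]}),
            "C": sf_genome("C", {"c": [1, 2, 3, 4]}),
            "D": sf_genome("D", {"c1": [1, 2], "c2": [3, 4]}),
        }
        genome, _ = order_racfs([r1, r2], descendants, {i: 10 for i in range(1, 5)})
        assert genome.chromosomes == {"anc1": [1, 2, 3, 4]}

    def test_two_vs_two_conflict_stays_unmerged(self):
        r1, r2 = RACF(1, [1, 2]), RACF(2, [3, 4])
        descendants = {
            "A": sf_genome("A", {"c": [1, 2, 3, 4]}),
            "B": sf_genome("B", {"c": [1, 2, 3, 4]}),
            "C": sf_genome("C", {"c": [1, 2, -4, -3]}),
            "D": sf_genome("D", {"c": [1, 2, -4, -3]}),
        }
        genome, decisions = order_racfs(
            [r1, r2], descendants, {i: 10 for i in range(1, 5)}
        )
        assert len(genome.chromosomes) == 2
        assert all(not d["accepted"] for d in decisions)


class TestComparison:
    def test_identical_reconstructions(self):
        a = [RACF(1, [1, 2, 3])]
        sfs, _ = self._sfs()
        table, frac = compare_reconstructions(a, [RACF(1, [1, 2, 3])], sfs)
        assert set(table["class"]) == {"maintained"}
        assert frac == 0.0

    def test_split_is_extra_not_inconsistent(self):
        sfs, _ = self._sfs()
        a = [RACF(1, [1, 2, 3])]
        b = [RACF(1, [1, 2]), RACF(2, [3])]
        table, frac = compare_reconstructions(a, b, sfs)
        classes = dict(zip(table["adjacency"], table["class"]))
        assert sorted(classes.values()) == ["extra", "maintained"]
        assert frac == 0.0

    def test_contradiction_is_inconsistent(self):
        sfs, lengths = self._sfs()
        a = [RACF(1, [1, 2]), RACF(2, [3])]
        b = [RACF(1, [1, 3]), RACF(2, [2])]
        table, frac = compare_reconstructions(a, b, sfs)
        assert "inconsistent" in set(table["class"])
        assert frac == pytest.approx((lengths[1] + lengths[2]) / sum(lengths.values()))

    def test_different_universe_errors(self):
        sfs, _ = self._sfs()
        with pytest.raises(ValidationError):
            compare_reconstructions([RACF(1, [1, 2])], [RACF(1, [1, 2, 3])], sfs)

    @staticmethod
    def _sfs():
        from syntevo.reconstruct import SyntenicFragment

        lengths = {1: 400_000, 2: 500_000, 3: 600_000}
        sfs = [
            SyntenicFragment(
                i, Interval("c", sum(lengths[j] for j in range(1, i)),
                            sum(lengths[j] for j in range(1, i + 1))), [i], {}
            )
            for i in (1, 2, 3)
        ]
        return sfs, lengths


class TestReferenceSwap:
    def test_block_level_adjacencies_mostly_agree(self, small_history):
        """Rebuilding against a different reference tip changes <10% of
        accepted adjacencies (expressed on block extremities)."""
        tree, genomes, _, _ = small_history

        def block_adjacencies(reference):
            maps = make_orthology_maps(genomes, reference)
            strand = {b: iv.strand for b, iv in genomes[reference].layout().items()}
            sfs, _ = detect_sfs({t: maps[t] for t in tree.tips()}, 300_000)
            scores = score_adjacencies(sfs, tree, "ABCD")
            racfs = assemble_racfs(scores, sf_ids=[s.id for s in sfs])
            by_id = {s.id: s for s in sfs}
            out = set()

            def block_end(sf_id, sf_ext):
                blocks = by_id[sf_id].blocks
                b = blocks[-1] if sf_ext == HEAD else blocks[0]
                # the presented block extremity depends on the block's strand
                # in the reference's own reading
                if sf_ext == HEAD:
                    return (b, HEAD if strand[b] > 0 else TAIL)
                return (b, TAIL if strand[b] > 0 else HEAD)

            for a in racf_adjacencies(racfs):
                (ia, ea), (ib, eb) = a.ends()
                out.add(Adjacency(block_end(ia, ea), block_end(ib, eb)))
            return out

        ref_root = block_adjacencies("root")
        ref_tip = block_adjacencies("F")
        changed = len(ref_root ^ ref_tip) / max(len(ref_root | ref_tip), 1)
        assert changed < 0.10


class TestProjection:
    def test_sf_level_genome_matches_projection_for_tips(self, small_history):
        tree, genomes, _, maps = small_history
        sfs, _ = detect_sfs({t: maps[t] for t in tree.tips()}, 300_000)
        direct = sf_level_genome(sfs, "A")
        projected = project_sf_genome(sfs, maps["A"], "A")
        assert adjacencies_of(direct) == adjacencies_of(projected)
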