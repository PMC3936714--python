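import numpy as np
import pytest

import oriscope as o
from oriscope.genome_io import GenomeAssembly, GenomeIOError, Replicon, revcomp
from oriscope.origin_scanner import (
    DEFAULT_ORB_CONSENSUS,
    annotate_origins,
    find_at_rich,
    find_enhancer,
    pair_inverted_orbs,
    scan_orbs,
)

from _oracles import brute_force_inverted_repeat, brute_force_orb_scan


def _random_assembly(seed, length=5000, gc=0.5):
    rng = np.random.default_rng(seed)
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    seq = "".join(np.array(list("ACGT"))[rng.choice(4, length, p=p)])
    return GenomeAssembly((Replicon("r", seq),))


class TestScanOrbs:
    def test_poly_a_has_no_hits(self):
        asm = GenomeAssembly((Replicon("r", "A" * 10_000),))
        assert scan_orbs(asm) == []

    def test_empty_consensus_rejected(self):
        asm = _random_assembly(0)
        with pytest.raises(GenomeIOError):
            scan_orbs(asm, consensus="")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_hamming_oracle(self, seed):
        rng = np.random.default_rng(seed)
        asm = _random_assembly(seed + 100)
        seq = asm.replicons[0].sequence
        # plant a few degenerate copies so the comparison is not vacuous
        planted = []
        for k in range(4):
            inst = list(DEFAULT_ORB_CONSENSUS)
            for i in rng.choice(len(inst), size=k % 4, replace=False):
                inst[i] = rng.choice([b for b in "ACGT" if b != inst[i]])
            inst = "".join(inst)
            if k % 2:
                inst = revcomp(inst)
            pos = 200 + 800 * k
            seq = seq[:pos] + inst + seq[pos + len(inst):]
            planted.append(pos)
        asm = GenomeAssembly((Replicon("r", seq),))
        hits = scan_orbs(asm)
        got = sorted((h.start, h.end, h.strand, h.mismatches) for h in hits)
        expected = brute_force_orb_scan(seq, DEFAULT_ORB_CONSENSUS, 3)
        assert got == expected
        assert set(planted) <= {h[0] for h in got}

    def test_strand_symmetry_under_reverse_complement(self, oric2_build):
        assembly, _, _ = oric2_build
        L = assembly.replicons[0].length
        mirrored = GenomeAssembly(
            (Replicon("r", revcomp(assembly.replicons[0].sequence)),))
        fwd = scan_orbs(assembly)
        rev = scan_orbs(mirrored)
        flip = sorted(
            (L - h.end, L - h.start, "-" if h.strand == "+" else "+",
             h.mismatches)
            for h in fwd
        )
        assert flip == sorted(
            (h.start, h.end, h.strand, h.mismatches) for h in rev)

    def test_planted_orbs_carry_gstrings(self, oric1_build):
        assembly, gt, _ = oric1_build
        hits = scan_orbs(assembly)
        assert len(hits) == 2
        by_strand = {h.strand: h for h in hits}
        assert by_strand["+"].start == gt["oriC1.orb_left"].start
        assert by_strand["-"].start == gt["oriC1.orb_right"].start
        assert all(h.has_gstring and h.gstring_len >= 6 for h in hits)

    def test_gstring_mutation_strips_the_flag(self, oric1_build):
        # G-run -> A-run at the plus-strand ORB: the hit survives but its
        # halophile-specific G-string extension is gone
        assembly, gt, _ = oric1_build
        mutated = o.apply_named_mutation(assembly, gt, "oriC1", "SMII")
        hits = scan_orbs(mutated)
        by_strand = {h.strand: h for h in hits}
        assert not by_strand["+"].has_gstring
        assert by_strand["-"].has_gstring

    def test_hit_across_circular_seam_is_found(self):
        inst = DEFAULT_ORB_CONSENSUS
        rng = np.random.default_rng(5)
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 3000)])
        # place the motif across the origin of the circle
        seq = inst[8:] + bg + inst[:8]
        asm = GenomeAssembly((Replicon("r", seq),))
        hits = scan_orbs(asm)
        assert any(h.start == len(seq) - 8 and h.strand == "+" for h in hits)


class TestFindAtRich:
    def test_all_at_sequence_is_one_region(self):
        rep = Replicon("r", "AT" * 1000)
        regions = find_at_rich(rep, min_at=0.9)
        assert len(regions) == 1
        s, e, frac = regions[0]
        assert e - s >= rep.length
        assert frac == 1.0

    def test_planted_core_is_the_only_region(self, oric1_build):
        assembly, gt, _ = oric1_build
        regions = find_at_rich(assembly.replicons[0])
        core = gt["oriC1.at_core"]
        overlapping = [r for r in regions
                       if r[0] < core.end and core.start < r[1]]
        assert len(overlapping) == 1
        assert len(regions) == 1

    def test_uniform_background_yields_no_region(self):
        asm = _random_assembly(77, length=20_000, gc=0.6)
        assert find_at_rich(asm.replicons[0]) == []

    def test_window_larger_than_replicon_rejected(self):
        with pytest.raises(GenomeIOError):
            find_at_rich(Replicon("r", "ACGT" * 10), window=100)


class TestPairing:
    def test_no_opposite_strand_pairs_gives_no_candidates(self):
        asm = _random_assembly(3)
        hits = [h for h in scan_orbs(asm) if h.strand == "+"]
        assert pair_inverted_orbs(hits, {"r": []}, asm) == []

    def test_mimic_origin_is_paired_over_the_planted_locus(self, oric1_build):
        assembly, gt, _ = oric1_build
        res = annotate_origins(assembly)
        assert len(res.candidates) == 1
        cand = res.candidates[0]
        locus = gt["oriC1.origin_locus"]
        assert cand.span[0] == locus.start
        assert cand.span[1] == locus.end
        core = gt["oriC1.at_core"]
        assert cand.at_core[0] < core.end and core.start < cand.at_core[1]

    def test_two_origin_genome_yields_both_candidates(self):
        spec1 = o.OriginArchitectureSpec(name="oriC1")
        spec2 = o.OriginArchitectureSpec(name="oriC2", enhancer_arm=None,
                                         titration_orb_count=11,
                                         titration_region_len=722)
        assembly, gt = o.build_genome(
            [spec1, spec2], [120_000], seed=11,
            placements=[(0, 20_000), (0, 80_000)])
        res = annotate_origins(assembly)
        assert len(res.candidates) == 2
        spans = sorted(c.span[0] for c in res.candidates)
        assert spans == [gt["oriC1.origin_locus"].start,
                         gt["oriC2.origin_locus"].start]


class TestEnhancer:
    def test_planted_arm_pair_is_found_with_arm_ten(self, oric1_build):
        assembly, _, _ = oric1_build
        res = annotate_origins(assembly)
        enh = res.candidates[0].enhancer
        assert enh is not None
        assert enh.arm_len == 10
        assert enh.g_fraction == pytest.approx(0.9)

    def test_arm_sequences_are_exact_reverse_complements(self, oric1_build):
        assembly, _, _ = oric1_build
        res = annotate_origins(assembly)
        enh = res.candidates[0].enhancer
        seq = assembly.replicons[0].sequence
        left = seq[enh.left_arm[0]:enh.left_arm[1]]
        right = seq[enh.right_arm[0]:enh.right_arm[1]]
        assert right == revcomp(left)

    def test_absent_in_poly_a_interval(self, oric1_build):
        assembly, gt, _ = oric1_build
        res = annotate_origins(assembly)
        cand = res.candidates[0]
        core = gt["oriC1.at_core"]
        # erase everything G-rich between the G-strings
        flat = assembly
        for eid in ("oriC1.enhancer_left", "oriC1.enhancer_right"):
            e = gt[eid]
            flat = o.apply_site_mutation(flat, e, "A" * (e.end - e.start))
        flat = o.apply_site_mutation(
            flat, core, "AT" * ((core.end - core.start) // 2))
        assert find_enhancer(cand, flat) is None

    def test_site_mutants_abolish_the_enhancer_call(self, oric1_build):
        assembly, gt, _ = oric1_build
        for sm in ("SMIII", "SMIV"):
            mutated = o.apply_named_mutation(assembly, gt, "oriC1", sm)
            res = annotate_origins(mutated)
            assert res.candidates[0].enhancer is None

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_repeat_oracle(self, seed):
        # random interval seeded with a planted repeat half the time
        rng = np.random.default_rng(1000 + seed)
        n = 260
        s = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        if seed % 2:
            arm = "GGGCGGGGAGGG"
            s = s[:40] + arm + s[52:200] + revcomp(arm) + s[212:]
        oracle = brute_force_inverted_repeat(s, arm_min=8, g_rich_min=0.8)
        got = _run_find_enhancer_on_interval(s)
        if oracle is None:
            assert got is None
        else:
            assert got is not None
            arm_len, left_start, right_start = oracle
            assert got.arm_len == arm_len
            assert got.left_arm[0] - _PAD == left_start
            assert got.right_arm[0] - _PAD == right_start


_PAD = None  # set by helper: interval offset inside the scaffold


def _run_find_enhancer_on_interval(interval_seq):
    """Wrap an arbitrary interval in a synthetic ORB pair so find_enhancer
    searches exactly that interval."""
    global _PAD
    from oriscope.origin_scanner import ORBHit, OriginCandidate

    cons = DEFAULT_ORB_CONSENSUS
    left = cons
    right = revcomp(cons)
    seq = left + interval_seq + right + "ACGT" * 50
    _PAD = len(left)
    asm = GenomeAssembly((Replicon("r", seq),))
    p = ORBHit("r", 0, len(cons), "+", 0, False, 0)
    q = ORBHit("r", _PAD + len(interval_seq),
               _PAD + len(interval_seq) + len(cons), "-", 0, False, 0)
    cand = OriginCandidate(
        replicon_id="r",
        span=(0, q.end),
        orb_pair=(p, q),
        at_core=(0, 0, 0.0),
    )
    return find_enhancer(cand, asm)


class TestTitrationRegions:
    def test_eleven_orbs_in_mimic_cluster(self, oric2_build):
        assembly, gt, _ = oric2_build
        res = annotate_origins(assembly)
        assert len(res.titration_regions) == 1
        region = res.titration_regions[0]
        assert region.orb_count == 11
        assert region.intergenic
        truth = gt["oriC2.titration_region"]
        assert truth.start <= region.span[0]
        assert region.span[1] <= truth.end
        gene = gt["oriC2.cdc6"]
        assert region.span[0] >= gene.end  # downstream of the cdc6 analog

    def test_three_orbs_in_lacusprofundi_mimic(self, hla_build):
        assembly, _, _ = hla_build
        res = annotate_origins(assembly)
        assert [r.orb_count for r in res.titration_regions] == [3]

    def test_no_cluster_when_none_planted(self, oric1_build):
        assembly, _, _ = oric1_build
        res = annotate_origins(assembly)
        assert res.titration_regions == []

    def test_origin_candidate_orbs_are_excluded(self, oric2_build):
        assembly, _, _ = oric2_build
        res = annotate_origins(assembly)
        cand_span = res.candidates[0].span
        for region in res.titration_regions:
            for h in region.orb_hits:
                assert not (h.start < cand_span[1] and cand_span[0] < h.end)


class TestClassification:
    def test_mimic_candidate_is_ori_cdc6(self, oric1_build):
        assembly, _, cfg = oric1_build
        res = annotate_origins(assembly)
        cand = res.candidates[0]
        assert cand.classification == "ori_cdc6"
        assert cand.initiator_distance == cfg["origin"]["cdc6_offset"] + 1
        assert cand.nearest_initiator.name == "cdc6_oriC1"

    def test_no_initiator_means_orphan(self, oric1_build):
        assembly, _, _ = oric1_build
        stripped = GenomeAssembly(assembly.replicons, ())
        res = annotate_origins(stripped)
        cand = res.candidates[0]
        assert cand.classification == "orphan"
        assert cand.initiator_distance is None

    def test_seven_origins_on_three_replicons_all_recovered(self):
        # the multireplicon layout: 2 + 4 + 1 ori-cdc6 loci
        specs = [o.OriginArchitectureSpec(name=f"ori{i}", enhancer_arm=None)
                 for i in range(7)]
        placements = [(0, 20_000), (0, 70_000),
                      (1, 10_000), (1, 30_000), (1, 50_000), (1, 70_000),
                      (2, 15_000)]
        assembly, gt = o.build_genome(
            specs, [100_000, 90_000, 40_000], seed=23, placements=placements)
        res = annotate_origins(assembly)
        ori = [c for c in res.candidates if c.classification == "ori_cdc6"]
        assert len(ori) == 7
        found = sorted((c.replicon_id, c.span[0]) for c in ori)
        expected = sorted(
            (gt[f"ori{i}.origin_locus"].replicon_id,
             gt[f"ori{i}.origin_locus"].start)
            for i in range(7)
        )
        assert found == expected


class TestRecoveryAcrossSeeds:
    def test_planted_origin_recovery_is_exact_on_seeded_genomes(self):
        # precision = recall = 1 with default parameters
        for seed in range(10):
            spec = o.OriginArchitectureSpec(
                name="ori", enhancer_arm=None if seed % 2 else "GGGGAGGGGG")
            assembly, gt = o.build_genome([spec], [50_000], seed=seed,
                                          placements=[(0, 17_000)])
            res = annotate_origins(assembly)
            assert len(res.candidates) == 1
            locus = gt["ori.origin_locus"]
            assert res.candidates[0].span == (locus.start, locus.end)
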