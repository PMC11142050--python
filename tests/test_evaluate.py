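"""Error quantification: anchor alignment, SV classification against
hand-built toys for all six classes, het-switch attribution, N50 vs a
brute-force oracle, k-mer diversity and variant calling/merging."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mhcasm.core import ReadPair, revcomp, stage_rng
from mhcasm.evaluate import (NoAnchorsError, VariantRecord, anchor_align,
                             assembly_stats, attribute_het_switch, call_errors,
                             call_variants_vs_reference,
                             merge_haplotype_variants, unique_kmer_ratio)


def rand_dna(n, seed=0, tag="dna"):
    rng = stage_rng(seed, tag)
    return "".join("ACGT"[c] for c in rng.integers(0, 4, n))


class TestAnchorAlign:
    def test_identical_sequences_single_match_block(self):
        seq = rand_dna(3000, seed=1)
        chain = anchor_align(seq, seq)
        assert chain.strand == "+"
        assert len(chain.blocks) == 1
        assert chain.blocks[0].ops == [("M", 3000)]

    def test_deletion_bridged_between_flanking_anchors(self):
        truth = rand_dna(5000, seed=2)
        assembly = truth[:2000] + truth[2500:]
        chain = anchor_align(assembly, truth)
        ops = [op for b in chain.blocks for op in b.ops]
        assert ("D", 500) in ops
        report = call_errors(chain)
        dels = [e for e in report.events if e.type == "deletion"]
        assert len(dels) == 1 and dels[0].len == 500 and dels[0].pos == 2000

    def test_reversed_assembly_is_oriented_then_monotone(self):
        truth = rand_dna(4000, seed=3)
        chain = anchor_align(revcomp(truth), truth)
        assert chain.strand == "-"
        assert chain.assembly == truth
        starts = [b.t_start for b in chain.blocks]
        assert starts == sorted(starts)

    def test_unrelated_sequences_raise(self):
        with pytest.raises(NoAnchorsError):
            anchor_align(rand_dna(1000, seed=4, tag="a"),
                         rand_dna(1000, seed=5, tag="b"))


class TestCallErrors:
    def test_identical_sequences_zero_percentages(self):
        seq = rand_dna(4000, seed=6)
        r = call_errors(anchor_align(seq, seq))
        assert (r.base_call_error_pct, r.nonrepeat_sv_error_pct,
                r.repeat_sv_error_pct, r.total_error_pct) == (0, 0, 0, 0)

    def test_five_snps_on_5000_bp_is_point_one_percent(self):
        truth = rand_dna(5000, seed=7)
        asm = list(truth)
        for pos in (400, 1400, 2400, 3400, 4400):
            asm[pos] = "A" if truth[pos] != "A" else "C"
        r = call_errors(anchor_align("".join(asm), truth))
        assert r.base_call_error_pct == pytest.approx(0.1)
        assert r.total_error_pct == pytest.approx(0.1)
        assert all(e.type == "SNP" for e in r.events)

    def test_component_percentages_sum_to_total(self):
        truth = rand_dna(6000, seed=8)
        asm = truth[:1000] + truth[1000:1050] + truth[1000:3000] + truth[3500:]
        r = call_errors(anchor_align(asm, truth), repeat_bed=[(5000, 5500, "X")])
        assert r.total_error_pct == pytest.approx(
            r.base_call_error_pct + r.nonrepeat_sv_error_pct + r.repeat_sv_error_pct)

    def test_assembly_n_positions_are_uncalled(self):
        truth = rand_dna(3000, seed=9)
        asm = truth[:1500] + "N" * 20 + truth[1520:]
        r = call_errors(anchor_align(asm, truth))
        assert r.events == []


class TestSVClassification:
    """One constructed toy per SV class; classifications are hand-derived."""

    @pytest.fixture()
    def truth(self):
        # unique background with an annotated diverged repeat copy at
        # [3000, 3630) and a 30 bp tandem motif repeated at [6000, 6060)
        core = rand_dna(9000, seed=10)
        rep = rand_dna(630, seed=11, tag="rep")
        motif = rand_dna(30, seed=12, tag="motif")
        seq = core[:3000] + rep + core[3000:5370] + motif * 2 + core[5370:]
        bed = [(3000, 3630, "repX")]
        return seq, bed, rep, motif

    def expect_single(self, report, etype, length, repeat_associated):
        evs = [e for e in report.events if e.type != "SNP"]
        assert len(evs) == 1
        e = evs[0]
        assert (e.type, e.len, e.repeat_associated) == (etype, length, repeat_associated)

    def test_plain_insertion(self, truth):
        seq, bed, _rep, _motif = truth
        asm = seq[:1500] + rand_dna(120, seed=13, tag="ins") + seq[1500:]
        self.expect_single(call_errors(anchor_align(asm, seq), bed),
                           "insertion", 120, False)

    def test_plain_deletion(self, truth):
        seq, bed, _rep, _motif = truth
        asm = seq[:1500] + seq[1700:]
        self.expect_single(call_errors(anchor_align(asm, seq), bed),
                           "deletion", 200, False)

    def test_repeat_expansion(self, truth):
        seq, bed, rep, _motif = truth
        # an extra (mutated) copy of the annotated repeat inserted inside it
        extra = list(rep)
        rng = stage_rng(14, "mut")
        for pos in rng.choice(len(extra), size=80, replace=False):
            extra[pos] = "ACGT"[int(rng.integers(4))]
        asm = seq[:3300] + "".join(extra) + seq[3300:]
        self.expect_single(call_errors(anchor_align(asm, seq), bed),
                           "repeat_expansion", 630, True)

    def test_repeat_contraction(self, truth):
        seq, bed, _rep, _motif = truth
        asm = seq[:3100] + seq[3400:]          # 300 bp lost inside the repeat
        self.expect_single(call_errors(anchor_align(asm, seq), bed),
                           "repeat_contraction", 300, True)

    def test_tandem_expansion(self, truth):
        seq, bed, _rep, motif = truth
        asm = seq[:6000] + motif + seq[6000:]  # third copy of the 30 bp motif
        self.expect_single(call_errors(anchor_align(asm, seq), bed),
                           "tandem_expansion", 30, True)

    def test_tandem_contraction(self, truth):
        seq, bed, _rep, motif = truth
        asm = seq[:6000] + seq[6030:]          # one motif copy removed
        self.expect_single(call_errors(anchor_align(asm, seq), bed),
                           "tandem_contraction", 30, True)


class TestHetSwitch:
    def test_attribution_splits_switches_from_true_errors(self):
        hap_a = rand_dna(4000, seed=15)
        b = list(hap_a)
        het_sites = [500, 1500, 2500, 3500]
        for pos in het_sites:
            b[pos] = "A" if hap_a[pos] != "A" else "G"
        hap_b = "".join(b)
        asm = list(hap_a)
        asm[500] = hap_b[500]                 # het inclusion
        asm[1500] = hap_b[1500]               # het inclusion
        third = [x for x in "ACGT" if x not in (hap_a[2200], )][0]
        asm[2200] = third if third != hap_a[2200] else "T"   # true error site
        report = call_errors(anchor_align("".join(asm), hap_a))
        snps = [e for e in report.events if e.type == "SNP"]
        true_frac, het_frac = attribute_het_switch(snps, hap_a, hap_b)
        assert het_frac == pytest.approx(2 / 3)
        assert true_frac == pytest.approx(1 / 3)

    def test_no_mismatches_reports_zero_zero(self):
        hap = rand_dna(2000, seed=16)
        assert attribute_het_switch([], hap, hap) == (0.0, 0.0)


class TestAssemblyStats:
    def test_worked_example(self):
        st_ = assembly_stats([5, 4, 3, 2, 1])
        assert st_.n50 == 4 and st_.n_contigs == 5 and st_.total_len == 15

    def test_single_and_uniform(self):
        assert assembly_stats([77]).n50 == 77
        assert assembly_stats([8, 8, 8]).n50 == 8

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            assembly_stats([])

    @given(st.lists(st.integers(min_value=1, max_value=10_000), min_size=1,
                    max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_brute_force(self, lengths):
        def oracle(ls):
            ls = sorted(ls, reverse=True)
            half = sum(ls) / 2
            acc = 0
            for l in ls:
                acc += l
                if acc >= half:
                    return l
        assert assembly_stats(lengths).n50 == oracle(lengths)


class TestUniqueKmerRatio:
    def test_identical_reads_ratio_near_zero(self):
        seq = rand_dna(150, seed=17)
        pairs = [ReadPair(f"p{i}", seq, "F" * 150, seq, "F" * 150) for i in range(50)]
        assert unique_kmer_ratio(pairs) == 0.0

    def test_all_distinct_reads_ratio_one(self):
        pairs = [ReadPair(f"p{i}", rand_dna(150, seed=18, tag=f"a{i}"), "F" * 150,
                          rand_dna(150, seed=18, tag=f"b{i}"), "F" * 150)
                 for i in range(30)]
        assert unique_kmer_ratio(pairs) == pytest.approx(1.0)

    def test_no_long_enough_read_rejected(self):
        with pytest.raises(ValueError):
            unique_kmer_ratio([ReadPair("p", "ACGT", "FFFF", "ACGT", "FFFF")])

    def test_higher_divergence_gives_higher_ratio(self):
        from mhcasm.simulate import (ReadSimConfig, generate_guide_panel,
                                     simulate_individual, simulate_reads)
        panel = generate_guide_panel(1, base_len=10_000, dr_mix=["DR8"], seed=19)
        cfg = ReadSimConfig(depth=30, base_error=0.0, g_run_rate=0.0,
                            low_qual_tail_rate=0.0, seed=19)
        ratios = {}
        for div in (0.0, 0.02):
            ind = simulate_individual(panel, (panel[0].id, panel[0].id),
                                      divergence=div, indel_rate=0.0, seed=19)
            ratios[div] = unique_kmer_ratio(simulate_reads(ind, cfg))
        assert ratios[0.02] > ratios[0.0]


class TestVariants:
    def test_identical_sequences_no_records(self):
        seq = rand_dna(2000, seed=20)
        assert call_variants_vs_reference(seq, seq) == []

    def test_single_substitution(self):
        ref = rand_dna(2000, seed=21)
        p = 777
        alt = "A" if ref[p] != "A" else "C"
        recs = call_variants_vs_reference(ref[:p] + alt + ref[p + 1:], ref)
        assert recs == [VariantRecord(p, ref[p], alt)]

    def test_deletion_left_normalized_in_tandem_context(self):
        # reference carries ...T ACACAC G...; deleting any "AC" copy must
        # normalise to the leftmost representation anchored on the T
        left = rand_dna(600, seed=22, tag="l")
        right = rand_dna(600, seed=23, tag="r")
        ref = left + "T" + "AC" * 3 + "G" + right
        t_pos = len(left)
        cons = left + "T" + "AC" * 2 + "G" + right
        recs = call_variants_vs_reference(cons, ref)
        assert len(recs) == 1
        assert recs[0] == VariantRecord(t_pos, "TAC", "T")

    def test_merge_semantics(self):
        a = [VariantRecord(10, "A", "T"), VariantRecord(20, "C", "G"),
             VariantRecord(30, "G", "A")]
        b = [VariantRecord(10, "A", "T"), VariantRecord(30, "G", "C")]
        merged = merge_haplotype_variants(a, b)
        assert (10, "A", ["T"], "1/1") in merged
        assert (20, "C", ["G"], "0/1") in merged
        assert (30, "G", ["A", "C"], "1/2") in merged
        assert merge_haplotype_variants([], []) == []

    def test_vcf_output_parses_with_pysam(self, tmp_path):
        import pysam

        from mhcasm.io import write_vcf
        ref = rand_dna(1000, seed=24)
        rows = [(10, "A", ["T"], "0/1"), (500, "GAC", ["G"], "1/1")]
        path = tmp_path / "x.vcf"
        write_vcf(path, "guide", len(ref), rows, sample="ind1")
        with pysam.VariantFile(str(path)) as vf:
            recs = list(vf)
        assert [r.pos for r in recs] == [11, 501]        # VCF is 1-based
        assert recs[0].samples["ind1"]["GT"] == (0, 1)
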