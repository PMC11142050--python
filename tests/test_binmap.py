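"""Mapper semantics: seed index, end-to-end scoring threshold, binning
set algebra, superblock tiling, and equivalence of accept/reject decisions
with an independent full dynamic-programming aligner."""

import numpy as np
import pytest

from mhcasm.binmap import (Alignment, Scoring, SeedIndex, bin_reads,
                           build_superblocks, index_guide, map_read)
from mhcasm.core import ReadPair, revcomp, stage_rng


# ----------------------------------------------------------------- oracle

def oracle_best_score(read: str, target: str, sc: Scoring) -> float:
    """Independent full Gotoh semi-global aligner (query end-to-end, free
    target ends), over both strands. Plain Python, no seeding heuristics."""
    best = -np.inf
    for q in (read, revcomp(read)):
        n, m = len(q), len(target)
        NEG = -1e9
        H = [0.0] * (m + 1)
        V = [NEG] * (m + 1)
        Z = [NEG] * (m + 1)
        for i in range(1, n + 1):
            prev_diag = H[0]
            H[0] = sc.gap_open + sc.gap_extend * i
            V[0] = H[0]
            Z[0] = NEG
            for j in range(1, m + 1):
                sub = sc.match if q[i - 1] == target[j - 1] else sc.mismatch
                V[j] = max(H[j] + sc.gap_open + sc.gap_extend, V[j] + sc.gap_extend)
                Z[j] = max(H[j - 1] + sc.gap_open + sc.gap_extend,
                           Z[j - 1] + sc.gap_extend)
                h = prev_diag + sub
                prev_diag = H[j]
                H[j] = max(h, V[j], Z[j])
        best = max(best, max(H))
    return best


def mutate(seq, n_sub, n_indel, rng):
    s = list(seq)
    for pos in rng.choice(len(s), size=n_sub, replace=False):
        s[pos] = "ACGT"[("ACGT".index(s[pos]) + 1 + int(rng.integers(3))) % 4]
    for _ in range(n_indel):
        pos = int(rng.integers(1, len(s) - 1))
        if rng.random() < 0.5:
            s.insert(pos, "ACGT"[int(rng.integers(4))])
        else:
            del s[pos]
    return "".join(s)


class TestOracleEquivalence:
    def test_accept_reject_matches_full_dp(self):
        """Seeded mapper decisions equal brute-force DP decisions on small
        instances (short targets allow the exhaustive rescue)."""
        rng = stage_rng(17, "oracle")
        sc = Scoring()
        for trial in range(25):
            tlen = int(rng.integers(300, 2000))
            target = "".join("ACGT"[c] for c in rng.integers(0, 4, tlen))
            index = SeedIndex({"t": target}, seed_k=15)
            rlen = int(rng.integers(30, 61))
            start = int(rng.integers(0, tlen - rlen))
            base = target[start:start + rlen]
            reads = [
                base,
                revcomp(base),
                mutate(base, n_sub=int(rng.integers(0, rlen // 8 + 1)), n_indel=0, rng=rng),
                mutate(base, n_sub=int(rng.integers(0, rlen // 6 + 1)),
                       n_indel=int(rng.integers(0, 3)), rng=rng),
                "".join("ACGT"[c] for c in rng.integers(0, 4, rlen)),  # unrelated
            ]
            for read in reads:
                got = map_read(read, index, scoring=sc) is not None
                want = oracle_best_score(read, target, sc) >= sc.threshold(len(read))
                assert got == want, (trial, read)

    def test_reported_score_never_beats_oracle(self):
        rng = stage_rng(23, "oracle2")
        sc = Scoring()
        target = "".join("ACGT"[c] for c in rng.integers(0, 4, 800))
        index = SeedIndex({"t": target}, seed_k=15)
        for _ in range(10):
            read = mutate(target[100:160], n_sub=3, n_indel=1, rng=rng)
            al = map_read(read, index, scoring=sc)
            if al is not None:
                assert al.score <= oracle_best_score(read, target, sc) + 1e-9


class TestIndex:
    def test_forward_seed_positions(self):
        rng = stage_rng(3, "idx")
        guide = "".join("ACGT"[c] for c in rng.integers(0, 4, 1000))
        idx = index_guide(guide, seed_k=15)
        assert idx.n_forward_seeds == 1000 - 15 + 1

    def test_homopolymer_guide_single_distinct_seed(self):
        idx = index_guide("A" * 100, seed_k=15)
        assert len(idx.seeds) == 1

    def test_k_longer_than_guide_rejected(self):
        with pytest.raises(ValueError):
            index_guide("ACGTACGT", seed_k=15)


@pytest.fixture(scope="module")
def guide():
    rng = stage_rng(5, "guide")
    return "".join("ACGT"[c] for c in rng.integers(0, 4, 3000))


class TestMapRead:
    def test_perfect_match_scores_zero(self, guide):
        idx = index_guide(guide)
        al = map_read(guide[500:650], idx)
        assert al is not None and al.score == 0
        assert al.target_start == 500 and al.strand == "+"
        assert al.edits == [("M", 150)]

    def test_threshold_boundary_15_vs_16_mismatches(self, guide):
        idx = index_guide(guide)
        read = list(guide[1000:1150])
        positions = list(range(4, 150, 9))[:16]
        for i, pos in enumerate(positions):
            read[pos] = "ACGT"[("ACGT".index(read[pos]) + 1) % 4]
            if i == 14:
                r15 = "".join(read)
        r16 = "".join(read)
        al15 = map_read(r15, idx)
        assert al15 is not None and al15.score == -90        # 15 x -6 >= -0.6 x 150
        assert map_read(r16, idx) is None                    # -96 < -90

    def test_reverse_strand_and_alignment_invariants(self, guide):
        idx = index_guide(guide)
        al = map_read(revcomp(guide[2000:2150]), idx)
        assert al is not None and al.strand == "-"
        assert al.target_start == 2000
        assert al.score <= 0
        assert sum(l for op, l in al.edits if op in "MXI") == 150

    def test_unmapped_is_a_value(self, guide):
        idx = index_guide(guide)
        rng = stage_rng(9, "unrelated")
        assert map_read("".join("ACGT"[c] for c in rng.integers(0, 4, 150)), idx) is None


class TestBinReads:
    def test_partition_is_exact(self, small_panel, small_reads):
        idx = SeedIndex({small_panel[0].id: small_panel[0].sequence})
        sub = small_reads[:800]
        res = bin_reads(sub, idx)
        assert len(res.mapped) + len(res.unmapped) == len(sub)
        assert {p.id for p in res.mapped}.isdisjoint({p.id for p in res.unmapped})
        assert [p.id for p in res.mapped + res.unmapped] and \
            set(p.id for p in res.mapped) | set(p.id for p in res.unmapped) == \
            {p.id for p in sub}

    def test_novel_cassette_reads_fall_in_unmapped_bin(self, small_panel, small_individual,
                                                       small_reads):
        # reads drawn from within the DR4 cassette do not align to the DR3 guide
        dr3 = small_panel[0]
        idx = SeedIndex({dr3.id: dr3.sequence})
        cass_lo, cass_hi = 22_000, 22_000 + 14_000   # locus in the DR4 haplotype
        inside = [p for p in small_reads
                  if p.id.split(":")[2] == "hB"
                  and cass_lo + 200 < int(p.id.split(":")[3])
                  and int(p.id.split(":")[3]) + int(p.id.split(":")[4]) < cass_hi - 200]
        res = bin_reads(inside[:60], idx)
        assert len(res.unmapped) == len(inside[:60])

    def test_both_mates_perfect_in_mapped_bin(self, small_panel):
        g = small_panel[0].sequence
        idx = SeedIndex({small_panel[0].id: g})
        p = ReadPair("p", g[100:250], "F" * 150, revcomp(g[400:550]), "F" * 150)
        res = bin_reads([p], idx)
        assert res.mapped and not res.unmapped


class TestSuperblocks:
    def test_tiling_arithmetic(self):
        fps = [("a", 0, 300), ("b", 50_000, 50_300), ("c", 99_700, 100_000)]
        sbs = build_superblocks(fps, target_span=50_000, overlap=5_000)
        assert [s.guide_interval for s in sbs] == [(0, 50_000), (45_000, 95_000),
                                                  (90_000, 100_000)]

    def test_pair_assigned_to_every_intersecting_tile(self):
        fps = [("a", 0, 300), ("x", 46_000, 46_500), ("c", 99_700, 100_000)]
        sbs = build_superblocks(fps, target_span=50_000, overlap=5_000)
        homes = [s.guide_interval for s in sbs if "x" in s.read_ids]
        assert homes == [(0, 50_000), (45_000, 95_000)]

    def test_empty_and_single_window_cases(self):
        assert build_superblocks([], 50_000, 5_000) == []
        sbs = build_superblocks([("a", 1000, 1300), ("b", 9000, 9300)],
                                target_span=50_000, overlap=5_000)
        assert len(sbs) == 1 and sbs[0].guide_interval == (1000, 9300)

    def test_overlap_must_be_smaller_than_span(self):
        with pytest.raises(ValueError):
            build_superblocks([("a", 0, 100)], target_span=1000, overlap=1000)

    def test_est_coverage(self):
        fps = [(f"p{i}", 0, 1000) for i in range(30)]
        sbs = build_superblocks(fps, target_span=50_000, overlap=5_000)
        assert len(sbs) == 1
        assert sbs[0].est_coverage == pytest.approx(30.0)
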