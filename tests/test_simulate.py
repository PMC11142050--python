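"""Simulator contracts: truth round-trips, determinism, coverage and the
class II structural length ordering."""

import numpy as np
import pytest

from mhcasm.core import revcomp
from mhcasm.simulate import (DR_CASSETTE_LEN, ReadSimConfig, allele_exemplars,
                             apply_variants, generate_guide_panel,
                             simulate_individual, simulate_reads,
                             truth_repeat_bed)


class TestGuidePanel:
    def test_dr_length_ordering_from_one_ancestor(self):
        c4 = [(1, 0, 1)] * 3          # same C4 block, so lengths isolate the cassettes
        panel = generate_guide_panel(3, base_len=60_000,
                                     dr_mix=["DR4", "DR3", "DR8"], seed=2, c4_mix=c4)
        by_class = {g.dr_class: g for g in panel}
        assert by_class["DR4"].length > by_class["DR3"].length > by_class["DR8"].length
        assert (by_class["DR4"].length - by_class["DR3"].length ==
                DR_CASSETTE_LEN["DR4"] - DR_CASSETTE_LEN["DR3"])

    def test_zero_repeat_density_gives_empty_bed(self):
        panel = generate_guide_panel(2, base_len=30_000, repeat_density=0.0, seed=1)
        assert all(g.repeat_intervals == [] for g in panel)

    def test_repeat_intervals_within_bounds_and_recorded(self):
        panel = generate_guide_panel(2, base_len=50_000, dr_mix=["DR3", "DR4"],
                                     repeat_density=0.2, seed=4)
        for g in panel:
            assert g.repeat_intervals, "expected repeats at density 0.2"
            total = sum(e - s for s, e, _f in g.repeat_intervals)
            assert 0.1 * 50_000 < total < 0.35 * 50_000
            for s, e, _fam in g.repeat_intervals:
                assert 0 <= s < e <= g.length
            # intervals annotate actual repeat-family copies: same-family
            # intervals have correlated sequence
            fams = {}
            for s, e, fam in g.repeat_intervals:
                fams.setdefault(fam, []).append(g.sequence[s:e])
            for copies in fams.values():
                if len(copies) >= 2:
                    # copies are each ~12% diverged from the family
                    # consensus, so pairwise identity sits near 78%
                    a, b = copies[0], copies[1]
                    n = min(len(a), len(b))
                    ident = sum(x == y for x, y in zip(a[:n], b[:n])) / n
                    assert 0.65 < ident < 0.95

    def test_same_seed_is_byte_identical(self):
        p1 = generate_guide_panel(2, base_len=20_000, dr_mix=["DR2", "DR3"],
                                  repeat_density=0.1, seed=9)
        p2 = generate_guide_panel(2, base_len=20_000, dr_mix=["DR2", "DR3"],
                                  repeat_density=0.1, seed=9)
        assert [g.sequence for g in p1] == [g.sequence for g in p2]
        assert [g.repeat_intervals for g in p1] == [g.repeat_intervals for g in p2]

    def test_invalid_dr_class_rejected(self):
        with pytest.raises(ValueError, match="invalid dr_class"):
            generate_guide_panel(1, base_len=20_000, dr_mix=["DR7"], seed=0)

    def test_allele_exemplars_cover_cassette_classes_only(self):
        ex = allele_exemplars(["DR3", "DR4", "DR8"], seed=5)
        assert "03" in ex and "04" in ex
        assert "08" not in ex          # DR8 carries no cassette to key on


class TestDiploidIndividual:
    def test_zero_rates_reproduce_guides_exactly(self, small_panel):
        ind = simulate_individual(small_panel, (small_panel[0].id, small_panel[1].id),
                                  divergence=0.0, indel_rate=0.0, seed=1)
        assert ind.hap_a == small_panel[0].sequence
        assert ind.hap_b == small_panel[1].sequence
        assert ind.truth_variants == []

    def test_truth_variants_round_trip(self, small_panel, small_individual):
        ind = small_individual
        assert apply_variants(small_panel[0].sequence, ind.truth_variants, "A") == ind.hap_a
        assert apply_variants(small_panel[1].sequence, ind.truth_variants, "B") == ind.hap_b

    def test_variant_count_tracks_rate(self, small_panel):
        # every recorded variant is an applied mutation; the count matches
        # the binomial draw at the stated rate
        ind = simulate_individual(small_panel, (small_panel[0].id, small_panel[1].id),
                                  divergence=0.01, indel_rate=0.0, seed=11)
        n_a = sum(1 for v in ind.truth_variants if v[0] == "A")
        L = small_panel[0].length
        assert abs(n_a - 0.01 * L) < 5 * np.sqrt(0.01 * L)
        assert all(v[4] == "snp" for v in ind.truth_variants)

    def test_heterozygous_genotype_spans_guide_classes(self, small_individual):
        assert small_individual.drb1_genotype == ("03", "04")

    def test_unrealistic_divergence_rejected(self, small_panel):
        with pytest.raises(ValueError, match="binning"):
            simulate_individual(small_panel, (small_panel[0].id, small_panel[1].id),
                                divergence=0.2, seed=0)

    def test_unknown_guide_rejected(self, small_panel):
        with pytest.raises(KeyError):
            simulate_individual(small_panel, ("nope", small_panel[1].id), seed=0)

    def test_truth_repeat_bed_lifts_through_indels(self, small_panel, small_individual):
        bed = truth_repeat_bed(small_panel[0], small_individual, "A")
        hap = small_individual.hap_a
        guide = small_panel[0].sequence
        import edlib
        for (s, e, fam), (gs, ge, gfam) in zip(bed, small_panel[0].repeat_intervals):
            assert fam == gfam
            assert 0 <= s < e <= len(hap)
            # lifted interval carries (near-)identical sequence; indels inside
            # the interval shift bases, so compare with an edit distance
            dist = edlib.align(hap[s:e], guide[gs:ge], task="distance")["editDistance"]
            assert dist / (e - s) < 0.1


class TestReadSimulation:
    def test_pair_count_formula(self, small_panel):
        ind = simulate_individual(small_panel, (small_panel[0].id, small_panel[0].id),
                                  divergence=0.0, indel_rate=0.0, seed=1)
        cfg = ReadSimConfig(depth=30, read_len=150, seed=1)
        pairs = simulate_reads(ind, cfg)
        expect = round(30 * (len(ind.hap_a) + len(ind.hap_b)) / (2 * 150))
        assert len(pairs) == expect

    def test_error_free_reads_substring_match_a_haplotype(self, small_panel):
        ind = simulate_individual(small_panel, (small_panel[0].id, small_panel[1].id),
                                  divergence=0.003, indel_rate=0.0, seed=2)
        cfg = ReadSimConfig(depth=2, base_error=0.0, g_run_rate=0.0,
                            low_qual_tail_rate=0.0, seed=2)
        genome = ind.hap_a + "#" + ind.hap_b
        for p in simulate_reads(ind, cfg)[:300]:
            for seq in (p.seq1, p.seq2):
                assert seq in genome or revcomp(seq) in genome

    def test_coverage_law(self, small_panel):
        ind = simulate_individual(small_panel, (small_panel[0].id, small_panel[1].id),
                                  divergence=0.0, indel_rate=0.0, seed=3)
        cfg = ReadSimConfig(depth=25, base_error=0.0, g_run_rate=0.0,
                            low_qual_tail_rate=0.0, seed=3)
        pairs = simulate_reads(ind, cfg)
        cov = np.zeros(len(ind.hap_a))
        for p in pairs:
            _ind, _pn, hap, start, insert, _flip = p.id.split(":")
            if hap != "hA":
                continue
            s, ins = int(start), int(insert)
            cov[s:s + 150] += 1
            cov[s + ins - 150:s + ins] += 1
        mean_cov = cov[200:-200].mean()       # interior, away from edge effects
        assert abs(mean_cov - 25) / 25 < 0.1

    def test_g_artifacts_reproducible_and_paced(self, small_panel):
        ind = simulate_individual(small_panel, (small_panel[0].id, small_panel[0].id),
                                  divergence=0.0, indel_rate=0.0, seed=4)
        cfg = ReadSimConfig(depth=15, g_run_rate=0.01, seed=9)
        n1 = sum(("G" * 20 in p.seq1) + ("G" * 20 in p.seq2)
                 for p in simulate_reads(ind, cfg))
        n2 = sum(("G" * 20 in p.seq1) + ("G" * 20 in p.seq2)
                 for p in simulate_reads(ind, cfg))
        assert n1 == n2
        n_reads = 2 * len(simulate_reads(ind, cfg))
        assert 0.003 < n1 / n_reads < 0.03

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            ReadSimConfig(depth=0).validate()
        with pytest.raises(ValueError):
            ReadSimConfig(read_len=600, insert_mean=500).validate()
        with pytest.raises(ValueError):
            ReadSimConfig(base_error=1.5).validate()
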