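"""Synthetic MHC-like guide panel, diploid individuals and paired-end reads.

The simulator emulates the features of the MHC that drive the assembly
method's design, at desk scale:

* a panel of guide haplotypes sharing a common ancestor sequence but
  distinguished by HLA class II structural blocks — each DR class carries a
  distinct inserted cassette at a fixed ancestral locus, with the DR4
  cassette the longest and DR8 carrying none, so that class-defining length
  ordering (DR4 > DR2 > DR3 > none) and alignment breaks are reproducible;
* a complement C4 block modelled as a tandem ~5 kb unit with 1-3 copies,
  A/B isotype motifs and a long/short form distinguished by an internal
  ~1 kb insertion;
* interspersed repeat elements implanted at a configurable density, with a
  truth BED recorded per guide;
* diploid individuals built by mutating two guides at stated SNP/indel
  rates with full truth-variant tracking; and
* 150 bp paired-end reads with base-call errors, occasional low-quality
  tails and poly-G artifact reads (a known Illumina two-colour artifact).

Everything is deterministic given one integer seed; each stage draws from
its own named stream (see :func:`mhcasm.core.stage_rng`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field

import numpy as np

from .core import ReadPair, random_dna, revcomp, stage_rng

DR_CLASSES = ("DR1", "DR2", "DR3", "DR4", "DR8")

#: Total class II cassette length per DR class (bp), including the 1 kb
#: allele-group tag. Only the relative structure matters (DR4 longest,
#: DR8 absent); absolute sizes are chosen so that class-II alignment breaks
#: are clearly visible on a 300 kb panel.
DR_CASSETTE_LEN = {"DR1": 4000, "DR2": 8000, "DR3": 6000, "DR4": 14000, "DR8": 0}

#: DRB1 first-field allele groups consistent with each DR class. Mirrors the
#: default allele->class table in :mod:`mhcasm.haplotype_assign`.
CLASS_GROUPS = {
    "DR1": ("01", "10"),
    "DR2": ("15", "16"),
    "DR3": ("03", "11", "12", "13", "14"),
    "DR4": ("04", "07", "09"),
    "DR8": ("08",),
}

GROUP_TAG_LEN = 1000
C4_UNIT_LEN = 5000
C4_LONG_INSERT_LEN = 1000
C4_LONG_INSERT_AT = 1200        # offset of the long-form insertion in a unit
C4_ISOTYPE_AT = 3300            # offset of the 10 bp A/B isotype motif
C4_ISOTYPE = {"A": "ACCGGAATTC", "B": "TGGCTTCAAG"}

#: Default per-guide C4 configurations, cycled across the panel:
#: (c4a copies, c4b copies, long forms).
DEFAULT_C4_MIX = [(1, 0, 1), (1, 1, 0), (2, 1, 1), (0, 1, 1),
                  (1, 2, 2), (2, 0, 0), (3, 0, 1), (1, 1, 2)]

#: Interspersed repeat families implanted by the panel generator:
#: (family name, consensus length, relative abundance).
REPEAT_FAMILIES = [("SINE1", 300, 0.6), ("LINE1", 1000, 0.3), ("LTR1", 450, 0.1)]
#: Per-copy substitution rate from the family consensus. Genomic
#: interspersed elements are old: typical copies sit ~10-25% from their
#: consensus, so pairwise copy divergence here (~2x this rate) matches the
#: lower end of that range.
REPEAT_COPY_DIVERGENCE = 0.12

# Relative ancestral positions of the structural loci.
_CASSETTE_LOCUS_FRAC = 0.55
_C4_LOCUS_FRAC = 0.75


@dataclass
class GuideHaplotype:
    """A named guide haplotype with DR class, C4 annotation and repeats.

    ``repeat_intervals`` are 0-based half-open (start, end, family) in the
    guide's own coordinates.
    """

    id: str
    sequence: str
    dr_class: str
    c4_copies: tuple[int, int, int]      # (c4a, c4b, long_forms)
    repeat_intervals: list[tuple[int, int, str]] = field(default_factory=list)
    allele_group: str = ""

    @property
    def length(self) -> int:
        return len(self.sequence)

    def validate(self) -> None:
        if self.dr_class not in DR_CLASSES:
            raise ValueError(f"unknown DR class {self.dr_class!r}")
        for s, e, _fam in self.repeat_intervals:
            if not (0 <= s < e <= self.length):
                raise ValueError(f"repeat interval ({s},{e}) outside [0,{self.length})")


@dataclass
class DiploidIndividual:
    id: str
    hap_a: str
    hap_b: str
    source_guides: tuple[str, str]
    #: (hap 'A'|'B', guide position, ref, alt, class 'snp'|'ins'|'del')
    truth_variants: list[tuple[str, int, str, str, str]]
    drb1_genotype: tuple[str, str]
    c4_status: tuple[tuple[int, int, int], tuple[int, int, int]]

    def haplotypes(self):
        return {"A": self.hap_a, "B": self.hap_b}


@dataclass
class ReadSimConfig:
    depth: float = 30.0
    read_len: int = 150
    insert_mean: int = 500
    insert_sd: int = 50
    base_error: float = 0.001
    g_run_rate: float = 0.002
    low_qual_tail_rate: float = 0.01
    seed: int = 0

    def validate(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be > 0")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must not exceed insert_mean")
        for name in ("base_error", "g_run_rate", "low_qual_tail_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0,1]")


# ------------------------------------------------------------------ panel

def _implant_repeats(ancestor: str, density: float, rng: np.random.Generator,
                     forbidden: list[int]) -> tuple[str, list[tuple[int, int, str]]]:
    """Replace segments of the ancestor with mutated repeat-family copies."""
    if density <= 0:
        return ancestor, []
    length = len(ancestor)
    target_bp = int(density * length)
    fams = [(n, l) for n, l, _w in REPEAT_FAMILIES]
    weights = np.array([w for _n, _l, w in REPEAT_FAMILIES])
    consensus = {n: random_dna(l, rng) for n, l in fams}
    occupied: list[tuple[int, int]] = sorted((p - 2, p + 2) for p in forbidden)
    placed: list[tuple[int, int, str]] = []
    seq = list(ancestor)
    placed_bp = 0
    attempts = 0
    while placed_bp < target_bp and attempts < 50 * max(1, target_bp // 300):
        attempts += 1
        fi = rng.choice(len(fams), p=weights / weights.sum())
        fam, flen = fams[fi]
        start = int(rng.integers(0, length - flen))
        end = start + flen
        i = bisect.bisect_left(occupied, (start, start))
        clash = False
        for s, e in occupied[max(0, i - 1):i + 2]:
            if s < end and start < e:
                clash = True
                break
        if clash:
            continue
        copy = list(consensus[fam])
        n_mut = rng.binomial(flen, REPEAT_COPY_DIVERGENCE)
        for pos in rng.choice(flen, size=n_mut, replace=False):
            copy[pos] = "ACGT"[(("ACGT".index(copy[pos]) + int(rng.integers(1, 4))) % 4)]
        seq[start:end] = copy
        bisect.insort(occupied, (start, end))
        placed.append((start, end, fam))
        placed_bp += flen
    placed.sort()
    return "".join(seq), placed


def _c4_block(c4: tuple[int, int, int], unit: str, insert: str) -> str:
    """Concatenated C4 tandem units with A/B motifs and long/short forms."""
    a, b, long_forms = c4
    parts = []
    for i in range(a + b):
        iso = "A" if i < a else "B"
        u = unit[:C4_ISOTYPE_AT] + C4_ISOTYPE[iso] + unit[C4_ISOTYPE_AT + 10:]
        if i < long_forms:
            u = u[:C4_LONG_INSERT_AT] + insert + u[C4_LONG_INSERT_AT:]
        parts.append(u)
    return "".join(parts)


def group_tag(group: str, seed: int) -> str:
    """Allele-group-specific 1 kb tag embedded at the cassette 5' end.

    Tags are a function of (group, seed) only, so an allele reference panel
    can be regenerated independently of the guide panel's composition.
    """
    return random_dna(GROUP_TAG_LEN, stage_rng(seed, f"tag:{group}"))


def allele_exemplars(dr_mix, seed: int) -> dict[str, str]:
    """First-field allele exemplar sequences for the naive genotyper.

    One exemplar per allele group present in ``dr_mix``'s classes (DR8 has
    no cassette and therefore no exemplar; DR8 genotypes must be provided).
    """
    out = {}
    for dr in dict.fromkeys(dr_mix):
        if DR_CASSETTE_LEN[dr] == 0:
            continue
        for grp in CLASS_GROUPS[dr]:
            out[grp] = group_tag(grp, seed)
    return out


def generate_guide_panel(n: int, base_len: int = 300_000, dr_mix=None,
                         repeat_density: float = 0.0, seed: int = 0,
                         c4_mix=None) -> list[GuideHaplotype]:
    """Generate ``n`` guide haplotypes derived from one ancestor sequence.

    Guides differ by DR-class cassettes inserted at a fixed ancestral locus,
    by C4 tandem copy number/form, and carry interspersed repeats at
    ``repeat_density`` with the truth intervals recorded. Deterministic
    given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if dr_mix is None:
        dr_mix = [DR_CLASSES[i % len(DR_CLASSES)] for i in range(n)]
    if len(dr_mix) != n:
        raise ValueError("dr_mix length must equal n")
    for dr in dr_mix:
        if dr not in DR_CLASSES:
            raise ValueError(f"invalid dr_class {dr!r}; valid: {DR_CLASSES}")
    if c4_mix is None:
        c4_mix = [DEFAULT_C4_MIX[i % len(DEFAULT_C4_MIX)] for i in range(n)]

    rng = stage_rng(seed, "panel")
    cassette_locus = int(base_len * _CASSETTE_LOCUS_FRAC)
    c4_locus = int(base_len * _C4_LOCUS_FRAC)
    ancestor = random_dna(base_len, rng)
    ancestor, repeats = _implant_repeats(ancestor, repeat_density, rng,
                                         forbidden=[cassette_locus, c4_locus])

    c4_unit = random_dna(C4_UNIT_LEN, stage_rng(seed, "c4:unit"))
    c4_insert = random_dna(C4_LONG_INSERT_LEN, stage_rng(seed, "c4:long"))
    cassette_body = {
        dr: random_dna(max(0, DR_CASSETTE_LEN[dr] - GROUP_TAG_LEN),
                       stage_rng(seed, f"cassette:{dr}"))
        for dr in set(dr_mix)
    }

    panel = []
    group_cursor: dict[str, int] = {}
    for i, dr in enumerate(dr_mix):
        groups = CLASS_GROUPS[dr]
        grp = groups[group_cursor.get(dr, 0) % len(groups)]
        group_cursor[dr] = group_cursor.get(dr, 0) + 1
        cassette = "" if DR_CASSETTE_LEN[dr] == 0 else group_tag(grp, seed) + cassette_body[dr]
        c4 = tuple(c4_mix[i])
        block = _c4_block(c4, c4_unit, c4_insert)
        seq = (ancestor[:cassette_locus] + cassette +
               ancestor[cassette_locus:c4_locus] + block + ancestor[c4_locus:])
        ivals = []
        for s, e, fam in repeats:
            off = 0
            if s >= cassette_locus:
                off += len(cassette)
            if s >= c4_locus:
                off += len(block)
            ivals.append((s + off, e + off, fam))
        g = GuideHaplotype(id=f"G{i:02d}_{dr}", sequence=seq, dr_class=dr,
                           c4_copies=c4, repeat_intervals=ivals, allele_group=grp)
        g.validate()
        panel.append(g)
    return panel


def class_ii_interval(guide: GuideHaplotype, base_len: int) -> tuple[int, int]:
    """Guide-coordinate interval of the class II cassette region."""
    locus = int(base_len * _CASSETTE_LOCUS_FRAC)
    return locus, locus + DR_CASSETTE_LEN[guide.dr_class]


# -------------------------------------------------------------- individual

def apply_variants(guide_seq: str, variants, hap: str) -> str:
    """Apply the truth variants recorded for haplotype ``hap`` to its guide.

    This is the round-trip contract of the simulator: the haplotype equals
    its guide with exactly the recorded variants applied.
    """
    muts = sorted((v for v in variants if v[0] == hap), key=lambda v: v[1])
    out = []
    cur = 0
    for _h, pos, ref, alt, _cls in muts:
        out.append(guide_seq[cur:pos])
        out.append(alt)
        cur = pos + len(ref)
    out.append(guide_seq[cur:])
    return "".join(out)


def simulate_individual(panel, guide_pair: tuple[str, str], divergence: float = 0.002,
                        indel_rate: float = 2.5e-4, seed: int = 0,
                        ind_id: str = "sim") -> DiploidIndividual:
    """Mutate two guides into a diploid individual with tracked truth.

    ``divergence`` is the per-bp SNP rate of each haplotype relative to its
    source guide; ``indel_rate`` the per-bp rate of short (1-10 bp,
    geometric) insertions/deletions. Rates >= 0.1 are rejected — they break
    the best-matching-haplotype assumption the whole method rests on.
    """
    if divergence >= 0.1 or indel_rate >= 0.1:
        raise ValueError("divergence/indel_rate >= 0.1 is unrealistically high "
                         "and breaks haplotype binning assumptions")
    guides = {g.id: g for g in panel}
    for gid in guide_pair:
        if gid not in guides:
            raise KeyError(f"guide {gid!r} not in panel ({sorted(guides)})")
    ga, gb = guides[guide_pair[0]], guides[guide_pair[1]]

    variants: list[tuple[str, int, str, str, str]] = []
    haps = {}
    for hap, guide in (("A", ga), ("B", gb)):
        rng = stage_rng(seed, f"individual:{hap}")
        L = guide.length
        seq = guide.sequence
        n_snp = rng.binomial(L, divergence)
        n_indel = rng.binomial(L, indel_rate)
        snp_pos = rng.choice(L, size=n_snp, replace=False)
        indel_pos = rng.choice(L, size=n_indel, replace=False)
        events = {}
        for pos in snp_pos:
            ref = seq[pos]
            alt = "ACGT"[("ACGT".index(ref) + int(rng.integers(1, 4))) % 4]
            events[int(pos)] = (ref, alt, "snp")
        for pos in indel_pos:
            pos = int(pos)
            if pos in events or pos + 12 >= L:
                continue
            ilen = min(10, int(rng.geometric(0.6)))
            if rng.random() < 0.5:
                ref, alt, cls = seq[pos], seq[pos] + random_dna(ilen, rng), "ins"
            else:
                ref, alt, cls = seq[pos:pos + 1 + ilen], seq[pos], "del"
            events[pos] = (ref, alt, cls)
        # drop events whose ref span overlaps a later event
        last_end = -1
        for pos in sorted(events):
            ref, alt, cls = events[pos]
            if pos < last_end:
                continue
            variants.append((hap, pos, ref, alt, cls))
            last_end = pos + len(ref)
        haps[hap] = apply_variants(seq, variants, hap)

    return DiploidIndividual(
        id=ind_id, hap_a=haps["A"], hap_b=haps["B"],
        source_guides=(ga.id, gb.id),
        truth_variants=variants,
        drb1_genotype=(ga.allele_group, gb.allele_group),
        c4_status=(ga.c4_copies, gb.c4_copies),
    )


def truth_repeat_bed(guide: GuideHaplotype, ind: DiploidIndividual, hap: str
                     ) -> list[tuple[int, int, str]]:
    """Guide repeat intervals lifted to the haplotype's own coordinates.

    Indel truth variants shift downstream coordinates; this applies the
    cumulative offset so repeat masks are exact in truth-haplotype space.
    """
    muts = sorted((v for v in ind.truth_variants if v[0] == hap), key=lambda v: v[1])
    positions = [v[1] for v in muts]
    offsets = []
    acc = 0
    for _h, _p, ref, alt, _c in muts:
        acc += len(alt) - len(ref)
        offsets.append(acc)

    def lift(pos: int) -> int:
        i = bisect.bisect_right(positions, pos) - 1
        return pos + (offsets[i] if i >= 0 else 0)

    return [(lift(s), lift(e), fam) for s, e, fam in guide.repeat_intervals]


# -------------------------------------------------------------------- reads

def simulate_reads(ind: DiploidIndividual, cfg: ReadSimConfig) -> list[ReadPair]:
    """Draw paired-end reads uniformly from both haplotypes.

    Pair count is ``round(depth * total_haplotype_len / (2 * read_len))`` so
    that mean per-base coverage of each haplotype equals ``depth``. Read
    names record provenance as ``id:pN:hX:start:insert[:flip]``.
    """
    cfg.validate()
    rng = stage_rng(cfg.seed, "reads")
    haps = [("A", ind.hap_a), ("B", ind.hap_b)]
    lens = np.array([len(s) for _h, s in haps], dtype=float)
    total = lens.sum()
    n_pairs = int(round(cfg.depth * total / (2 * cfg.read_len)))
    L = cfg.read_len

    hap_idx = rng.choice(len(haps), size=n_pairs, p=lens / total)
    inserts = np.clip(np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)),
                      L, lens[hap_idx]).astype(np.int64)
    starts = (rng.random(n_pairs) * (lens[hap_idx] - inserts + 1)).astype(np.int64)
    flips = rng.random(n_pairs) < 0.5

    baseline_q = "F" * L  # Q37
    pairs: list[ReadPair] = []
    for i in range(n_pairs):
        h, seq = haps[hap_idx[i]]
        s, ins = int(starts[i]), int(inserts[i])
        fwd = seq[s:s + L]
        rev = revcomp(seq[s + ins - L:s + ins])
        r1, r2 = (rev, fwd) if flips[i] else (fwd, rev)
        pairs.append(ReadPair(f"{ind.id}:p{i}:h{h}:{s}:{ins}:{int(flips[i])}",
                              r1, baseline_q, r2, baseline_q))

    _inject_base_errors(pairs, cfg, rng)
    _inject_tails_and_artifacts(pairs, cfg, rng)
    return pairs


def _inject_base_errors(pairs, cfg, rng) -> None:
    if cfg.base_error <= 0 or not pairs:
        return
    L = cfg.read_len
    total_bases = 2 * L * len(pairs)
    n_err = rng.binomial(total_bases, cfg.base_error)
    # with-replacement draw: colliding positions just re-mutate one base
    flat = rng.integers(0, total_bases, size=n_err)
    by_read: dict[tuple[int, int], list[int]] = {}
    for f in flat:
        ri, rest = divmod(int(f), 2 * L)
        mate, pos = divmod(rest, L)
        by_read.setdefault((ri, mate), []).append(pos)
    for (ri, mate), positions in by_read.items():
        p = pairs[ri]
        seq = list(p.seq1 if mate == 0 else p.seq2)
        for pos in positions:
            seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + int(rng.integers(1, 4))) % 4]
        if mate == 0:
            p.seq1 = "".join(seq)
        else:
            p.seq2 = "".join(seq)


def _inject_tails_and_artifacts(pairs, cfg, rng) -> None:
    L = cfg.read_len
    for p in pairs:
        for mate in (1, 2):
            if cfg.low_qual_tail_rate and rng.random() < cfg.low_qual_tail_rate:
                seq = list(getattr(p, f"seq{mate}"))
                t = int(rng.integers(5, 31))
                quals = list(getattr(p, f"qual{mate}"))
                for j in range(len(seq) - t, len(seq)):
                    quals[j] = chr(int(rng.integers(2, 13)) + 33)
                    if rng.random() < 0.2:
                        seq[j] = "ACGT"[int(rng.integers(0, 4))]
                setattr(p, f"seq{mate}", "".join(seq))
                setattr(p, f"qual{mate}", "".join(quals))
            if cfg.g_run_rate and rng.random() < cfg.g_run_rate:
                keep = int(rng.integers(0, max(1, L - 20)))
                seq = getattr(p, f"seq{mate}")[:keep] + "G" * (L - keep)
                setattr(p, f"seq{mate}", seq)
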