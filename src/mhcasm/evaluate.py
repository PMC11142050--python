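"""Assembly validation: error quantification against a truth sequence,
structural-variant classification, heterozygous-switch attribution,
assembly statistics and read-set k-mer diversity.

Error quantification follows the assembly-to-reference comparison recipe:
the assembly is anchored to the truth by unique exact matches (>= 100 bp),
anchors are chained colinearly, inter-anchor segments are pairwise aligned,
and every difference is an event — single-base mismatches are base-call
errors, indels >= 1 bp are structural errors, classified as tandem or
interspersed-repeat associated where the evidence supports it. Each error
category is expressed as a percentage of the assembled length, so the
three components sum exactly to the total error percentage. Positions
where the assembly carries N (explicit gaps) are uncalled, not errors.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field

import edlib
import numpy as np
from intervaltree import IntervalTree

from .core import revcomp

SV_SIZE_CLASSES = ((1, 49), (50, 499), (500, 999), (1000, None))


@dataclass
class ErrorEvent:
    type: str          # SNP, insertion, deletion, repeat_/tandem_ expansion/contraction
    pos: int           # truth coordinate (0-based)
    len: int           # event length in bp
    repeat_associated: bool
    ref: str = ""
    alt: str = ""


@dataclass
class ErrorReport:
    assembly_len: int
    base_call_error_pct: float
    nonrepeat_sv_error_pct: float
    repeat_sv_error_pct: float
    total_error_pct: float
    events: list[ErrorEvent] = field(default_factory=list)

    def sv_size_histogram(self) -> dict[str, int]:
        hist = {}
        for lo, hi in SV_SIZE_CLASSES:
            label = f"{lo}-{hi}" if hi else f">={lo}"
            hist[label] = sum(1 for e in self.events
                              if e.type != "SNP" and lo <= e.len <= (hi or 10 ** 12))
        return hist


@dataclass
class AssemblyStats:
    n_contigs: int
    n50: int
    total_len: int


@dataclass
class Block:
    a_start: int
    a_end: int
    t_start: int
    t_end: int
    ops: list[tuple[str, int]]         # M/X/I/D over [a_start,a_end) x [t_start,t_end)


@dataclass
class AnchorChain:
    """Monotone alignment of an (oriented) assembly to a truth sequence."""
    assembly: str                      # oriented to the truth strand
    truth: str
    strand: str
    blocks: list[Block]

    @property
    def aligned_assembly_bp(self) -> int:
        return sum(b.a_end - b.a_start for b in self.blocks)


class NoAnchorsError(ValueError):
    pass


# ------------------------------------------------------------ anchoring

def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    out: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i:i + k]
        if km in dup:
            continue
        if km in out:
            del out[km]
            dup.add(km)
        else:
            out[km] = i
    return out


def _anchor_matches(assembly: str, truth_unique: dict[str, int], k: int
                    ) -> list[tuple[int, int]]:
    asm_unique = _unique_kmer_positions(assembly, k)
    return sorted((apos, truth_unique[km]) for km, apos in asm_unique.items()
                  if km in truth_unique and "N" not in km)


def _merge_diagonal(matches: list[tuple[int, int]], k: int
                    ) -> list[tuple[int, int, int]]:
    """Collapse same-diagonal consecutive matches into (apos, tpos, len)."""
    segs = []
    for a, t in matches:
        if segs and t - a == segs[-1][1] - segs[-1][0] and a <= segs[-1][0] + segs[-1][2]:
            s = segs[-1]
            segs[-1] = (s[0], s[1], max(s[2], a + k - s[0]))
        else:
            segs.append((a, t, k))
    return segs


def _chain_colinear(segs: list[tuple[int, int, int]]) -> list[tuple[int, int, int]]:
    """Max-weight colinear subset (weighted LIS on truth position)."""
    if not segs:
        return []
    segs = sorted(segs)
    n = len(segs)
    # coordinate-compress truth positions for a max-Fenwick tree
    tvals = sorted({t for _a, t, _l in segs})
    rank = {t: i + 1 for i, t in enumerate(tvals)}
    tree_val = [0.0] * (len(tvals) + 1)
    tree_idx = [-1] * (len(tvals) + 1)

    def update(i, val, idx):
        while i <= len(tvals):
            if val > tree_val[i]:
                tree_val[i], tree_idx[i] = val, idx
            i += i & (-i)

    def query(i):
        best, bidx = 0.0, -1
        while i > 0:
            if tree_val[i] > best:
                best, bidx = tree_val[i], tree_idx[i]
            i -= i & (-i)
        return best, bidx

    score = [0.0] * n
    back = [-1] * n
    for i, (a, t, l) in enumerate(segs):
        prev, pidx = query(rank[t] - 1)
        score[i] = prev + l
        back[i] = pidx
        update(rank[t], score[i], i)
    end = int(np.argmax(score))
    chain = []
    while end != -1:
        chain.append(segs[end])
        end = back[end]
    chain.reverse()
    # trim overlaps between neighbours so coordinates stay monotone
    out = []
    for a, t, l in chain:
        if out:
            pa, pt, pl = out[-1]
            cut = max(pa + pl - a, pt + pl - t, 0)
            if cut >= l or cut >= pl:
                if l > pl:
                    out.pop()
                else:
                    continue
            elif cut:
                a, t, l = a + cut, t + cut, l - cut
        out.append((a, t, l))
    return out


def _edlib_ops(a: str, t: str) -> list[tuple[str, int]]:
    """Global alignment ops of assembly segment vs truth segment."""
    if not a and not t:
        return []
    if not a:
        return [("D", len(t))]
    if not t:
        return [("I", len(a))]
    res = edlib.align(a, t, mode="NW", task="path")
    ops = []
    num = ""
    for ch in res["cigar"]:
        if ch.isdigit():
            num += ch
            continue
        l = int(num)
        num = ""
        op = {"=": "M", "X": "X", "I": "I", "D": "D"}[ch]
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + l)
        else:
            ops.append((op, l))
    return ops


def anchor_align(assembly: str, truth: str, min_anchor: int = 100) -> AnchorChain:
    """Unique-anchor chained alignment of an assembly to its truth.

    Orientation is chosen globally (the strand with more unique-anchor
    support); anchors are unique >= ``min_anchor`` exact matches chained
    colinearly, and inter-anchor segments are aligned pairwise. Leading and
    trailing unanchored sequence is left unaligned. Raises
    :class:`NoAnchorsError` when the sequences share no unique anchor.
    """
    if not assembly or not truth:
        raise ValueError("sequences must be non-empty")
    k = min_anchor
    truth_unique = _unique_kmer_positions(truth, k)
    fwd = _anchor_matches(assembly, truth_unique, k)
    rc = revcomp(assembly)
    rev = _anchor_matches(rc, truth_unique, k)
    if not fwd and not rev:
        raise NoAnchorsError(
            f"no unique exact matches >= {min_anchor} bp; sequences appear unrelated")
    if len(rev) > len(fwd):
        strand, oriented, matches = "-", rc, rev
    else:
        strand, oriented, matches = "+", assembly, fwd

    chain = _chain_colinear(_merge_diagonal(matches, k))
    blocks: list[Block] = []
    pa = pt = None
    for a, t, l in chain:
        if pa is not None and (a > pa or t > pt):
            seg_ops = _edlib_ops(oriented[pa:a], truth[pt:t])
            blocks.append(Block(pa, a, pt, t, seg_ops))
        blocks.append(Block(a, a + l, t, t + l, [("M", l)]))
        pa, pt = a + l, t + l
    # fuse adjacent blocks into runs for compactness
    fused: list[Block] = []
    for b in blocks:
        if fused and fused[-1].a_end == b.a_start and fused[-1].t_end == b.t_start:
            prev = fused[-1]
            ops = prev.ops + b.ops
            merged_ops: list[tuple[str, int]] = []
            for op, l in ops:
                if merged_ops and merged_ops[-1][0] == op:
                    merged_ops[-1] = (op, merged_ops[-1][1] + l)
                else:
                    merged_ops.append((op, l))
            fused[-1] = Block(prev.a_start, b.a_end, prev.t_start, b.t_end, merged_ops)
        else:
            fused.append(b)
    return AnchorChain(assembly=oriented, truth=truth, strand=strand, blocks=fused)


# ---------------------------------------------------------- error calling

def _is_tandem(event_seq: str, truth: str, t_pos: int, max_motif: int = 100,
               min_cov: float = 0.8) -> bool:
    """Event sequence explained by copies of a short motif adjacent in truth."""
    l = len(event_seq)
    if l == 0:
        return False
    for flank in (truth[t_pos:t_pos + min(l, max_motif)],
                  truth[max(0, t_pos - min(l, max_motif)):t_pos]):
        if len(flank) < 2:
            continue
        tiled = (flank * (l // len(flank) + 2))[:l]
        dist = edlib.align(event_seq, tiled, task="distance")["editDistance"]
        if 1 - dist / l >= min_cov:
            return True
    return False


def _repeat_tree(repeat_bed) -> IntervalTree | None:
    if repeat_bed is None:
        return None
    tree = IntervalTree()
    for iv in repeat_bed:
        s, e = (iv[0], iv[1]) if isinstance(iv[0], int) else (iv[1], iv[2])
        if e > s:
            tree[s:e] = True
    return tree


def call_errors(chain: AnchorChain, repeat_bed=None) -> ErrorReport:
    """Classify every assembly/truth difference and express error rates.

    * single-base substitutions -> SNP (base-call error);
    * indels >= 1 bp -> structural events: tandem expansion/contraction
      when the event sequence matches adjacent truth sequence, repeat
      expansion/contraction when it overlaps the repeat mask (truth
      coordinates), else plain insertion/deletion;
    * percentages are 100 x event bp / assembled length, over base-call,
      non-repeat SV and repeat-associated SV categories (tandem events
      count as repeat-associated).

    Assembly N positions are uncalled and contribute no events.
    """
    tree = _repeat_tree(repeat_bed)
    assembly, truth = chain.assembly, chain.truth
    events: list[ErrorEvent] = []
    for b in chain.blocks:
        a, t = b.a_start, b.t_start
        for op, l in b.ops:
            if op == "M":
                a += l
                t += l
            elif op == "X":
                for i in range(l):
                    ab = assembly[a + i]
                    if ab != "N" and truth[t + i] != "N":
                        events.append(ErrorEvent("SNP", t + i, 1, False,
                                                 ref=truth[t + i], alt=ab))
                a += l
                t += l
            elif op == "I":
                seq = assembly[a:a + l]
                if set(seq) != {"N"}:
                    events.append(_classify_sv(seq.replace("N", ""), t, True, truth, tree))
                a += l
            else:  # D
                seq = truth[t:t + l]
                events.append(_classify_sv(seq, t, False, truth, tree))
                t += l
    events = [e for e in events if e.len > 0]

    asm_len = len(assembly)
    base_bp = sum(e.len for e in events if e.type == "SNP")
    rep_bp = sum(e.len for e in events if e.type != "SNP" and e.repeat_associated)
    nonrep_bp = sum(e.len for e in events if e.type != "SNP" and not e.repeat_associated)
    base_pct = 100.0 * base_bp / asm_len
    nonrep_pct = 100.0 * nonrep_bp / asm_len
    rep_pct = 100.0 * rep_bp / asm_len
    return ErrorReport(assembly_len=asm_len, base_call_error_pct=base_pct,
                       nonrepeat_sv_error_pct=nonrep_pct, repeat_sv_error_pct=rep_pct,
                       total_error_pct=base_pct + nonrep_pct + rep_pct, events=events)


def _classify_sv(seq: str, t_pos: int, is_insertion: bool, truth: str,
                 tree: IntervalTree | None) -> ErrorEvent:
    l = len(seq)
    kind = "expansion" if is_insertion else "contraction"
    if _is_tandem(seq, truth, t_pos):
        return ErrorEvent(f"tandem_{kind}", t_pos, l, True, alt=seq if is_insertion else "",
                          ref="" if is_insertion else seq)
    span = (t_pos, t_pos + (1 if is_insertion else l))
    if tree is not None and tree.overlap(span[0], span[1]):
        return ErrorEvent(f"repeat_{kind}", t_pos, l, True,
                          alt=seq if is_insertion else "", ref="" if is_insertion else seq)
    return ErrorEvent("insertion" if is_insertion else "deletion", t_pos, l, False,
                      alt=seq if is_insertion else "", ref="" if is_insertion else seq)


# --------------------------------------------------- het-switch attribution

def attribute_het_switch(snp_events: list[ErrorEvent], truth_hap: str,
                         other_hap: str) -> tuple[float, float]:
    """Split assembly mismatches into true errors vs heterozygous inclusions.

    A mismatch whose assembly base equals the homologous base of the other
    phased haplotype is an improper inclusion of the other haplotype's
    allele rather than a sequencing/assembly error. Returns
    (true_error_fraction, het_inclusion_fraction); (0, 0) when there are
    no mismatches.
    """
    snps = [e for e in snp_events if e.type == "SNP"]
    if not snps:
        return 0.0, 0.0
    chain = anchor_align(other_hap, truth_hap)
    # piecewise map: truth position -> other-hap position
    pieces = []              # (t_start, t_end, o_start) for M/X runs
    for b in chain.blocks:
        a, t = b.a_start, b.t_start
        for op, l in b.ops:
            if op in "MX":
                pieces.append((t, t + l, a))
                a += l
                t += l
            elif op == "I":
                a += l
            else:
                t += l
    starts = [p[0] for p in pieces]
    het = 0
    for e in snps:
        i = bisect_left(starts, e.pos + 1) - 1
        opos = None
        if i >= 0:
            ts, te, os_ = pieces[i]
            if ts <= e.pos < te:
                opos = os_ + (e.pos - ts)
        if opos is not None and chain.assembly[opos] == e.alt:
            het += 1
    n = len(snps)
    return (n - het) / n, het / n


# ------------------------------------------------------------- statistics

def assembly_stats(contigs) -> AssemblyStats:
    """Contig count, N50 and total length.

    N50: the length of the shortest contig in the minimal set of longest
    contigs whose summed length reaches half the total.
    """
    lengths = sorted((len(c.sequence) if hasattr(c, "sequence") else int(c)
                      for c in contigs), reverse=True)
    if not lengths:
        raise ValueError("assembly_stats requires at least one contig")
    total = sum(lengths)
    acc = 0
    for l in lengths:
        acc += l
        if acc * 2 >= total:
            return AssemblyStats(n_contigs=len(lengths), n50=l, total_len=total)
    return AssemblyStats(n_contigs=len(lengths), n50=lengths[-1], total_len=total)


def unique_kmer_ratio(pairs, k: int = 150) -> float:
    """Distinct k-mers occurring exactly once in the read set, per read.

    Canonical k-mers over both mates; the denominator is the number of
    reads of length >= k. Higher values indicate more sequence diversity
    than the read depth can saturate (e.g. divergence from the guide).
    """
    counts: dict[str, int] = {}
    n_reads = 0
    for p in pairs:
        for seq in (p.seq1, p.seq2):
            if len(seq) < k:
                continue
            n_reads += 1
            for i in range(len(seq) - k + 1):
                km = seq[i:i + k]
                km = min(km, revcomp(km))
                counts[km] = counts.get(km, 0) + 1
    if n_reads == 0:
        raise ValueError(f"no read reaches length k={k}")
    singletons = sum(1 for c in counts.values() if c == 1)
    return singletons / n_reads


# ------------------------------------------------------------- variants

@dataclass
class VariantRecord:
    pos: int            # 0-based on the reference
    ref: str
    alt: str

    def key(self):
        return (self.pos, self.ref, self.alt)


def _left_normalize(pos: int, ref: str, alt: str, reference: str
                    ) -> tuple[int, str, str]:
    """Standard indel left-normalisation (truncate shared right bases,
    extending left from the reference when one allele would empty; then
    strip redundant shared left bases)."""
    while True:
        changed = False
        if ref and alt and ref[-1] == alt[-1]:
            if len(ref) == 1 or len(alt) == 1:
                if pos == 0:
                    return pos, ref, alt
                prev = reference[pos - 1]
                ref, alt = prev + ref, prev + alt
                pos -= 1
            ref, alt = ref[:-1], alt[:-1]
            changed = True
        while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
            ref, alt = ref[1:], alt[1:]
            pos += 1
            changed = True
        if not changed:
            return pos, ref, alt


def call_variants_vs_reference(consensus: str, reference: str,
                               min_anchor: int = 100) -> list[VariantRecord]:
    """SNPs and indels of a placed consensus against a reference sequence.

    Indels are anchored on the preceding reference base and left-normalised.
    Events touching N (assembly gaps) are not emitted.
    """
    chain = anchor_align(consensus, reference, min_anchor=min_anchor)
    records: list[VariantRecord] = []
    assembly, truth = chain.assembly, chain.truth
    for b in chain.blocks:
        a, t = b.a_start, b.t_start
        for op, l in b.ops:
            if op == "M":
                a += l
                t += l
            elif op == "X":
                for i in range(l):
                    ab = assembly[a + i]
                    if ab != "N" and truth[t + i] != "N":
                        records.append(VariantRecord(t + i, truth[t + i], ab))
                a += l
                t += l
            elif op == "I":
                seq = assembly[a:a + l]
                if "N" not in seq and t > 0:
                    pos, ref, alt = _left_normalize(t - 1, reference[t - 1],
                                                    reference[t - 1] + seq, reference)
                    records.append(VariantRecord(pos, ref, alt))
                a += l
            else:
                seq = truth[t:t + l]
                if "N" not in seq and t > 0:
                    pos, ref, alt = _left_normalize(t - 1, reference[t - 1] + seq,
                                                    reference[t - 1], reference)
                    records.append(VariantRecord(pos, ref, alt))
                t += l
    records.sort(key=lambda r: r.key())
    return records


def merge_haplotype_variants(records_a: list[VariantRecord],
                             records_b: list[VariantRecord]
                             ) -> list[tuple[int, str, list[str], str]]:
    """Merge two per-haplotype call sets into per-individual genotypes.

    Same position+alleles in both -> 1/1; present in one -> 0/1; two
    different alts at one (pos, ref) -> one record with both alts, 1/2.
    Returns (pos, ref, alts, gt) rows ready for the VCF writer.
    """
    a_keys = {r.key() for r in records_a}
    b_keys = {r.key() for r in records_b}
    sites: dict[tuple[int, str], dict[str, str]] = {}
    for r in list(records_a) + list(records_b):
        alts = sites.setdefault((r.pos, r.ref), {})
        if r.alt not in alts:
            in_a = r.key() in a_keys
            in_b = r.key() in b_keys
            alts[r.alt] = "hom" if (in_a and in_b) else "het"
    out = []
    for (pos, ref), alts in sorted(sites.items()):
        alt_list = sorted(alts)
        if len(alt_list) == 1:
            gt = "1/1" if alts[alt_list[0]] == "hom" else "0/1"
        else:
            gt = "1/2"
        out.append((pos, ref, alt_list, gt))
    return out
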