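"""Seed-and-extend read mapping against guide haplotypes (or contigs),
mapped/unmapped binning with mate rescue, and superblock partitioning.

Mapping model: exact seed k-mers (default k=15) anchor candidate diagonals;
candidates are scored end-to-end (the whole read must align) under
``{match 0, mismatch -6, gap open -5, gap extend -3}`` and accepted iff
score >= -0.6 x read length — the threshold the assembly workflow sets on
its aligner. A mismatch-only extension is tried first (vectorised); an
affine-gap dynamic program over a small window is used when the read may
contain indels. For short targets an exhaustive semi-global scan is run
before declaring a read unmapped, so accept/reject decisions are exact
wherever exhaustive search is affordable.

Superblocks are fixed-span overlapping tiles of the guide (default 50 kb
span, 5 kb overlap) trimmed to the mapped-read footprint; each mapped pair
joins every superblock its footprint intersects, giving localized read sets
for per-window de novo assembly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from numba import njit

from .core import revcomp, seq_to_codes


@dataclass
class Scoring:
    match: int = 0
    mismatch: int = -6
    gap_open: int = -5
    gap_extend: int = -3
    min_score_per_bp: float = -0.6

    def threshold(self, read_len: int) -> float:
        return self.min_score_per_bp * read_len


@dataclass
class Alignment:
    query_id: str
    target_id: str
    target_start: int
    target_end: int            # 0-based half-open
    strand: str                # '+' | '-'
    score: int
    edits: list[tuple[str, int]] = field(default_factory=list)  # (op in M/X/I/D, len)

    @property
    def aligned_query_len(self) -> int:
        return sum(l for op, l in self.edits if op in "MXI")

    @property
    def n_matches(self) -> int:
        return sum(l for op, l in self.edits if op == "M")


@dataclass
class Superblock:
    guide_interval: tuple[int, int]
    read_ids: set[str]
    est_coverage: float


# ------------------------------------------------------------------ index

class SeedIndex:
    """Exact-match seed index over one or more target sequences.

    Query lookups cover both strands by probing the reverse complement of
    the read; only forward target k-mers are stored.
    """

    def __init__(self, targets: Mapping[str, str] | str, seed_k: int = 15,
                 max_seed_hits: int = 100):
        if isinstance(targets, str):
            targets = {"target": targets}
        self.k = seed_k
        self.max_seed_hits = max_seed_hits
        self.ids: list[str] = []
        self.seqs: list[str] = []
        self.codes: list[np.ndarray] = []
        offsets = [0]
        for tid, seq in targets.items():
            if len(seq) < seed_k:
                raise ValueError(f"target {tid!r} shorter than seed k={seed_k}")
            self.ids.append(tid)
            self.seqs.append(seq)
            self.codes.append(seq_to_codes(seq))
            offsets.append(offsets[-1] + len(seq) + seed_k)  # pad between targets
        self.offsets = np.array(offsets[:-1], dtype=np.int64)
        self.n_forward_seeds = sum(len(s) - seed_k + 1 for s in self.seqs)
        seeds: dict[bytes, list[int]] = {}
        for ti, seq in enumerate(self.seqs):
            b = seq.encode("ascii")
            off = int(self.offsets[ti])
            for i in range(len(b) - seed_k + 1):
                seeds.setdefault(b[i:i + seed_k], []).append(off + i)
        self.seeds = {km: np.array(v, dtype=np.int64) for km, v in seeds.items()
                      if len(v) <= max_seed_hits}
        self._rep_seeds = {km for km, v in seeds.items() if len(v) > max_seed_hits}

    @property
    def total_target_len(self) -> int:
        return sum(len(s) for s in self.seqs)

    def locate(self, global_pos: int) -> tuple[int, int]:
        ti = int(np.searchsorted(self.offsets, global_pos, side="right")) - 1
        return ti, global_pos - int(self.offsets[ti])


def index_guide(guide, seed_k: int = 15) -> SeedIndex:
    """Index a guide haplotype (accepts a sequence or a GuideHaplotype)."""
    seq = guide if isinstance(guide, str) else guide.sequence
    tid = "guide" if isinstance(guide, str) else guide.id
    return SeedIndex({tid: seq}, seed_k=seed_k)


# ------------------------------------------------------- affine-gap DP core

@njit(cache=False)
def _affine_semiglobal(q, t, match, mismatch, gap_open, gap_extend):  # pragma: no cover
    """Semi-global affine DP: query end-to-end, free target start/end.

    Returns (score, t_start, t_end, ops) with ops coded 0=M,1=X,2=I,3=D in
    alignment order. Numba-compiled; exercised via its Python callers.
    """
    n, m = len(q), len(t)
    NEG = -10 ** 8
    H = np.empty((n + 1, m + 1), dtype=np.int32)
    V = np.empty((n + 1, m + 1), dtype=np.int32)
    Z = np.empty((n + 1, m + 1), dtype=np.int32)
    for j in range(m + 1):
        H[0, j] = 0
        V[0, j] = NEG
        Z[0, j] = NEG
    for i in range(1, n + 1):
        V[i, 0] = gap_open + gap_extend * i
        H[i, 0] = V[i, 0]
        Z[i, 0] = NEG
        for j in range(1, m + 1):
            if q[i - 1] < 4 and q[i - 1] == t[j - 1]:
                sub = match
            else:
                sub = mismatch
            v = max(H[i - 1, j] + gap_open + gap_extend, V[i - 1, j] + gap_extend)
            z = max(H[i, j - 1] + gap_open + gap_extend, Z[i, j - 1] + gap_extend)
            h = H[i - 1, j - 1] + sub
            if v > h:
                h = v
            if z > h:
                h = z
            H[i, j] = h
            V[i, j] = v
            Z[i, j] = z
    best_j = 0
    best = H[n, 0]
    for j in range(1, m + 1):
        if H[n, j] > best:
            best = H[n, j]
            best_j = j
    # traceback
    ops = np.empty(n + m + 2, dtype=np.int8)
    no = 0
    i, j = n, best_j
    state = 0  # 0=H, 1=V, 2=Z
    while i > 0:
        if state == 0:
            if j > 0:
                if q[i - 1] < 4 and q[i - 1] == t[j - 1]:
                    sub = match
                else:
                    sub = mismatch
                if H[i, j] == H[i - 1, j - 1] + sub:
                    ops[no] = 0 if (q[i - 1] < 4 and q[i - 1] == t[j - 1]) else 1
                    no += 1
                    i -= 1
                    j -= 1
                    continue
            if H[i, j] == V[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[no] = 2
            no += 1
            if V[i, j] != V[i - 1, j] + gap_extend:
                state = 0
            i -= 1
        else:
            ops[no] = 3
            no += 1
            if Z[i, j] != Z[i, j - 1] + gap_extend:
                state = 0
            j -= 1
    t_start = j
    return best, t_start, best_j, ops[:no][::-1].copy()


def _compress_ops(codes) -> list[tuple[str, int]]:
    """Run-length encode per-step op codes (0=M,1=X,2=I,3=D) into edits."""
    arr = np.asarray(codes, dtype=np.int8)
    if arr.size == 0:
        return []
    change = np.nonzero(np.diff(arr))[0] + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [arr.size]))
    return [("MXID"[arr[s]], int(e - s)) for s, e in zip(starts, ends)]


def _hamming_edits(qc: np.ndarray, tc: np.ndarray) -> tuple[int, list[tuple[str, int]]]:
    mism = (qc != tc) | (qc == 4) | (tc == 4)
    nmm = int(np.count_nonzero(mism))
    codes = mism.astype(np.int8)  # 0=M, 1=X
    return nmm, _compress_ops(codes)


# ---------------------------------------------------------------- mapping

def _gap_margin(scoring: Scoring, read_len: int) -> int:
    span = (-scoring.threshold(read_len) + scoring.gap_open) / (-scoring.gap_extend)
    return max(8, int(span) + 2)


def _collect_votes(index: SeedIndex, qb: bytes, step: int) -> dict[int, int]:
    k = index.k
    votes: dict[int, int] = {}
    n = len(qb) - k + 1
    seeds_get = index.seeds.get
    for off in range(0, max(n, 0), step):
        hits = seeds_get(qb[off:off + k])
        if hits is None:
            continue
        for gp in hits:
            d = int(gp) - off
            votes[d] = votes.get(d, 0) + 1
    return votes


def _collect_candidates(index: SeedIndex, qb: bytes) -> dict[int, int]:
    """Seed-diagonal votes: coarse (step k) probing, with a dense (step 1)
    rescue when the coarse pass finds nothing."""
    votes = _collect_votes(index, qb, index.k)
    if not votes:
        votes = _collect_votes(index, qb, 1)
    return votes


def map_read(read: str, index: SeedIndex, read_id: str = "read",
             scoring: Scoring | None = None, exhaustive_limit: int = 4000,
             max_candidates: int = 16) -> Alignment | None:
    """Best end-to-end placement of a read, or None when unmapped.

    Ties are broken by leftmost target start, then '+' strand. Unmapped is
    a value, not an error.
    """
    scoring = scoring or Scoring()
    L = len(read)
    thr = scoring.threshold(L)
    margin = _gap_margin(scoring, L)
    best: tuple | None = None  # (score, ti, t_start, t_end, strand, edits)

    def consider(score, ti, s, e, strand, edits):
        nonlocal best
        key = (-score, ti, s, 0 if strand == "+" else 1)
        if best is None or key < (-best[0], best[1], best[2], 0 if best[4] == "+" else 1):
            best = (score, ti, s, e, strand, edits)

    strands = (("+", read), ("-", revcomp(read)))
    qbs = [q.encode("ascii") for _s, q in strands]
    votes_by_strand = [_collect_votes(index, qb, index.k) for qb in qbs]
    if not any(votes_by_strand):
        votes_by_strand = [_collect_votes(index, qb, 1) for qb in qbs]

    dp_pool: list[tuple[int, int, int, str]] = []  # (votes, ti, start, strand)
    qcodes: dict[str, np.ndarray] = {}
    for (strand, q), votes in zip(strands, votes_by_strand):
        if not votes:
            continue
        qc = qcodes.setdefault(strand, seq_to_codes(q))
        ranked = sorted(votes.items(), key=lambda kv: (-kv[1], kv[0]))[:max_candidates]
        for d, v in ranked:
            ti, s = index.locate(d)
            tcodes = index.codes[ti]
            if 0 <= s and s + L <= len(tcodes):
                tw = tcodes[s:s + L]
                nmm = int(np.count_nonzero((qc != tw) | (qc == 4) | (tw == 4)))
                score = scoring.mismatch * nmm + scoring.match * (L - nmm)
                if score >= thr:
                    consider(score, ti, s, s + L, strand, None)
                    continue
            dp_pool.append((v, ti, s, strand))
    if best is not None:
        return _finish(best, index, read_id, dict(strands))

    # affine DP over candidate windows (reads that may carry indels)
    dp_pool.sort(key=lambda x: (-x[0], x[1], x[2]))
    seen = set()
    for _v, ti, s, strand in dp_pool[:8]:
        w_lo = max(0, s - margin)
        w_hi = min(len(index.codes[ti]), s + L + margin)
        key = (ti, w_lo // margin if margin else w_lo, strand)
        if key in seen or w_hi - w_lo < 1:
            continue
        seen.add(key)
        q = read if strand == "+" else revcomp(read)
        _run_dp(q, ti, w_lo, w_hi, strand, index, scoring, thr, consider)
    if best is not None:
        return _finish(best, index, read_id, dict(strands))

    # exhaustive rescue for short targets: decisions stay exact
    if index.total_target_len <= exhaustive_limit:
        for strand, q in strands:
            for ti in range(len(index.codes)):
                _run_dp(q, ti, 0, len(index.codes[ti]), strand, index, scoring, thr,
                        consider)
        if best is not None:
            return _finish(best, index, read_id, dict(strands))
    return None


def _run_dp(q, ti, w_lo, w_hi, strand, index, scoring, thr, consider):
    qc = seq_to_codes(q)
    tw = index.codes[ti][w_lo:w_hi]
    score, ts, te, ops = _affine_semiglobal(
        qc.astype(np.int8), tw.astype(np.int8), scoring.match, scoring.mismatch,
        scoring.gap_open, scoring.gap_extend)
    if score >= thr:
        consider(int(score), ti, w_lo + int(ts), w_lo + int(te), strand,
                 _compress_ops(ops))


def _finish(best, index: SeedIndex, read_id: str, strand_seqs) -> Alignment:
    score, ti, s, e, strand, edits = best
    if edits is None:
        qc = seq_to_codes(strand_seqs[strand])
        _nmm, edits = _hamming_edits(qc, index.codes[ti][s:e])
    return Alignment(query_id=read_id, target_id=index.ids[ti], target_start=s,
                     target_end=e, strand=strand, score=score, edits=edits)


# ---------------------------------------------------------------- binning

@dataclass
class BinResult:
    mapped: list
    unmapped: list
    alignments: dict[str, Alignment]   # mate id ("<pair>/1") -> Alignment

    def footprints(self) -> list[tuple[str, int, int]]:
        """Per-pair (id, start, end) footprint over the mapped mates."""
        spans: dict[str, tuple[int, int]] = {}
        for mid, al in self.alignments.items():
            pid = mid.rsplit("/", 1)[0]
            s, e = al.target_start, al.target_end
            if pid in spans:
                s0, e0 = spans[pid]
                spans[pid] = (min(s0, s), max(e0, e))
            else:
                spans[pid] = (s, e)
        return sorted((pid, s, e) for pid, (s, e) in spans.items())


def bin_reads(pairs, index: SeedIndex, scoring: Scoring | None = None) -> BinResult:
    """Split pairs into mapped/unmapped bins against one guide.

    Mate-rescue semantics: a pair is mapped if either mate maps. Pairing is
    preserved in both bins.
    """
    scoring = scoring or Scoring()
    mapped, unmapped = [], []
    alignments: dict[str, Alignment] = {}
    for p in pairs:
        a1 = map_read(p.seq1, index, f"{p.id}/1", scoring)
        a2 = map_read(p.seq2, index, f"{p.id}/2", scoring)
        if a1 is not None:
            alignments[f"{p.id}/1"] = a1
        if a2 is not None:
            alignments[f"{p.id}/2"] = a2
        (mapped if (a1 is not None or a2 is not None) else unmapped).append(p)
    return BinResult(mapped=mapped, unmapped=unmapped, alignments=alignments)


# ------------------------------------------------------------- superblocks

def build_superblocks(footprints: Iterable[tuple[str, int, int]],
                      target_span: int = 50_000, overlap: int = 5_000
                      ) -> list[Superblock]:
    """Tile the covered guide region into overlapping fixed-span windows.

    ``footprints`` are per-pair (id, start, end) intervals sorted by start
    (a :meth:`BinResult.footprints` output). Each pair is assigned to every
    superblock its footprint intersects.
    """
    if overlap >= target_span:
        raise ValueError("overlap must be smaller than target_span")
    fps = sorted(footprints, key=lambda f: (f[1], f[2], f[0]))
    if not fps:
        return []
    lo = fps[0][1]
    hi = max(e for _i, _s, e in fps)
    tiles: list[tuple[int, int]] = []
    s = lo
    while True:
        if s + target_span >= hi:
            tiles.append((s, hi))
            break
        tiles.append((s, s + target_span))
        s += target_span - overlap
    blocks = []
    for ts, te in tiles:
        ids = set()
        cov_bp = 0
        for pid, fs, fe in fps:
            if fs < te and ts < fe:
                ids.add(pid)
                cov_bp += min(fe, te) - max(fs, ts)
        if ids:
            blocks.append(Superblock(guide_interval=(ts, te), read_ids=ids,
                                     est_coverage=cov_bp / max(1, te - ts)))
    return blocks
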