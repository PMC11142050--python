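"""De Bruijn contig assembly per superblock, cross-mapping contig
filtering, and greedy supercontig merging.

The graph is the standard odd-k de Bruijn graph over canonical k-mers
(default k=51, the value that balances accuracy and speed for both the
guide-mapped and unmapped read pools). Counts are stored symmetrically
under both orientations of each k-mer, which makes traversal plain string
arithmetic; node-level queries (counts, degrees) are orientation-free.

Cleaning follows the usual assembler recipe: low-coverage k-mer removal
(auto cutoff from the coverage median), short dead-end tip clipping, and
bubble popping for near-identical branch pairs (heterozygous SNPs and
read errors), applied iteratively to a fixpoint.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable

import edlib

from .core import revcomp

_BASES = (b"A", b"C", b"G", b"T")


@dataclass
class Contig:
    id: str
    sequence: str
    mean_kmer_coverage: float
    origin: str = "mapped"             # "mapped" | "unmapped"
    superblock_id: str | None = None

    def __len__(self) -> int:
        return len(self.sequence)


class DeBruijnGraph:
    """Canonical k-mer graph with coverage counts (k odd).

    ``counts`` holds both orientations of every k-mer with equal counts;
    ``n_nodes``/``nodes()`` report canonical k-mers only.
    """

    def __init__(self, k: int):
        if k % 2 == 0:
            raise ValueError("k must be odd (avoids reverse-complement palindromes)")
        self.k = k
        self.counts: dict[bytes, int] = {}

    # -- node-level queries ------------------------------------------------

    def __contains__(self, kmer: bytes) -> bool:
        return kmer in self.counts

    def coverage(self, kmer: bytes) -> int:
        return self.counts.get(kmer, 0)

    @property
    def n_nodes(self) -> int:
        return sum(1 for km in self.nodes())

    def nodes(self) -> Iterable[bytes]:
        for km in self.counts:
            if km <= _rc(km):
                yield km

    def right_exts(self, kmer: bytes) -> list[bytes]:
        suf = kmer[1:]
        return [suf + b for b in _BASES if suf + b in self.counts]

    def left_exts(self, kmer: bytes) -> list[bytes]:
        pre = kmer[:-1]
        return [b + pre for b in _BASES if b + pre in self.counts]

    def remove(self, kmer: bytes) -> None:
        self.counts.pop(kmer, None)
        self.counts.pop(_rc(kmer), None)


_RC_TABLE = bytes.maketrans(b"ACGTN", b"TGCAN")


def _rc(kmer: bytes) -> bytes:
    return kmer.translate(_RC_TABLE)[::-1]


def build_debruijn(reads: Iterable[str], k: int = 51) -> DeBruijnGraph:
    """Count canonical k-mers of the reads (both mates, both strands).

    Coverage of a k-mer equals the number of reads containing it in either
    orientation. k-mers containing N are skipped.
    """
    g = DeBruijnGraph(k)
    counts = g.counts
    any_long_enough = False
    saw_read = False
    for read in reads:
        saw_read = True
        if len(read) < k:
            continue
        any_long_enough = True
        has_n = "N" in read
        for seq in (read, revcomp(read)):
            b = seq.encode("ascii")
            for i in range(len(b) - k + 1):
                km = b[i:i + k]
                if has_n and b"N" in km:
                    continue
                counts[km] = counts.get(km, 0) + 1
    if saw_read and not any_long_enough:
        raise ValueError(f"all reads shorter than k={k}; use a smaller k")
    return g


# ------------------------------------------------------------- simplify

def _unitigs(g: DeBruijnGraph) -> list[list[bytes]]:
    """Maximal non-branching paths, each reported in one orientation."""
    visited: set[bytes] = set()
    out: list[list[bytes]] = []

    def is_start(km: bytes) -> bool:
        lefts = g.left_exts(km)
        if len(lefts) != 1:
            return True
        return len(g.right_exts(lefts[0])) != 1

    for km in list(g.counts):
        if km in visited:
            continue
        if not is_start(km):
            continue
        path = [km]
        visited.add(km)
        visited.add(_rc(km))
        cur = km
        while True:
            rights = g.right_exts(cur)
            if len(rights) != 1:
                break
            nxt = rights[0]
            if len(g.left_exts(nxt)) != 1 or nxt in visited:
                break
            path.append(nxt)
            visited.add(nxt)
            visited.add(_rc(nxt))
            cur = nxt
        out.append(path)
    # leftover pure cycles
    for km in list(g.counts):
        if km in visited:
            continue
        path = [km]
        visited.add(km)
        visited.add(_rc(km))
        cur = km
        while True:
            rights = g.right_exts(cur)
            if len(rights) != 1 or rights[0] in visited:
                break
            cur = rights[0]
            path.append(cur)
            visited.add(cur)
            visited.add(_rc(cur))
        out.append(path)
    return out


def _spell(path: list[bytes]) -> bytes:
    return path[0] + b"".join(km[-1:] for km in path[1:])


def _path_cov(g: DeBruijnGraph, path: list[bytes]) -> float:
    return sum(g.coverage(km) for km in path) / len(path)


def _auto_cutoff(g: DeBruijnGraph) -> int:
    if not g.counts:
        return 2
    covs = sorted(g.counts.values())
    median = covs[len(covs) // 2]
    return max(2, math.ceil(median / 10))


def _clip_tips(g: DeBruijnGraph, tip_len: int) -> int:
    removed = 0
    for path in _unitigs(g):
        if not all(km in g.counts for km in path):
            continue
        left_dead = not g.left_exts(path[0])
        right_dead = not g.right_exts(path[-1])
        # a tip dangles from exactly one side; isolated paths are kept (they
        # become short contigs and fall to the length filter instead)
        if left_dead != right_dead and len(_spell(path)) < tip_len:
            for km in path:
                g.remove(km)
            removed += 1
    return removed


def _branch_walk(g: DeBruijnGraph, start: bytes, limit: int
                 ) -> tuple[list[bytes], bytes | None]:
    """Follow unique right extensions from ``start`` until the successor is
    a reconvergence node (in-degree > 1); returns (interior, reconvergence).
    """
    path = [start]
    cur = start
    for _ in range(limit):
        rights = g.right_exts(cur)
        if len(rights) != 1:
            return path, None
        nxt = rights[0]
        if len(g.left_exts(nxt)) > 1:
            return path, nxt
        if nxt == start:
            return path, None
        path.append(nxt)
        cur = nxt
    return path, None


def _pop_bubbles(g: DeBruijnGraph, bubble_ident: float, limit: int) -> int:
    popped = 0
    for km in list(g.counts):
        if km not in g.counts:
            continue
        rights = g.right_exts(km)
        if len(rights) < 2:
            continue
        walks = [_branch_walk(g, r, limit) for r in rights]
        done = False
        for i in range(len(walks)):
            for j in range(i + 1, len(walks)):
                (pa, ea), (pb, eb) = walks[i], walks[j]
                if ea is None or eb is None or ea != eb:
                    continue
                if set(pa) & set(pb):
                    continue
                sa, sb = _spell(pa), _spell(pb)
                dist = edlib.align(sa.decode(), sb.decode(),
                                   task="distance")["editDistance"]
                ident = 1.0 - dist / max(len(sa), len(sb))
                if ident < bubble_ident:
                    continue
                ca, cb = _path_cov(g, pa), _path_cov(g, pb)
                # keep the higher-coverage branch; break exact ties by
                # sequence so popping is deterministic
                loser = pb if (ca, sa) >= (cb, sb) else pa
                for node in loser:
                    g.remove(node)
                popped += 1
                done = True
                break
            if done:
                break
    return popped


def simplify_graph(g: DeBruijnGraph, tip_len: int | None = None,
                   bubble_ident: float = 0.95, cov_cutoff="auto",
                   max_rounds: int = 8) -> DeBruijnGraph:
    """Clean the graph: coverage cutoff, tip clipping, bubble popping.

    ``cov_cutoff='auto'`` uses max(2, ceil(median coverage / 10)). Cleaning
    repeats until a fixpoint (or ``max_rounds``).
    """
    tip_len = tip_len if tip_len is not None else 2 * g.k
    cutoff = _auto_cutoff(g) if cov_cutoff == "auto" else cov_cutoff
    if cutoff and cutoff > 1:
        for km in [km for km, c in g.counts.items() if c < cutoff]:
            g.counts.pop(km, None)
    limit = max(10 * g.k, 500)
    for _ in range(max_rounds):
        changed = _clip_tips(g, tip_len)
        changed += _pop_bubbles(g, bubble_ident, limit)
        if not changed:
            break
    return g


def extract_contigs(g: DeBruijnGraph, min_contig_len: int = 100,
                    origin: str = "mapped", superblock_id: str | None = None,
                    id_prefix: str = "ctg") -> list[Contig]:
    """Spell maximal non-branching paths into contigs with mean coverage."""
    contigs = []
    for path in _unitigs(g):
        seq = _spell(path).decode()
        if len(seq) < min_contig_len:
            continue
        canon = min(seq, revcomp(seq))
        contigs.append((canon, _path_cov(g, path)))
    contigs.sort(key=lambda c: (-len(c[0]), c[0]))
    return [Contig(id=f"{id_prefix}_{i:05d}", sequence=seq, mean_kmer_coverage=cov,
                   origin=origin, superblock_id=superblock_id)
            for i, (seq, cov) in enumerate(contigs)]


# ------------------------------------------------- cross-mapping filter

def _chunk_match_fraction(seq: str, targets: list[str], min_ident: float,
                          chunk: int = 300) -> float:
    """Fraction of ``seq`` bp whose chunks align to any target at
    >= min_ident identity (edlib infix search, both strands)."""
    n = len(seq)
    matched = 0
    pos = 0
    while pos < n:
        end = min(n, pos + chunk)
        if n - end < chunk // 2:
            end = n
        piece = seq[pos:end]
        budget = int(len(piece) * (1 - min_ident))
        hit = False
        for cand in (piece, revcomp(piece)):
            for t in targets:
                r = edlib.align(cand, t, mode="HW", task="distance", k=budget)
                if r["editDistance"] != -1:
                    hit = True
                    break
            if hit:
                break
        if hit:
            matched += len(piece)
        pos = end
    return matched / n if n else 0.0


def filter_cross_mapping(unmapped_contigs: list[Contig], alt_bmh: str | None = None,
                         decoys: Iterable[str] | None = None, min_ident: float = 0.9,
                         min_cov: float = 0.5) -> list[Contig]:
    """Drop unmapped-pool contigs that belong elsewhere.

    A contig is removed when >= ``min_cov`` of its length aligns at
    >= ``min_ident`` identity to the alternative BMH (heterozygous
    individuals) or to any decoy sequence (off-target genome). With no
    targets given this is the identity.
    """
    targets = list(decoys or [])
    if alt_bmh:
        targets.append(alt_bmh)
    if not targets:
        return list(unmapped_contigs)
    return [c for c in unmapped_contigs
            if _chunk_match_fraction(c.sequence, targets, min_ident) < min_cov]


# ------------------------------------------------------- supercontig merge

def _end_kmer_map(seq: str, k: int, max_ovl: int) -> dict[str, int]:
    """First occurrence position of each k-mer within the prefix region."""
    region = seq[:max_ovl + k]
    out: dict[str, int] = {}
    for i in range(len(region) - k + 1):
        km = region[i:i + k]
        if km not in out:
            out[km] = i
    return out


def _overlap_identity(a: str, b: str) -> float:
    mism = sum(1 for x, y in zip(a, b) if x != y)
    return 1.0 - mism / len(a) if a else 0.0


def _drop_contained(items: list[tuple[str, float, str]], min_ident: float
                    ) -> list[tuple[str, float, str]]:
    """Remove entries contained in a longer entry at >= min_ident identity."""
    items = sorted(items, key=lambda w: (-len(w[0]), w[0]))
    kept: list[tuple[str, float, str]] = []
    for seq, cov, orig in items:
        budget = int(len(seq) * (1 - min_ident))
        contained = False
        for kseq, _kc, _ko in kept:
            for cand in (seq, revcomp(seq)):
                r = edlib.align(cand, kseq, mode="HW", task="distance", k=budget)
                if r["editDistance"] != -1:
                    contained = True
                    break
            if contained:
                break
        if not contained:
            kept.append((seq, cov, orig))
    return kept


def merge_supercontigs(contigs: list[Contig], min_ovl: int = 40,
                       min_ident: float = 0.95, probe_k: int = 25,
                       max_ovl: int = 6000) -> list[Contig]:
    """Greedy overlap-layout merge into non-redundant supercontigs.

    Contigs fully contained in a longer contig (at >= ``min_ident``) are
    dropped; suffix-prefix overlaps >= ``min_ovl`` bp at >= ``min_ident``
    identity (substitution-only comparison; indel-bearing overlaps stay
    unmerged and are left to scaffolding) are joined, the disputed overlap
    taken from the higher-coverage side. Repeats until no qualifying
    overlap or containment remains. Overlaps are found through exact probe
    k-mers near contig ends, in all relative orientations.
    """
    if not contigs:
        raise ValueError("merge_supercontigs requires at least one contig")
    work = _drop_contained(
        [(c.sequence, c.mean_kmer_coverage, c.origin) for c in contigs], min_ident)

    items: dict[int, tuple[str, float, str]] = {}
    pmaps: dict[tuple[int, str], dict[str, int]] = {}
    next_id = 0

    def add(entry):
        nonlocal next_id
        idx = next_id
        next_id += 1
        items[idx] = entry
        seq = entry[0]
        pmaps[(idx, "+")] = _end_kmer_map(seq, probe_k, max_ovl)
        pmaps[(idx, "-")] = _end_kmer_map(revcomp(seq), probe_k, max_ovl)
        return idx

    def drop(idx):
        del items[idx]
        del pmaps[(idx, "+")]
        del pmaps[(idx, "-")]

    def _n_suitors(bi, bo, exclude):
        """Distinct contigs whose suffix qualifies against (bi, bo)'s prefix."""
        pmap = pmaps[(bi, bo)]
        suitors = set()
        for xi, (xseq, _xc, _xo) in items.items():
            if xi == bi:
                continue
            for xo in ("+", "-"):
                x = xseq if xo == "+" else revcomp(xseq)
                lx = len(x)
                for q in (lx - probe_k, lx - probe_k - 50, lx - probe_k - 125):
                    if q < 0:
                        continue
                    p = pmap.get(x[q:q + probe_k])
                    if p is None:
                        continue
                    b = items[bi][0] if bo == "+" else revcomp(items[bi][0])
                    ovl = lx - (q - p)
                    if ovl < min_ovl or ovl > min(lx, len(b), max_ovl):
                        continue
                    if _overlap_identity(x[lx - ovl:], b[:ovl]) >= min_ident:
                        suitors.add(xi)
                        break
        suitors.add(exclude)
        return len(suitors)

    def try_merge(ai):
        """Find one unambiguous suffix->prefix join with ``ai`` on the left.

        An end with two distinct qualifying partners (typical of contigs
        ending inside similar repeat copies) is left unmerged — joining
        either would risk a chimera.
        """
        aseq, acov, aorig = items[ai]
        for ao in ("+", "-"):
            a = aseq if ao == "+" else revcomp(aseq)
            la = len(a)
            hits: dict[tuple[int, str], int] = {}
            for q in (la - probe_k, la - probe_k - 50, la - probe_k - 125):
                if q < 0:
                    continue
                probe = a[q:q + probe_k]
                for (bi, bo), pmap in pmaps.items():
                    if bi == ai:
                        continue
                    p = pmap.get(probe)
                    if p is None:
                        continue
                    b = items[bi][0] if bo == "+" else revcomp(items[bi][0])
                    ovl = la - (q - p)
                    if ovl < min_ovl or ovl > min(la, len(b), max_ovl):
                        continue
                    if _overlap_identity(a[la - ovl:], b[:ovl]) < min_ident:
                        continue
                    prev = hits.get((bi, bo))
                    if prev is None or ovl > prev:
                        hits[(bi, bo)] = ovl
            if not hits or len(hits) > 1:
                continue
            (bi, bo), ovl = next(iter(hits.items()))
            if _n_suitors(bi, bo, exclude=ai) > 1:
                continue                    # partner's end is itself contested
            bseq, bcov, borig = items[bi]
            b = bseq if bo == "+" else revcomp(bseq)
            keep_a = acov >= bcov
            merged = a[:la - ovl] + (a[la - ovl:] if keep_a else b[:ovl]) + b[ovl:]
            cov = (acov * la + bcov * len(b)) / (la + len(b))
            orig = aorig if aorig == borig else "mixed"
            return bi, (merged, cov, orig)
        return None

    queue = [add(w) for w in work]
    while queue:
        ai = queue.pop()
        if ai not in items:
            continue
        hit = try_merge(ai)
        if hit is None:
            continue
        bi, entry = hit
        drop(ai)
        drop(bi)
        queue.append(add(entry))

    final = _drop_contained(list(items.values()), min_ident)
    final.sort(key=lambda w: (-len(w[0]), w[0]))
    return [Contig(id=f"sctg_{i:05d}", sequence=min(seq, revcomp(seq)),
                   mean_kmer_coverage=cov, origin=orig)
            for i, (seq, cov, orig) in enumerate(final)]
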