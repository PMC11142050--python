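"""Pileup polishing, paired-end scaffolding, guide-based ordering and
orientation with score filtering, and consensus emission.

Polishing maps the read set back onto the contigs and applies a majority
vote per column (alternative base > 50% of >= 5 covering reads; indels
restricted to length-1 events). Scaffolding links contigs joined by >= 3
consistently oriented read pairs, estimates gaps from the insert-size
model, and resolves branching links by support. Placement mirrors a
reference-guided scaffolder's confidence scores: a scaffold's pieces vote
for a placement window and strand on the guide; ``location_score`` is the
fraction of aligned bp supporting the modal window, ``orientation_score``
the fraction on the modal strand. Scaffolds failing the published filter
(location < 0.1, or location < 0.3 and orientation < 0.75) are demoted to
the unplaced output rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
import numpy as np

from .assemble import Contig
from .binmap import Scoring, SeedIndex, _collect_candidates, map_read
from .core import revcomp, seq_to_codes

MIN_GAP = 10


@dataclass
class Scaffold:
    id: str
    parts: list[tuple[str, str]]          # (contig_id, strand)
    gaps: list[int]                       # N-run lengths between parts
    sequence: str

    def __post_init__(self):
        if len(self.gaps) != max(0, len(self.parts) - 1):
            raise ValueError("len(gaps) must equal len(parts) - 1")


@dataclass
class PlacementScore:
    scaffold_id: str
    location_score: float
    orientation_score: float
    assigned_start: int
    assigned_strand: str


@dataclass
class OrientedAssembly:
    placed_consensus: str
    unplaced: list[Scaffold]
    placed: list[tuple[Scaffold, PlacementScore]] = field(default_factory=list)
    unplaced_scores: list[PlacementScore] = field(default_factory=list)


# ---------------------------------------------------------------- polishing

def _map_pairs_to_targets(pairs, index: SeedIndex, scoring: Scoring):
    """Yield (pair, mate_no, oriented_query, alignment) for mapping mates."""
    for p in pairs:
        for mate_no, seq in ((1, p.seq1), (2, p.seq2)):
            al = map_read(seq, index, f"{p.id}/{mate_no}", scoring)
            if al is None:
                continue
            q = seq if al.strand == "+" else revcomp(seq)
            yield p, mate_no, q, al


def polish_contigs(contigs: list[Contig], pairs, min_depth: int = 5,
                   majority: float = 0.5, scoring: Scoring | None = None
                   ) -> list[Contig]:
    """Majority-vote pileup polishing of contig consensus bases.

    A column is edited only when covered by >= ``min_depth`` reads and an
    alternative call (base, or a length-1 insertion/deletion) exceeds the
    ``majority`` fraction of covering reads.
    """
    if not contigs:
        return []
    scoring = scoring or Scoring()
    index = SeedIndex({c.id: c.sequence for c in contigs})
    tmap = {c.id: i for i, c in enumerate(contigs)}
    piles = [np.zeros((len(c.sequence), 5), dtype=np.int32) for c in contigs]  # ACGT + del
    ins: dict[tuple[int, int], dict[str, int]] = {}

    for _p, _m, q, al in _map_pairs_to_targets(pairs, index, scoring):
        ci = tmap[al.target_id]
        qc = seq_to_codes(q)
        pile = piles[ci]
        qi, ti = 0, al.target_start
        for op, l in al.edits:
            if op in "MX":
                np.add.at(pile, (np.arange(ti, ti + l), np.minimum(qc[qi:qi + l], 3)), 1)
                qi += l
                ti += l
            elif op == "I":
                if l == 1:
                    slot = ins.setdefault((ci, ti), {})
                    base = q[qi]
                    slot[base] = slot.get(base, 0) + 1
                qi += l
            else:  # D
                if l == 1:
                    pile[ti, 4] += 1
                ti += l

    polished = []
    for ci, c in enumerate(contigs):
        pile = piles[ci]
        depth = pile.sum(axis=1)
        out = []
        for t, base in enumerate(c.sequence):
            islot = ins.get((ci, t))
            if islot:
                b, n = max(islot.items(), key=lambda kv: (kv[1], kv[0]))
                if depth[t] >= min_depth and n > majority * depth[t]:
                    out.append(b)
            if depth[t] >= min_depth:
                wi = int(np.argmax(pile[t]))
                if pile[t, wi] > majority * depth[t]:
                    if wi == 4:
                        continue                      # deletion wins
                    out.append("ACGT"[wi])
                    continue
            out.append(base)
        polished.append(Contig(id=c.id, sequence="".join(out),
                               mean_kmer_coverage=c.mean_kmer_coverage,
                               origin=c.origin, superblock_id=c.superblock_id))
    return polished


# -------------------------------------------------------------- scaffolding

def scaffold_paired(contigs: list[Contig], pairs, insert_mean: float,
                    insert_sd: float, min_links: int = 3,
                    scoring: Scoring | None = None) -> list[Scaffold]:
    """Link contigs spanned by consistently oriented read pairs.

    A link needs >= ``min_links`` supporting pairs; the gap is the mean of
    per-pair estimates ``insert - d1 - d2`` floored at 10 N. Branching
    links are resolved by highest support; exact ties leave the ends
    unlinked. Only linear chains are emitted.
    """
    if not contigs:
        return []
    scoring = scoring or Scoring()
    index = SeedIndex({c.id: c.sequence for c in contigs})
    seqs = {c.id: c.sequence for c in contigs}
    lens = {c.id: len(c.sequence) for c in contigs}

    by_pair: dict[str, list] = {}
    for p, mate_no, _q, al in _map_pairs_to_targets(pairs, index, scoring):
        by_pair.setdefault(p.id, []).append(al)

    raw: dict[tuple, list[float]] = {}
    for pid, als in by_pair.items():
        if len(als) != 2 or als[0].target_id == als[1].target_id:
            continue
        sides = []
        for al in als:
            if al.strand == "+":
                sides.append((al.target_id, "R", lens[al.target_id] - al.target_start))
            else:
                sides.append((al.target_id, "L", al.target_end))
        (xa, ea, da), (xb, eb, db) = sides
        gap = insert_mean - da - db
        if gap > insert_mean + 6 * insert_sd:
            continue
        key = ((xa, ea), (xb, eb))
        if (xb, eb) < (xa, ea):
            key = ((xb, eb), (xa, ea))
        raw.setdefault(key, []).append(gap)

    # orientation-conflict resolution per contig pair
    by_cpair: dict[tuple, list[tuple]] = {}
    for (na, nb), gaps in raw.items():
        by_cpair.setdefault((na[0], nb[0]), []).append((na, nb, gaps))
    edges = []
    for _cp, variants in by_cpair.items():
        variants.sort(key=lambda v: (-len(v[2]), v[0], v[1]))
        if len(variants) > 1 and len(variants[0][2]) == len(variants[1][2]):
            continue                                  # conflicting, drop
        na, nb, gaps = variants[0]
        mean_gap = float(np.mean(gaps))
        # a strongly negative gap means the contigs overlap but would not
        # merge (disagreeing sequence): linking them would duplicate the
        # overlap, so leave them to guide placement instead
        if len(gaps) >= min_links and mean_gap >= -2 * insert_sd:
            edges.append((len(gaps), na, nb, mean_gap))

    # per-end tie blocking, then greedy linear chaining
    per_end: dict[tuple, list[int]] = {}
    for i, (sup, na, nb, _g) in enumerate(edges):
        per_end.setdefault(na, []).append(i)
        per_end.setdefault(nb, []).append(i)
    blocked_ends = set()
    for end, eids in per_end.items():
        sups = sorted((edges[i][0] for i in eids), reverse=True)
        if len(sups) > 1 and sups[0] == sups[1]:
            blocked_ends.add(end)

    parent: dict[str, str] = {c.id: c.id for c in contigs}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    used_ends = set()
    links: dict[tuple, tuple] = {}
    for sup, na, nb, gap in sorted(edges, key=lambda e: (-e[0], e[1], e[2])):
        if na in blocked_ends or nb in blocked_ends:
            continue
        if na in used_ends or nb in used_ends:
            continue
        if find(na[0]) == find(nb[0]):
            continue
        used_ends.update((na, nb))
        parent[find(na[0])] = find(nb[0])
        links[na] = (nb, gap)
        links[nb] = (na, gap)

    # walk each chain from a terminus
    def walk_to_terminus(start_id):
        node, came_from = start_id, None
        for _ in range(len(contigs) + 1):
            ends = [e for e in ("L", "R") if (node, e) in links and e != came_from]
            if not ends:
                return node
            (nnode, nend), _g = links[(node, ends[0])]
            node, came_from = nnode, nend
        return node

    scaffolds = []
    visited: set[str] = set()
    sid = 0
    for c in sorted(contigs, key=lambda c: (-len(c.sequence), c.id)):
        if c.id in visited:
            continue
        node = walk_to_terminus(c.id)
        parts, raw_gaps, seq_parts = [], [], []
        entry = None
        for _ in range(len(contigs) + 1):
            visited.add(node)
            if entry is None:
                linked = [e for e in ("L", "R") if (node, e) in links]
                leave = linked[0] if linked else "R"
            else:
                leave = "L" if entry == "R" else "R"
            orient = "+" if leave == "R" else "-"
            parts.append((node, orient))
            seq_parts.append(seqs[node] if orient == "+" else revcomp(seqs[node]))
            nxt = links.get((node, leave))
            if nxt is None:
                break
            (nnode, nend), gap = nxt
            raw_gaps.append(int(round(gap)))
            node, entry = nnode, nend
        seq_out = seq_parts[0]
        gaps_out = []
        for i in range(1, len(seq_parts)):
            g = raw_gaps[i - 1]
            part = seq_parts[i]
            if g < MIN_GAP:
                # the insert model says these contigs (nearly) abut or
                # overlap: resolve the seam by sequence where possible
                o = _overlap_scan(seq_out[-400:].lstrip("N"), part, max(0, -g))
                if o is not None:
                    seq_out += part[o:]
                    gaps_out.append(0)       # verified seam, no gap run
                    continue
                part = part[max(0, -g):]     # unverified overlap: trim estimate
                g = MIN_GAP
            g = max(MIN_GAP, g)
            seq_out += "N" * g + part
            gaps_out.append(g)
        scaffolds.append(Scaffold(id=f"scf_{sid:04d}", parts=parts,
                                  gaps=gaps_out, sequence=seq_out))
        sid += 1
    return scaffolds


# ---------------------------------------------------------------- placement

def _split_pieces(seq: str, piece: int = 1000, min_piece: int = 60):
    """(offset, subsequence) pieces between N-gaps, chopped to ``piece`` bp."""
    out = []
    start = None
    for i, b in enumerate(seq + "N"):
        if b == "N":
            if start is not None:
                seg = seq[start:i]
                for off in range(0, len(seg), piece):
                    sub = seg[off:off + piece]
                    if len(sub) >= min_piece:
                        out.append((start + off, sub))
                start = None
        elif start is None:
            start = i
    return out


def score_placement(scaffold: Scaffold, guide_index: SeedIndex,
                    cluster_tol: int | None = None) -> PlacementScore:
    """Seed-vote placement confidence of one scaffold on the guide."""
    seq = scaffold.sequence
    Ls = len(seq)
    tol = cluster_tol if cluster_tol is not None else max(10_000, Ls)
    placed = []     # (origin, strand, weight)
    for off, sub in _split_pieces(seq):
        best = None  # (votes, strand, diag)
        for strand, q in (("+", sub), ("-", revcomp(sub))):
            votes = _collect_candidates(guide_index, q.encode("ascii"))
            if not votes:
                continue
            # cluster nearby diagonals
            diags = sorted(votes)
            acc: list[list[int]] = []
            for d in diags:
                if acc and d - acc[-1][0] <= 200:
                    acc[-1][1] += votes[d]
                else:
                    acc.append([d, votes[d]])
            for d0, v in acc:
                cand = (v, strand, d0)
                if best is None or (cand[0], cand[1] == "+", -cand[2]) > (
                        best[0], best[1] == "+", -best[2]):
                    best = cand
        if best is None:
            continue
        v, strand, d = best
        lp = len(sub)
        origin = d - off if strand == "+" else d - (Ls - off - lp)
        placed.append((origin, strand, lp))

    if not placed:
        return PlacementScore(scaffold.id, 0.0, 0.0, 0, "+")

    total = sum(w for _o, _s, w in placed)
    placed.sort(key=lambda p: p[0])
    clusters: list[list[tuple]] = []
    for item in placed:
        if clusters and item[0] - clusters[-1][0][0] <= tol:
            clusters[-1].append(item)
        else:
            clusters.append([item])
    modal = max(clusters, key=lambda cl: (sum(w for _o, _s, w in cl),
                                          -cl[0][0]))
    loc = sum(w for _o, _s, w in modal) / total
    plus = sum(w for _o, s, w in placed if s == "+")
    strand = "+" if plus >= total - plus else "-"
    orient = max(plus, total - plus) / total
    in_strand = [o for o, s, _w in modal if s == strand] or [o for o, _s, _w in modal]
    assigned = int(np.median(in_strand))
    return PlacementScore(scaffold.id, loc, orient, assigned, strand)


def _overlap_scan(tail: str, head: str, o_est: int, scan: int = 150,
                  min_ident: float = 0.9, min_w: int = 25,
                  max_ovl: int = 2000) -> int | None:
    """Verified suffix(tail)/prefix(head) overlap length nearest ``o_est``.

    Scans overlap lengths outward from the estimate and accepts the first
    length whose terminal ``min(o, len(tail), 300)`` bases agree at
    >= ``min_ident``; returns None when no overlap is supported.
    """
    if len(tail) < min_w:
        return None
    tail_np = seq_to_codes(tail)
    head_np = seq_to_codes(head[:min(len(head), o_est + scan + 10)])
    lo, hi = 1, min(len(head_np), o_est + scan, max_ovl)
    for delta in range(0, scan + 1):
        for o in ({o_est - delta, o_est + delta} if delta else {o_est}):
            if not (lo <= o <= hi):
                continue
            w = min(o, len(tail_np), 300)
            if w < min_w:
                continue
            a, b = tail_np[-w:], head_np[o - w:o]
            ident = float(np.mean((a == b) & (a != 4)))
            if ident >= min_ident:
                return o
    return None


def _consensus_tail(pieces: list[str], tail_len: int) -> str:
    tail = ""
    for piece in reversed(pieces):
        if "N" in piece:
            tail = piece[piece.rfind("N") + 1:] + tail
            break
        tail = piece + tail
        if len(tail) >= tail_len:
            break
    return tail[-tail_len:]


def _verified_junction_cut(pieces: list[str], seq: str, trim: int,
                           tail_len: int = 400, min_ident: float = 0.9,
                           scan: int = 150, max_scan_ovl: int = 2000) -> int | None:
    """Sequence-verified cut for an overlapping scaffold junction.

    The coordinate estimate says the incoming scaffold's first ``trim``
    bases repeat already-emitted consensus. The true overlap is found by
    scanning overlap lengths around that estimate and comparing the
    consensus suffix with the scaffold prefix; for overlaps longer than
    the probe tail, the whole tail is located inside the scaffold head
    instead. Returns the verified redundant-prefix length, or None when no
    cut is supported by sequence (caller decides the fallback).
    """
    tail = _consensus_tail(pieces, tail_len)
    o = _overlap_scan(tail, seq, trim, scan=scan, min_ident=min_ident,
                      max_ovl=max_scan_ovl)
    if o is not None:
        return o
    # large overlap: locate the full tail inside the scaffold head
    if trim > len(tail) >= 50:
        big_head = seq[:trim + tail_len + 200]
        r = edlib.align(tail, big_head, mode="HW", task="locations",
                        k=int(len(tail) * (1 - min_ident)))
        if r["editDistance"] != -1 and r["locations"]:
            return r["locations"][0][1] + 1
    return None


def passes_placement_filter(score: PlacementScore) -> bool:
    """The published scaffold-orientation filter: reject when location
    score < 0.1, or location < 0.3 with orientation score < 0.75."""
    if score.location_score < 0.1:
        return False
    if score.location_score < 0.3 and score.orientation_score < 0.75:
        return False
    return True


def place_and_filter(scaffolds: list[Scaffold], guide_index: SeedIndex,
                     scores: list[PlacementScore] | None = None) -> OrientedAssembly:
    """Order/orient scaffolds on the guide and emit one placed consensus.

    Survivors are sorted by assigned guide start, reverse-complemented when
    placed on '-', and concatenated with N gaps sized from guide spacing
    (minimum 10 N). Filtered scaffolds are reported unplaced.
    """
    if scores is None:
        scores = [score_placement(s, guide_index) for s in scaffolds]
    placed, unplaced, unplaced_scores = [], [], []
    for s, sc in zip(scaffolds, scores):
        if passes_placement_filter(sc):
            placed.append((s, sc))
        else:
            unplaced.append(s)
            unplaced_scores.append(sc)
    placed.sort(key=lambda t: (t[1].assigned_start, -len(t[0].sequence), t[0].id))
    pieces = []
    kept: list[tuple[Scaffold, PlacementScore]] = []
    cursor = None
    for s, sc in placed:
        seq = s.sequence if sc.assigned_strand == "+" else revcomp(s.sequence)
        start = sc.assigned_start
        if cursor is None:
            pieces.append(seq)
        elif start >= cursor:
            pieces.append("N" * max(MIN_GAP, start - cursor))
            pieces.append(seq)
        else:
            # guide coordinates say this scaffold overlaps the previous one:
            # resolve the junction by sequence where possible (exact cut at
            # the point where the emitted consensus ends inside this
            # scaffold), else trim by coordinates under an N spacer
            trim = cursor - start
            if trim >= len(seq):
                unplaced.append(s)
                unplaced_scores.append(sc)
                continue
            cut = _verified_junction_cut(pieces, seq, trim)
            if cut is not None and cut >= len(seq):
                unplaced.append(s)
                unplaced_scores.append(sc)
                continue
            if cut is not None:
                seq = seq[cut:]
            elif trim <= 100:
                # placement jitter without detectable sequence overlap:
                # treat as abutting rather than cutting unverified sequence
                pieces.append("N" * MIN_GAP)
            else:
                pieces.append("N" * MIN_GAP)
                seq = seq[trim:]
            pieces.append(seq)
            start = cursor
        kept.append((s, sc))
        cursor = start + len(seq)
    return OrientedAssembly(placed_consensus="".join(pieces), unplaced=unplaced,
                            placed=kept, unplaced_scores=unplaced_scores)
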