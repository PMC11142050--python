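"""Read quality control: poly-G artifact removal, seeded subsampling,
quality trimming.

The filters follow the standard short-read pre-assembly recipe: drop read
pairs carrying a long (>= 20 bp by default) guanine homopolymer — a known
Illumina two-colour chemistry artifact — optionally subsample pairs with a
fixed seed, then trim each mate (strip leading/trailing bases with Q < 3 or
N, truncate at the first 4-base sliding window with mean quality <= 15) and
drop mates shorter than 40 bp. A pair survives only if both mates survive.
Adapter removal is assumed to have happened upstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core import ReadPair, phred_to_array, stage_rng


@dataclass
class QCConfig:
    min_g_run: int = 20
    n_pairs: int | None = None
    seed: int = 0
    lead_trail_q: int = 3
    window: int = 4
    window_q: int = 15
    min_len: int = 40

    def validate(self) -> None:
        if self.min_g_run < 1:
            raise ValueError("min_g_run must be >= 1")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")


def filter_g_homopolymer(pairs: list[ReadPair], min_g_run: int = 20) -> list[ReadPair]:
    """Drop whole pairs where either mate contains a >= ``min_g_run`` G-run."""
    run = "G" * min_g_run
    return [p for p in pairs if run not in p.seq1 and run not in p.seq2]


def subsample_pairs(pairs: list[ReadPair], n_pairs: int | None, seed: int = 0) -> list[ReadPair]:
    """Select exactly ``n_pairs`` pairs (mates kept together), seed-stable.

    Requesting more pairs than available passes the input through with a
    warning rather than failing, matching pipeline batch semantics.
    """
    if n_pairs is None or n_pairs == len(pairs):
        return list(pairs)
    if n_pairs > len(pairs):
        warnings.warn(f"requested {n_pairs} pairs but only {len(pairs)} available; "
                      "keeping all", stacklevel=2)
        return list(pairs)
    rng = stage_rng(seed, "subsample")
    idx = np.sort(rng.choice(len(pairs), size=n_pairs, replace=False))
    return [pairs[i] for i in idx]


def _trim_mate(seq: str, qual: str, cfg: QCConfig) -> tuple[str, str] | None:
    if len(seq) != len(qual):
        raise ValueError("sequence/quality length mismatch")
    q = phred_to_array(qual)
    n = len(seq)
    lo, hi = 0, n
    while lo < hi and (q[lo] < cfg.lead_trail_q or seq[lo] == "N"):
        lo += 1
    while hi > lo and (q[hi - 1] < cfg.lead_trail_q or seq[hi - 1] == "N"):
        hi -= 1
    # 5'->3' sliding windows: truncate at the start of the first window whose
    # mean quality is <= window_q
    w = cfg.window
    sub = q[lo:hi]
    if len(sub) >= w:
        means = np.convolve(sub, np.ones(w), mode="valid") / w
        bad = np.nonzero(means <= cfg.window_q)[0]
        if bad.size:
            hi = lo + int(bad[0])
    # the truncation point may expose a new low-quality tail; strip it so the
    # filter is idempotent
    while hi > lo and (q[hi - 1] < cfg.lead_trail_q or seq[hi - 1] == "N"):
        hi -= 1
    if hi - lo < cfg.min_len:
        return None
    return seq[lo:hi], qual[lo:hi]


def trim_reads(pairs: list[ReadPair], cfg: QCConfig | None = None) -> list[ReadPair]:
    """Quality-trim both mates; a pair survives only if both mates do."""
    cfg = cfg or QCConfig()
    cfg.validate()
    out = []
    for p in pairs:
        try:
            m1 = _trim_mate(p.seq1, p.qual1, cfg)
            m2 = _trim_mate(p.seq2, p.qual2, cfg)
        except ValueError as exc:
            raise ValueError(f"malformed FASTQ record {p.id!r}: {exc}") from exc
        if m1 is None or m2 is None:
            continue
        out.append(ReadPair(p.id, m1[0], m1[1], m2[0], m2[1]))
    return out


def run_qc(pairs: list[ReadPair], cfg: QCConfig | None = None
           ) -> tuple[list[ReadPair], dict[str, int]]:
    """Full QC stage; returns surviving pairs and per-filter counters."""
    cfg = cfg or QCConfig()
    cfg.validate()
    stats = {"input_pairs": len(pairs)}
    pairs = filter_g_homopolymer(pairs, cfg.min_g_run)
    stats["after_g_filter"] = len(pairs)
    pairs = subsample_pairs(pairs, cfg.n_pairs, cfg.seed)
    stats["after_subsample"] = len(pairs)
    pairs = trim_reads(pairs, cfg)
    stats["after_trim"] = len(pairs)
    stats["output_pairs"] = len(pairs)
    return pairs, stats
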