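"""Shared primitives: DNA helpers, seeded RNG streams, the read-pair record.

Coordinates are 0-based half-open everywhere inside the package; emitted
tables that follow 1-based conventions (VCF, AGP-like placements) convert at
the I/O boundary.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np

_COMP = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: Byte code for each base used by the vectorised mappers/pileups.
BASE_TO_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}
CODE_TO_BASE = "ACGTN"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMP)[::-1]


_CODE_LUT = np.full(256, 4, dtype=np.uint8)
for _b, _c in BASE_TO_CODE.items():
    _CODE_LUT[ord(_b)] = _c
    _CODE_LUT[ord(_b.lower())] = _c


def seq_to_codes(seq: str) -> np.ndarray:
    """Encode a DNA string as uint8 codes (A=0, C=1, G=2, T=3, N=4)."""
    return _CODE_LUT[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Independent, reproducible random stream for a named pipeline stage.

    Every source of randomness in the package flows from one integer seed;
    the stage name is folded in through a CRC so that stages can be re-run
    in isolation without perturbing each other.
    """
    return np.random.default_rng([zlib.crc32(stage.encode("ascii")), int(seed)])


def random_dna(length: int, rng: np.random.Generator) -> str:
    codes = rng.integers(0, 4, size=length)
    return "".join("ACGT"[c] for c in codes)


def phred_to_array(qual: str) -> np.ndarray:
    """Phred+33 quality string to integer scores."""
    return np.frombuffer(qual.encode("ascii"), dtype=np.uint8).astype(np.int32) - 33


def array_to_phred(scores) -> str:
    return "".join(chr(int(q) + 33) for q in scores)


@dataclass
class ReadPair:
    """A paired-end read: two mates with per-base qualities.

    ``id`` carries simulator provenance when the pair is synthetic
    (individual, source haplotype, fragment start, insert size), which lets
    downstream tests recover ground truth without side tables.
    """

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def mates(self):
        return (self.seq1, self.qual1), (self.seq2, self.qual2)

    @property
    def total_bp(self) -> int:
        return len(self.seq1) + len(self.seq2)
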