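"""File-format glue: FASTA, FASTQ, BED, TSV and minimal VCF.

FASTA goes through Biopython; FASTQ pairs use a plain 4-line reader/writer
(records are strictly 4 lines, gzip chosen by file suffix) because the
simulator and QC stages stream millions of records and need no feature of a
richer parser. BED intervals are 0-based half-open.
"""

from __future__ import annotations

import gzip
import json
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import ReadPair


def _open(path, mode="rt"):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping."""
    with _open(path) as fh:
        return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(fh, "fasta")}


def write_fasta(path, records: dict[str, str] | Iterable[tuple[str, str]],
                descriptions: dict[str, str] | None = None) -> None:
    if isinstance(records, dict):
        records = records.items()
    recs = []
    for name, seq in records:
        desc = (descriptions or {}).get(name, "")
        recs.append(SeqRecord(Seq(seq), id=name, description=desc))
    with _open(path, "wt") as fh:
        SeqIO.write(recs, fh, "fasta")


# ---------------------------------------------------------------- FASTQ

class MalformedFastqError(ValueError):
    pass


def read_fastq_pairs(r1_path, r2_path) -> list[ReadPair]:
    """Read mate-paired FASTQ files (4-line records, optionally gzipped)."""
    pairs = []
    with _open(r1_path) as f1, _open(r2_path) as f2:
        while True:
            h1 = f1.readline()
            h2 = f2.readline()
            if not h1 and not h2:
                break
            s1, p1, q1 = f1.readline(), f1.readline(), f1.readline()
            s2, p2, q2 = f2.readline(), f2.readline(), f2.readline()
            if not (h1.startswith("@") and h2.startswith("@")) or not q1 or not q2:
                raise MalformedFastqError(
                    f"truncated or malformed FASTQ record near {h1.strip() or h2.strip()!r}")
            s1, q1, s2, q2 = s1.strip(), q1.strip(), s2.strip(), q2.strip()
            name = h1[1:].split()[0].rstrip("/1")
            if len(s1) != len(q1) or len(s2) != len(q2):
                raise MalformedFastqError(f"sequence/quality length mismatch in {name!r}")
            pairs.append(ReadPair(name, s1.upper(), q1, s2.upper(), q2))
    return pairs


def write_fastq_pairs(pairs: Iterable[ReadPair], r1_path, r2_path) -> None:
    with _open(r1_path, "wt") as f1, _open(r2_path, "wt") as f2:
        for p in pairs:
            f1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------- BED / TSV

def read_bed(path) -> list[tuple[str, int, int, str]]:
    """Read BED: (chrom, start, end, name) with 0-based half-open coords."""
    rows = []
    with _open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            rows.append((f[0], int(f[1]), int(f[2]), f[3] if len(f) > 3 else "."))
    return rows


def write_bed(path, rows: Iterable[Sequence]) -> None:
    with _open(path, "wt") as fh:
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def write_tsv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    with _open(path, "wt") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_tsv(path) -> list[dict[str, str]]:
    with _open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        return [dict(zip(header, line.rstrip("\n").split("\t"))) for line in fh if line.strip()]


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------- VCF

VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##contig=<ID={contig},length={length}>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def write_vcf(path, contig: str, contig_len: int, records, sample: str = "SAMPLE") -> None:
    """Write minimal VCF v4.2 with fixed columns and a GT field.

    ``records`` are (pos0, ref, alts, gt) with 0-based pos and alts a list.
    """
    with _open(path, "wt") as fh:
        fh.write(VCF_HEADER.format(contig=contig, length=contig_len, sample=sample))
        for pos0, ref, alts, gt in records:
            fh.write(f"{contig}\t{pos0 + 1}\t.\t{ref}\t{','.join(alts)}\t.\tPASS\t.\tGT\t{gt}\n")
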