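"""Best-matching-haplotype (BMH) assignment from HLA-DRB1 first-field
genotype and C4 status, plus a naive k-mer stand-in genotyper.

The BMH is the guide haplotype used as a proxy parental chromosome: DRB1
first-field allele groups map (through known DRB1/DRB3/DRB4/DRB5 linkage)
to a DR class, one guide is chosen per class, and a heterozygous individual
gets two guides, each driving a separate assembly pass. Recombinant
haplotypes are deliberately not modelled.

The naive genotyper is simplified plumbing — it counts reads carrying
k-mers unique to one allele group's exemplar sequences. It stands in for a
dedicated HLA typing tool in self-contained runs and is in no way suitable
for actual HLA genotyping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

from .core import ReadPair, revcomp

#: Default first-field allele-group -> DR class table. Ships as data so
#: users can override it with their own mapping.
DEFAULT_ALLELE_TABLE: dict[str, str] = {
    "01": "DR1", "10": "DR1",
    "15": "DR2", "16": "DR2",
    "03": "DR3", "11": "DR3", "12": "DR3", "13": "DR3", "14": "DR3",
    "04": "DR4", "07": "DR4", "09": "DR4",
    "08": "DR8",
}

#: Second allele group is called when its informative-read count reaches
#: this fraction of the top group's count.
HET_RATIO = 0.25


@dataclass
class DRGenotype:
    alleles: tuple[str, str]
    source: str = "provided"          # "provided" | "naive_caller"


@dataclass
class BMHAssignment:
    guide_ids: list[str]
    dr_classes: set[str]
    rationale: str = ""


class NoCallError(RuntimeError):
    """Raised when the naive genotyper sees zero informative reads; the
    pipeline then requires an explicit genotype input."""


def assign_dr_class(genotype: DRGenotype, table: Mapping[str, str] | None = None) -> set[str]:
    """Map both first-field allele groups to their DR classes."""
    table = table or DEFAULT_ALLELE_TABLE
    classes = set()
    for grp in genotype.alleles:
        if grp not in table:
            raise KeyError(f"allele group {grp!r} not present in the allele->class table")
        classes.add(table[grp])
    return classes


def _c4_match_score(guide_c4: tuple[int, int, int], c4_status) -> int:
    """Priority: exact copy-number match > long/short profile match > none."""
    if c4_status is None:
        return 0
    a, b, long_forms = c4_status
    if (guide_c4[0], guide_c4[1]) == (a, b):
        return 2
    if (guide_c4[2] > 0) == (long_forms > 0):
        return 1
    return 0


def assign_bmh(dr_classes: Iterable[str], c4_status, panel) -> BMHAssignment:
    """Choose one guide per DR class, preferring the best C4 match.

    ``c4_status`` is the individual's (c4a, c4b, long_forms) annotation or
    None. A heterozygous DR genotype yields two guides; downstream assembly
    runs once per guide.
    """
    by_class: dict[str, list] = {}
    for g in panel:
        by_class.setdefault(g.dr_class, []).append(g)
    guide_ids, notes = [], []
    for dr in sorted(set(dr_classes)):
        if dr not in by_class:
            raise KeyError(f"no guide with DR class {dr} in panel; "
                           f"available: {sorted(by_class)}")
        best = max(by_class[dr], key=lambda g: (_c4_match_score(g.c4_copies, c4_status), g.id))
        guide_ids.append(best.id)
        notes.append(f"{dr}->{best.id} (C4 score {_c4_match_score(best.c4_copies, c4_status)})")
    return BMHAssignment(guide_ids=guide_ids, dr_classes=set(dr_classes),
                         rationale="; ".join(notes))


def _unique_group_kmers(allele_panel: Mapping[str, str] | Iterable[tuple[str, str]],
                        k: int) -> dict[bytes, str]:
    """k-mer (canonical, both strands) -> allele group, dropping shared k-mers."""
    if isinstance(allele_panel, Mapping):
        items = list(allele_panel.items())
    else:
        items = list(allele_panel)
    owner: dict[bytes, str | None] = {}
    for name, seq in items:
        group = name.split("*")[0]
        for s in (seq, revcomp(seq)):
            b = s.encode("ascii")
            for i in range(len(b) - k + 1):
                km = b[i:i + k]
                prev = owner.get(km)
                if prev is None:
                    owner[km] = group
                elif prev != group:
                    owner[km] = ""
    return {km: grp for km, grp in owner.items() if grp}


def naive_drb1_genotype(pairs: list[ReadPair],
                        allele_panel: Mapping[str, str] | Iterable[tuple[str, str]],
                        k: int = 31) -> DRGenotype:
    """Call a DRB1 first-field genotype by unique-k-mer read counting.

    Per allele group, counts reads (mates) containing at least one k-mer
    unique to that group's exemplars; calls the top group, plus the second
    group when its count reaches 25% of the top (an invented heterozygosity
    threshold). Raises :class:`NoCallError` when no read is informative.
    """
    if not list(allele_panel):
        raise ValueError("allele_panel must be non-empty")
    kmers = _unique_group_kmers(allele_panel, k)
    counts: dict[str, int] = {}
    for p in pairs:
        for seq in (p.seq1, p.seq2):
            b = seq.encode("ascii")
            if len(b) < k:
                continue
            hit_groups = set()
            for i in range(len(b) - k + 1):
                grp = kmers.get(b[i:i + k])
                if grp:
                    hit_groups.add(grp)
            for grp in hit_groups:
                counts[grp] = counts.get(grp, 0) + 1
    if not counts:
        raise NoCallError("no informative reads; provide an explicit genotype")
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top_grp, top_n = ranked[0]
    if len(ranked) > 1 and ranked[1][1] >= HET_RATIO * top_n:
        alleles = tuple(sorted((top_grp, ranked[1][0])))
    else:
        alleles = (top_grp, top_grp)
    return DRGenotype(alleles=alleles, source="naive_caller")
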