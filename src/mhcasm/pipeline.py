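"""End-to-end per-individual driver: QC -> BMH assignment -> binning ->
per-superblock and unmapped-pool assembly -> cross-mapping filter ->
supercontig merge -> polish -> scaffold -> guide placement -> reports.

A heterozygous individual runs the whole assembly once per assigned guide
haplotype (BMH), producing one pseudo-haploid consensus each; a homozygous
individual produces a single consensus. Every stage is deterministic given
the configuration, so re-running a config reproduces byte-identical
sequence outputs.
"""

from __future__ import annotations

import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

from . import evaluate as ev
from .assemble import (build_debruijn, extract_contigs, filter_cross_mapping,
                       merge_supercontigs, simplify_graph)
from .binmap import Scoring, SeedIndex, bin_reads, build_superblocks
from .core import ReadPair
from .haplotype_assign import (DRGenotype, assign_bmh, assign_dr_class,
                               naive_drb1_genotype)
from .io import write_fasta, write_json, write_tsv, write_vcf
from .readqc import QCConfig, run_qc
from .scaffold import place_and_filter, polish_contigs, scaffold_paired
from .simulate import DiploidIndividual, GuideHaplotype

#: hg38 coordinates of the canonical MHC extraction region, for users
#: bringing their own alignments (chr6, 0-based half-open); alt contigs
#: carrying MHC sequence should be extracted alongside.
MHC_REGION_HG38 = ("chr6", 28_509_119, 33_481_577)

DEPTH_HARD_FLOOR = 25.0
DEPTH_SOFT_FLOOR = 30.0


@dataclass
class RunConfig:
    individual_id: str = "sample"
    k_mapped: int = 51
    k_unmapped: int = 51
    min_contig_len: int = 100
    superblock_span: int = 50_000
    superblock_overlap: int = 5_000
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    qc: QCConfig = field(default_factory=QCConfig)
    scoring: Scoring = field(default_factory=Scoring)
    seed: int = 0
    outdir: str | None = None

    def validate(self) -> None:
        for k in (self.k_mapped, self.k_unmapped):
            if k % 2 == 0:
                raise ValueError("assembly k-mer sizes must be odd")
        self.qc.validate()


@dataclass
class HaplotypeAssembly:
    guide_id: str
    assembly: "object"                 # OrientedAssembly
    contigs: list
    scaffolds: list
    stats: ev.AssemblyStats | None
    error_report: ev.ErrorReport | None = None
    het_attribution: tuple[float, float] | None = None
    variants: list | None = None


@dataclass
class RunResult:
    individual_id: str
    genotype: DRGenotype
    guide_ids: list[str]
    assemblies: dict[str, HaplotypeAssembly]
    merged_variants: list | None
    log: dict


def warn_low_depth(estimated_depth: float) -> str | None:
    """Depth advisory mirroring the method's published recommendations."""
    if estimated_depth < DEPTH_HARD_FLOOR:
        msg = (f"estimated depth {estimated_depth:.1f}x is below 25x: assemblies "
               "at this coverage are fragmented and rarely reach full length")
        warnings.warn(msg, stacklevel=2)
        return "hard"
    if estimated_depth < DEPTH_SOFT_FLOOR:
        msg = (f"estimated depth {estimated_depth:.1f}x is below the recommended "
               "30x; expect reduced contiguity")
        warnings.warn(msg, stacklevel=2)
        return "soft"
    return None


def _assemble_one_bmh(pairs: list[ReadPair], guide: GuideHaplotype,
                      alt_guide: GuideHaplotype | None, decoys, cfg: RunConfig,
                      log: dict) -> HaplotypeAssembly:
    stage: dict = {}
    index = SeedIndex({guide.id: guide.sequence})
    binres = bin_reads(pairs, index, cfg.scoring)
    stage["mapped_pairs"] = len(binres.mapped)
    stage["unmapped_pairs"] = len(binres.unmapped)

    sblocks = build_superblocks(binres.footprints(), cfg.superblock_span,
                                cfg.superblock_overlap)
    stage["superblocks"] = len(sblocks)
    by_id = {p.id: p for p in pairs}
    contigs = []
    for si, sb in enumerate(sblocks):
        reads = []
        for pid in sorted(sb.read_ids):
            p = by_id[pid]
            reads.append(p.seq1)
            reads.append(p.seq2)
        g = build_debruijn(reads, cfg.k_mapped)
        simplify_graph(g)
        contigs.extend(extract_contigs(g, cfg.min_contig_len, origin="mapped",
                                       superblock_id=f"sb{si:03d}",
                                       id_prefix=f"{guide.id}_sb{si:03d}"))
    un_reads = [s for p in binres.unmapped for s in (p.seq1, p.seq2)
                if len(s) >= cfg.k_unmapped]
    un_contigs = []
    if un_reads:
        g = build_debruijn(un_reads, cfg.k_unmapped)
        simplify_graph(g)
        un_contigs = extract_contigs(g, cfg.min_contig_len, origin="unmapped",
                                     id_prefix=f"{guide.id}_un")
    stage["unmapped_contigs_raw"] = len(un_contigs)
    un_contigs = filter_cross_mapping(
        un_contigs, alt_bmh=alt_guide.sequence if alt_guide else None, decoys=decoys)
    stage["unmapped_contigs_kept"] = len(un_contigs)

    all_contigs = contigs + un_contigs
    if not all_contigs:
        raise RuntimeError(f"stage assemble[{guide.id}]: no contigs produced "
                           f"(mapped pairs: {len(binres.mapped)})")
    merged = merge_supercontigs(all_contigs)
    stage["supercontigs"] = len(merged)
    stats = ev.assembly_stats(merged)
    stage["n50"] = stats.n50
    stage["total_contig_len"] = stats.total_len

    polished = polish_contigs(merged, pairs, scoring=cfg.scoring)
    scaffolds = scaffold_paired(polished, pairs, cfg.insert_mean, cfg.insert_sd,
                                scoring=cfg.scoring)
    stage["scaffolds"] = len(scaffolds)
    oriented = place_and_filter(scaffolds, index)
    stage["placed_scaffolds"] = len(oriented.placed)
    stage["unplaced_scaffolds"] = len(oriented.unplaced)
    stage["consensus_len"] = len(oriented.placed_consensus)
    log[f"bmh:{guide.id}"] = stage
    return HaplotypeAssembly(guide_id=guide.id, assembly=oriented, contigs=merged,
                             scaffolds=scaffolds, stats=stats)


def run_individual(pairs: list[ReadPair], panel: list[GuideHaplotype],
                   cfg: RunConfig | None = None, *,
                   genotype: DRGenotype | tuple[str, str] | None = None,
                   c4_status: tuple[int, int, int] | None = None,
                   allele_panel=None, decoys=None,
                   truth: DiploidIndividual | None = None,
                   truth_repeats: dict[str, list] | None = None,
                   variant_reference: str | None = None) -> RunResult:
    """Run the full per-individual workflow; one assembly pass per BMH.

    ``genotype`` may be provided (DRB1 first-field pair) or inferred by the
    naive k-mer genotyper from ``allele_panel``. With ``truth`` (a simulated
    individual) the result carries per-haplotype error reports; with
    ``variant_reference`` (a sequence id from the panel) per-haplotype
    variant calls are merged into one per-individual record set.
    """
    cfg = cfg or RunConfig()
    cfg.validate()
    t0 = time.time()
    log: dict = {"individual": cfg.individual_id}

    pairs, qc_stats = run_qc(pairs, cfg.qc)
    log["qc"] = qc_stats
    if not pairs:
        raise RuntimeError("stage qc: no read pairs survived quality control")

    if genotype is None:
        if allele_panel is None:
            raise ValueError("provide a genotype or an allele_panel for naive calling")
        genotype = naive_drb1_genotype(pairs, allele_panel)
    elif not isinstance(genotype, DRGenotype):
        genotype = DRGenotype(alleles=tuple(genotype), source="provided")
    log["genotype"] = {"alleles": list(genotype.alleles), "source": genotype.source}

    dr_classes = assign_dr_class(genotype)
    assignment = assign_bmh(dr_classes, c4_status, panel)
    log["bmh_assignment"] = {"guides": assignment.guide_ids,
                             "dr_classes": sorted(assignment.dr_classes),
                             "rationale": assignment.rationale}
    guides = {g.id: g for g in panel}

    total_bp = sum(p.total_bp for p in pairs)
    mean_guide_len = sum(guides[g].length for g in assignment.guide_ids) / len(
        assignment.guide_ids)
    est_depth = total_bp / mean_guide_len
    if truth is not None:
        est_depth = total_bp / ((len(truth.hap_a) + len(truth.hap_b)) / 2)
    log["estimated_depth"] = round(est_depth, 2)
    log["depth_warning"] = warn_low_depth(est_depth)

    assemblies: dict[str, HaplotypeAssembly] = {}
    for gid in assignment.guide_ids:
        alt_ids = [g for g in assignment.guide_ids if g != gid]
        alt_guide = guides[alt_ids[0]] if alt_ids else None
        assemblies[gid] = _assemble_one_bmh(pairs, guides[gid], alt_guide,
                                            decoys, cfg, log)

    if truth is not None:
        _evaluate_against_truth(assemblies, truth, truth_repeats, log)

    merged_variants = None
    if variant_reference is not None:
        ref_seq = guides[variant_reference].sequence
        per_hap = []
        for gid, ha in assemblies.items():
            recs = ev.call_variants_vs_reference(ha.assembly.placed_consensus, ref_seq)
            ha.variants = recs
            per_hap.append(recs)
        if len(per_hap) == 1:
            per_hap.append(per_hap[0])
        merged_variants = ev.merge_haplotype_variants(per_hap[0], per_hap[1])
        log["merged_variant_records"] = len(merged_variants)

    log["runtime_s"] = round(time.time() - t0, 1)
    result = RunResult(individual_id=cfg.individual_id, genotype=genotype,
                       guide_ids=assignment.guide_ids, assemblies=assemblies,
                       merged_variants=merged_variants, log=log)
    if cfg.outdir:
        _write_outputs(result, cfg, guides, variant_reference)
    return result


def _evaluate_against_truth(assemblies, truth: DiploidIndividual,
                            truth_repeats, log) -> None:
    hap_for_guide = {truth.source_guides[0]: "A", truth.source_guides[1]: "B"}
    haps = truth.haplotypes()
    for gid, ha in assemblies.items():
        hap = hap_for_guide.get(gid)
        if hap is None:
            continue
        truth_seq = haps[hap]
        other_seq = haps["B" if hap == "A" else "A"]
        chain = ev.anchor_align(ha.assembly.placed_consensus, truth_seq)
        bed = (truth_repeats or {}).get(gid)
        ha.error_report = ev.call_errors(chain, repeat_bed=bed)
        snps = [e for e in ha.error_report.events if e.type == "SNP"]
        ha.het_attribution = ev.attribute_het_switch(snps, truth_seq, other_seq)
        log[f"error:{gid}"] = {
            "base_call_error_pct": round(ha.error_report.base_call_error_pct, 4),
            "nonrepeat_sv_error_pct": round(ha.error_report.nonrepeat_sv_error_pct, 4),
            "repeat_sv_error_pct": round(ha.error_report.repeat_sv_error_pct, 4),
            "total_error_pct": round(ha.error_report.total_error_pct, 4),
            "true_error_fraction": round(ha.het_attribution[0], 3),
            "het_inclusion_fraction": round(ha.het_attribution[1], 3),
        }


def _write_outputs(result: RunResult, cfg: RunConfig, guides,
                   variant_reference) -> None:
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    for gid, ha in result.assemblies.items():
        recs = {f"{result.individual_id}_{gid}_consensus": ha.assembly.placed_consensus}
        for s in ha.assembly.unplaced:
            recs[f"{result.individual_id}_{gid}_unplaced_{s.id}"] = s.sequence
        write_fasta(out / f"{result.individual_id}.{gid}.fasta", recs)
        rows = []
        cursor = 1
        for s, sc in ha.assembly.placed:
            rows.append((f"{result.individual_id}_{gid}_consensus", cursor,
                         cursor + len(s.sequence) - 1, s.id, sc.assigned_strand,
                         f"{sc.location_score:.3f}", f"{sc.orientation_score:.3f}"))
            cursor += len(s.sequence)
        write_tsv(out / f"{result.individual_id}.{gid}.placements.tsv",
                  ("object", "start_1based", "end_1based", "scaffold", "strand",
                   "location_score", "orientation_score"), rows)
        if ha.error_report is not None:
            r = ha.error_report
            write_tsv(out / f"{result.individual_id}.{gid}.errors.tsv",
                      ("assembly_len", "base_call_error_pct", "nonrepeat_sv_error_pct",
                       "repeat_sv_error_pct", "total_error_pct"),
                      [(r.assembly_len, f"{r.base_call_error_pct:.4f}",
                        f"{r.nonrepeat_sv_error_pct:.4f}", f"{r.repeat_sv_error_pct:.4f}",
                        f"{r.total_error_pct:.4f}")])
    if result.merged_variants is not None and variant_reference is not None:
        write_vcf(out / f"{result.individual_id}.merged.vcf", variant_reference,
                  guides[variant_reference].length, result.merged_variants,
                  sample=result.individual_id)
    write_json(out / f"{result.individual_id}.log.json", result.log)
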