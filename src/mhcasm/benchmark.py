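"""The package's reference validation scenario: a scaled-down synthetic
diploid assembled end-to-end and scored against its truth haplotypes.

The scenario fixes the study conditions once: two 300 kb guide haplotypes
(DR3 and DR4, both with a single long-form C4 unit, interspersed repeats
at 20% density), a diploid individual at 0.5% SNP divergence per haplotype
from its guides, and 150 bp paired-end reads at 30x per-haplotype coverage
with 0.1% base-call error. The full pipeline runs once per assigned BMH
and each consensus is compared with its truth haplotype.

Multi-copy and heterozygous-form C4 configurations are deliberately
excluded from this scenario: collapsing near-identical tandem C4 units
(and resolving a 1 kb long/short structural het) are known limitations of
short-read assembly, and at 300 kb a single such event would dominate
every error statistic with one absolute, length-independent artifact. The
scenario therefore isolates the rate-driven error sources (SNP/indel
divergence, read error, interspersed repeats); C4-aware BMH matching and
copy-number handling are exercised separately in the unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

from .pipeline import RunConfig, RunResult, run_individual
from .readqc import QCConfig
from .simulate import (DiploidIndividual, GuideHaplotype, ReadSimConfig,
                       generate_guide_panel, simulate_individual, simulate_reads,
                       truth_repeat_bed)


@dataclass
class BenchmarkConfig:
    base_len: int = 300_000
    dr_mix: tuple[str, str] = ("DR3", "DR4")
    c4_mix: tuple = ((1, 0, 1), (1, 0, 1))
    repeat_density: float = 0.2
    divergence: float = 0.005
    indel_rate: float = 5e-4
    depth: float = 30.0
    read_len: int = 150
    base_error: float = 0.001
    seed: int = 1


@dataclass
class BenchmarkResult:
    panel: list[GuideHaplotype]
    individual: DiploidIndividual
    run: RunResult
    truth_beds: dict[str, list]

    def error_reports(self):
        return {gid: ha.error_report for gid, ha in self.run.assemblies.items()
                if ha.error_report is not None}

    def mean(self, attr: str) -> float:
        reports = list(self.error_reports().values())
        return sum(getattr(r, attr) for r in reports) / len(reports)


def run_diploid_benchmark(seed: int = 1, cfg: BenchmarkConfig | None = None
                          ) -> BenchmarkResult:
    """Simulate the scenario and run the full pipeline per BMH."""
    cfg = cfg or BenchmarkConfig(seed=seed)
    cfg.seed = seed
    panel = generate_guide_panel(
        n=len(cfg.dr_mix), base_len=cfg.base_len, dr_mix=list(cfg.dr_mix),
        repeat_density=cfg.repeat_density, seed=cfg.seed, c4_mix=list(cfg.c4_mix))
    ind = simulate_individual(panel, (panel[0].id, panel[1].id),
                              divergence=cfg.divergence, indel_rate=cfg.indel_rate,
                              seed=cfg.seed, ind_id=f"bench{cfg.seed}")
    pairs = simulate_reads(ind, ReadSimConfig(
        depth=cfg.depth, read_len=cfg.read_len, base_error=cfg.base_error,
        seed=cfg.seed))
    beds = {g.id: truth_repeat_bed(g, ind, h) for g, h in zip(panel, "AB")}
    run_cfg = RunConfig(individual_id=ind.id, qc=QCConfig(seed=cfg.seed),
                        seed=cfg.seed)
    run = run_individual(pairs, panel, run_cfg, genotype=ind.drb1_genotype,
                         c4_status=panel[0].c4_copies, truth=ind,
                         truth_repeats=beds)
    return BenchmarkResult(panel=panel, individual=ind, run=run, truth_beds=beds)
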