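#!/usr/bin/env python
"""Generate the synthetic six-cow MeDIP cohort used by the downstream analyses.

Writes the genome FASTA, gene models (GTF), per-cow depth tracks (bedGraph),
the cohort design, the read-covered intervals, and the planted-feature truth
files under results/data/.
"""

from pathlib import Path

from medipgmr.synthetic_data import SimulationConfig, simulate_cohort, write_cohort_dir

OUT = Path(__file__).resolve().parents[1] / "results" / "data"


def main() -> None:
    config = SimulationConfig(seed=3)
    sim = simulate_cohort(config)
    write_cohort_dir(sim, OUT)
    n_dmr = len(sim.truth.dmrs)
    n_pmd = len(sim.truth.pmds)
    print(f"cohort: {len(sim.design.cows)} cows, {config.n_chroms} x "
          f"{config.chrom_length:,} bp chromosomes, {len(sim.genes)} genes")
    print(f"planted: {n_dmr} DMRs "
          f"({sum(d.kind == 'case_control' for d in sim.truth.dmrs)} case-control, "
          f"{sum(d.kind == 'environmental' for d in sim.truth.dmrs)} environmental), "
          f"{n_pmd} PMDs")
    print(f"covered intervals: {len(sim.intervals)} spanning "
          f"{sim.intervals.total_bp():,} bp "
          f"({sim.intervals.total_bp() / (config.n_chroms * config.chrom_length):.1%} "
          f"of the genome)")
    print(f"written to {OUT}")


if __name__ == "__main__":
    main()
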