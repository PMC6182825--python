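#!/usr/bin/env python
"""Genome-wide methylation description: windowed mean GMR, chromosome-end
comparisons, CpG-context sequencing coverage, CpG islands, and the
gene-density correlation.

Reads the cohort from results/data/ and writes tables under results/stats/.
"""

from pathlib import Path

from medipgmr import methylation_stats as ms
from medipgmr.io_formats import (
    MethylatedIntervalSet,
    read_cohort_design,
    read_depth_track,
    read_fasta,
    read_gene_models,
    stack_tracks,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "stats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    genome = read_fasta(DATA / "genome.fa")
    sizes = {c: len(s) for c, s in genome.items()}
    design = read_cohort_design(DATA / "design.tsv")
    genes = read_gene_models(DATA / "genes.gtf", sizes)
    tracks = []
    for cow in design.cow_ids:
        tracks += read_depth_track(DATA / f"{cow}.bedgraph", sizes, cow_id=cow)

    gmr = {}
    for chrom in sizes:
        _, matrix = stack_tracks(tracks, chrom, design.cow_ids)
        gmr[chrom] = ms.gmr_track(matrix)

    windows = ms.windows_for_cohort(gmr, 10_000)
    windows.to_csv(OUT / "windows_10kb.tsv", sep="\t", index=False)
    print(f"mean GMR over 10-kb windows: genome mean "
          f"{windows['mean_gmr'].mean():.3f}")

    seg = ms.chromosome_segment_stats(windows, sizes, end_width=500_000)
    seg.summary.to_csv(OUT / "segment_summary.tsv", sep="\t", index=False)
    seg.location_tests.to_csv(OUT / "segment_location_tests.tsv", sep="\t",
                              index=False)
    seg.variance_tests.to_csv(OUT / "segment_variance_tests.tsv", sep="\t",
                              index=False)
    for row in seg.summary.itertuples():
        print(f"  {row.segment:12s} mean {row.mean:.3f} +- {row.sd:.3f} (n={row.n})")

    cov = ms.cpg_site_coverage(tracks, genome)
    cov.to_csv(OUT / "cpg_coverage.tsv", sep="\t", index=False)
    for row in cov.itertuples():
        print(f"CpG sites sequenced at depth >= {row.threshold}: "
              f"{row.site_fraction:.1%} (genome-wide {row.genome_fraction:.1%})")

    islands = []
    for chrom, seq in genome.items():
        islands += [(chrom, s, e) for s, e in ms.find_cpg_islands(seq)]
    iv = MethylatedIntervalSet.from_records(islands, label="CpG_island")
    iv.write_bed(OUT / "cpg_islands.bed")
    print(f"CpG islands: {len(iv)} covering {iv.total_bp():,} bp")

    windows_1mb = ms.windows_for_cohort(gmr, 100_000)
    rho, p, counted = ms.gene_density_correlation(windows_1mb, genes)
    counted.to_csv(OUT / "gene_density_windows.tsv", sep="\t", index=False)
    print(f"Spearman correlation of window mean GMR with gene count: "
          f"rho = {rho:.2f} (P = {p:.2g})")


if __name__ == "__main__":
    main()
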