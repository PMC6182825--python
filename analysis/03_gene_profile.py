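#!/usr/bin/env python
"""Length-standardized metagene profile and the upstream methylation nadir.

Reads the cohort from results/data/ and writes the profile table under
results/profile/.
"""

from pathlib import Path

from medipgmr import methylation_stats as ms
from medipgmr.gene_profile import element_medians, find_tss_nadir, profile_gene_set
from medipgmr.io_formats import (
    read_cohort_design,
    read_depth_track,
    read_fasta,
    read_gene_models,
    stack_tracks,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "data"
OUT = ROOT / "results" / "profile"


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

    medians = element_medians(genes)
    print("standardized element lengths (bp):",
          ", ".join(f"{k} {v}" for k, v in medians.items()))
    profile = profile_gene_set(gmr, genes, flank=1000, medians=medians)
    profile.to_csv(OUT / "profile.tsv", sep="\t", index=False)

    nadir = find_tss_nadir(profile)
    print(f"profiled {len(genes)} genes; upstream methylation nadir "
          f"{nadir} bp before the TSS")
    by_el = profile.groupby("element")["mean_gmr"].mean()
    for el in ("upstream", "exon_first", "exon_middle", "exon_last",
               "intron_first", "intron_last", "downstream"):
        print(f"  {el:13s} mean GMR {by_el[el]:.3f}")


if __name__ == "__main__":
    main()
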