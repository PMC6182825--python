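"""Synthetic MeDIP-seq cohort generator.

Generates a complete toy study — genome with CpG-dense patches, gene models,
per-cow per-nucleotide depth tracks, planted differentially methylated
regions (DMR) and partially methylated domains (PMD), and truth files — so
every analysis stage is testable without external data.

Depth model.  Per-nucleotide depth for cow c is negative binomial with mean

    mu_c(x) = baseline * lib_scale_c * cow_bias_c(x) * region_effect(x)
              * cpg_factor(x) * dip(x) * pmd_suppression(x) * dmr_fold_c(x)

The region effect is log-normal, piecewise constant over ~1-kb blocks and
shared across cows: it is this shared enrichment structure that makes the
case/control ratio of standardized reads concentrate tightly around 1 under
the null, as observed in real MeDIP cohorts.  The per-cow bias term (also
log-normal, over coarser blocks) models animal-specific local
immunoprecipitation and library-construction bias; it is what spreads the
null ratio away from exactly 1.  The negative binomial supplies the
overdispersion (variance > mean) characteristic of MeDIP depth, the CpG
factor links enrichment to local CpG density, the promoter dip reproduces
the depth minimum just upstream of TSSs, and per-cow library scales emulate
unequal sequencing depth.  A fraction of intergenic blocks is "unmappable"
(depth exactly 0 for every cow), emulating repeat-dense sequence that
yields no uniquely mapped reads and giving the genome zero-coverage gaps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    CohortDesign,
    DepthTrack,
    GeneModel,
    MethylatedIntervalSet,
    write_cohort_design,
    write_depth_track,
    write_fasta,
    write_gene_models_gtf,
)
from .region_dmr import covered_intervals

__all__ = [
    "SimulationConfig",
    "PlantedDmr",
    "PlantedPmd",
    "TruthSet",
    "SimResult",
    "generate_genome",
    "simulate_depths",
    "simulate_cohort",
    "write_truth",
    "read_truth",
    "write_cohort_dir",
]

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class PlantedDmr:
    chrom: str
    start: int
    end: int
    fold: float
    kind: str                      # case_control | environmental
    affected_cows: tuple[str, ...]


@dataclass(frozen=True)
class PlantedPmd:
    chrom: str
    start: int
    end: int
    suppression: float


@dataclass
class TruthSet:
    dmrs: list[PlantedDmr] = field(default_factory=list)
    pmds: list[PlantedPmd] = field(default_factory=list)
    library_scales: dict[str, float] = field(default_factory=dict)


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic cohort.

    Defaults give a 3-chromosome x 6-Mb toy genome with 150 genes, eight
    planted 4-fold case-control DMRs, four farm-specific DMRs, and two
    400-kb PMDs — small enough for minutes-scale runs while leaving every
    stage nontrivial.  ``baseline_mean`` (reads per nucleotide per cow,
    before enrichment), ``region_effect_sd`` (SD of the shared log-normal
    enrichment, natural-log scale) and ``cow_effect_sd`` were chosen so that
    region read totals are well away from the noise floor and the
    case-control null SD lands near the ~0.02 level seen in real MeDIP
    cohorts (see docs/methods.md for the reasoning).
    """

    seed: int = 0
    n_chroms: int = 3
    chrom_length: int = 6_000_000
    n_genes: int = 150
    design: CohortDesign = field(default_factory=CohortDesign.six_cow_default)
    # depth model
    baseline_mean: float = 0.80
    dispersion: float = 0.5        # NB size; variance = m + m^2/size
    region_effect_sd: float = 0.9  # ln-scale SD of shared block enrichment
    region_effect_clip: float = 2.0  # clip of the block effect, in SD units
    region_block: int = 1000
    zero_fraction: float = 0.15    # genome fraction in unmappable blocks
    zero_block_len: int = 3000
    cpg_effect: float = 0.4        # ln-mean shift per SD of block CpG density
    cow_effect_sd: float = 0.31    # ln-scale SD of per-cow local enrichment bias
    cow_effect_clip: float = 3.0   # clip of the per-cow bias, in SD units
    cow_block: int = 6000          # block width of the per-cow bias
    lib_scale_range: tuple[float, float] = (0.7, 1.3)
    # promoter dip
    promoter_dip: bool = True
    dip_depth: float = 0.75        # fractional depth reduction at the dip centre
    dip_offset: int = 95           # bp upstream of the TSS
    dip_width: float = 150.0       # gaussian SD in bp
    # planted features (auto-placed when the explicit lists are empty)
    n_case_dmrs: int = 8
    n_env_dmrs: int = 4
    env_dmr_farm: str = "farm1"
    dmr_fold: float = 4.0
    dmr_length: int = 2000
    dmr_region_boost: float = 0.5  # ln-scale shared enrichment inside planted DMRs
    n_pmds: int = 2
    pmd_length: int = 400_000
    pmd_suppression: float = 0.1   # fraction of normal coverage retained in a PMD
    dmrs: list[PlantedDmr] = field(default_factory=list)
    pmds: list[PlantedPmd] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.baseline_mean <= 0 or self.dispersion <= 0:
            raise ValueError("rates must be positive")
        if self.dmr_fold <= 0 or self.pmd_suppression <= 0:
            raise ValueError("folds must be positive")

    def chrom_sizes(self) -> dict[str, int]:
        return {f"chr{i + 1}": self.chrom_length for i in range(self.n_chroms)}

    def null_variant(self) -> "SimulationConfig":
        """Same conditions with no planted signal (for null calibration)."""
        return dataclasses.replace(
            self, n_case_dmrs=0, n_env_dmrs=0, n_pmds=0, dmrs=[], pmds=[]
        )


@dataclass
class SimResult:
    config: SimulationConfig
    genome: dict[str, str]
    genes: list[GeneModel]
    design: CohortDesign
    tracks: list[DepthTrack]
    intervals: MethylatedIntervalSet
    truth: TruthSet


# ---------------------------------------------------------------------------
# genome and gene models
# ---------------------------------------------------------------------------

def _random_sequence(rng: np.random.Generator, n: int,
                     p: Sequence[float] = (0.29, 0.21, 0.21, 0.29)) -> np.ndarray:
    return rng.choice(BASES, size=n, p=np.asarray(p))


def _cpg_rich_sequence(rng: np.random.Generator, n: int,
                       cg_pair_prob: float = 0.25) -> np.ndarray:
    """GC-rich sequence with explicit CpG dinucleotides (island-like)."""
    out = np.empty(n, dtype=np.uint8)
    i = 0
    pairs = rng.random(n) < cg_pair_prob
    singles = rng.choice(BASES, size=n, p=np.array([0.2, 0.3, 0.3, 0.2]))
    j = 0
    while i < n:
        if pairs[j] and i + 1 < n:
            out[i] = ord("C")
            out[i + 1] = ord("G")
            i += 2
        else:
            out[i] = singles[j]
            i += 1
        j += 1
    return out


def _sample_gene_structure(rng: np.random.Generator) -> tuple[list[int], list[int]]:
    """(exon lengths, intron lengths) for one gene, transcriptional order."""
    n_exons = int(rng.integers(3, 9))
    exon_lens = np.clip(
        rng.lognormal(np.log(150), 0.6, size=n_exons), 30, 2000
    ).astype(int)
    intron_lens = np.clip(
        rng.lognormal(np.log(800), 0.7, size=n_exons - 1), 60, 5000
    ).astype(int)
    return list(exon_lens), list(intron_lens)


def generate_genome(config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[dict[str, str], list[GeneModel]]:
    """Random genome with CpG-dense patches plus placed gene models.

    Genes have 3-8 exons with log-normal length spread (so median-based
    standardization is nontrivial) on both strands; each promoter and a set
    of random background patches are CpG-enriched to exercise density-linked
    depth and island detection.  Raises when the requested genes cannot be
    placed without overlap.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.chrom_sizes()
    chroms = list(sizes)
    seq = {c: _random_sequence(rng, n) for c, n in sizes.items()}

    genes: list[GeneModel] = []
    per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        per_chrom[i] += 1
    margin = 2000
    min_gap = 2500
    for chrom, n_here in zip(chroms, per_chrom):
        structures = [_sample_gene_structure(rng) for _ in range(n_here)]
        total = sum(sum(e) + sum(i) for e, i in structures)
        # spread genes across the whole chromosome: random extra gaps on top
        # of a minimum spacing that keeps 1-kb flanks from overlapping
        leftover = sizes[chrom] - 2 * margin - total - min_gap * n_here
        if leftover <= 0:
            raise ValueError(
                f"cannot place {n_here} genes on {chrom}: ran out of space"
            )
        extra = np.diff(np.concatenate(
            ([0.0], np.sort(rng.uniform(0, leftover, size=max(0, n_here - 1))),
             [float(leftover)])))
        pos = margin
        for k in range(n_here):
            exon_lens, intron_lens = structures[k]
            start = pos + min_gap + int(extra[k])
            strand = "+" if rng.random() < 0.5 else "-"
            # build exons in genomic order; element order is strand-dependent
            if strand == "-":
                exon_lens = exon_lens[::-1]
                intron_lens = intron_lens[::-1]
            exons = []
            p = start
            for j, el in enumerate(exon_lens):
                exons.append((p, p + el))
                p += el
                if j < len(intron_lens):
                    p += intron_lens[j]
            gid = f"gene_{chrom}_{k + 1:03d}"
            genes.append(GeneModel(gid, chrom, strand, exons))
            pos = p

    # CpG-dense patches: promoters plus random background patches
    for g in genes:
        centre = g.tss
        s = max(0, centre - 500)
        e = min(sizes[g.chrom], centre + 500)
        seq[g.chrom][s:e] = _cpg_rich_sequence(rng, e - s)
    for chrom in chroms:
        for _ in range(max(1, config.n_genes // (3 * config.n_chroms))):
            plen = int(rng.integers(300, 800))
            s = int(rng.integers(0, sizes[chrom] - plen))
            seq[chrom][s:s + plen] = _cpg_rich_sequence(rng, plen)

    genome = {c: arr.tobytes().decode("ascii") for c, arr in seq.items()}
    return genome, genes


# ---------------------------------------------------------------------------
# planted features
# ---------------------------------------------------------------------------

def _place_features(config: SimulationConfig, rng: np.random.Generator
                    ) -> tuple[list[PlantedDmr], list[PlantedPmd]]:
    if config.dmrs or config.pmds:
        return list(config.dmrs), list(config.pmds)
    sizes = config.chrom_sizes()
    chroms = list(sizes)
    pmds: list[PlantedPmd] = []
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for i in range(config.n_pmds):
        chrom = chroms[i % len(chroms)]
        margin = min(100_000, max(0, sizes[chrom] - config.pmd_length) // 3)
        lo, hi = margin, sizes[chrom] - config.pmd_length - margin
        if hi <= lo:
            raise ValueError(
                f"{chrom} too short for a {config.pmd_length} bp planted PMD")
        for _ in range(200):
            s = int(rng.integers(lo, hi) // 10_000 * 10_000)
            e = s + config.pmd_length
            if all(e <= a or s >= b for a, b in occupied[chrom]):
                occupied[chrom].append((s, e))
                pmds.append(PlantedPmd(chrom, s, e, config.pmd_suppression))
                break
        else:
            raise ValueError("could not place planted PMDs without overlap")

    design = config.design
    case_cows = tuple(
        design.pair_for_farm(f)[0] for f in design.case_control_farms()
    )
    env_cows = tuple(
        m.cow_id for m in design.by_farm()[config.env_dmr_farm]
    ) if config.n_env_dmrs else ()
    dmrs: list[PlantedDmr] = []
    specs = [("case_control", case_cows)] * config.n_case_dmrs + \
            [("environmental", env_cows)] * config.n_env_dmrs
    for i, (kind, cows) in enumerate(specs):
        chrom = chroms[i % len(chroms)]
        for _ in range(500):
            s = int(rng.integers(10_000, sizes[chrom] - config.dmr_length - 10_000))
            e = s + config.dmr_length
            clear = all(e + 5000 <= a or s - 5000 >= b for a, b in occupied[chrom])
            if clear:
                occupied[chrom].append((s, e))
                dmrs.append(PlantedDmr(chrom, s, e, config.dmr_fold, kind, cows))
                break
        else:
            raise ValueError("could not place planted DMRs without overlap")
    return dmrs, pmds


# ---------------------------------------------------------------------------
# depth simulation
# ---------------------------------------------------------------------------

def _block_cpg_density(seq: str, block: int) -> np.ndarray:
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_cg = np.zeros(len(arr), dtype=np.int64)
    is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))
    n_blocks = int(np.ceil(len(arr) / block))
    pad = n_blocks * block - len(arr)
    padded = np.concatenate((is_cg, np.zeros(pad, dtype=np.int64)))
    return padded.reshape(n_blocks, block).sum(axis=1) / block


def simulate_depths(genome: dict[str, str], genes: Sequence[GeneModel],
                    config: SimulationConfig,
                    rng: np.random.Generator | None = None
                    ) -> tuple[list[DepthTrack], MethylatedIntervalSet, TruthSet]:
    """Negative-binomial depth tracks with planted DMRs/PMDs and truth files."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sizes = config.chrom_sizes()
    dmrs, pmds = _place_features(config, rng)
    design = config.design
    cow_ids = design.cow_ids
    lo, hi = config.lib_scale_range
    lib = {c: float(rng.uniform(lo, hi)) for c in cow_ids}
    truth = TruthSet(dmrs=dmrs, pmds=pmds, library_scales=lib)

    tracks: list[DepthTrack] = []
    for chrom, n in sizes.items():
        n_blocks = int(np.ceil(n / config.region_block))
        clip = config.region_effect_clip * config.region_effect_sd
        block_eff = np.clip(rng.normal(0.0, config.region_effect_sd, size=n_blocks),
                            -clip, clip)
        dens = _block_cpg_density(genome[chrom], config.region_block)
        z = (dens - dens.mean()) / (dens.std() or 1.0)
        block_ln = block_eff + config.cpg_effect * np.clip(z, -3, 3)
        # shared enrichment inside planted DMRs is pinned to a modest fixed
        # level so planted loci are read-covered like typical detected regions
        ln_shared = np.repeat(block_ln, config.region_block)[:n]
        for d in dmrs:
            if d.chrom == chrom:
                ln_shared[d.start:d.end] = config.dmr_region_boost
        shared = config.baseline_mean * np.exp(ln_shared)
        # short unmappable margins around each planted DMR delineate it as
        # its own read-covered region (the unit the caller tests), so the
        # planted fold is not diluted across region-chunk boundaries
        for d in dmrs:
            if d.chrom == chrom:
                shared[max(0, d.start - 300):d.start] = 0.0
                shared[d.end:min(n, d.end + 300)] = 0.0

        if config.promoter_dip:
            dip = np.ones(n)
            for g in genes:
                if g.chrom != chrom:
                    continue
                if g.strand == "+":
                    s, e = max(0, g.tss - 1000), min(n, g.tss + 200)
                    d_up = g.tss - np.arange(s, e)
                else:
                    s, e = max(0, g.tss - 200), min(n, g.tss + 1000)
                    d_up = np.arange(s, e) - g.tss
                dip[s:e] *= 1.0 - config.dip_depth * np.exp(
                    -0.5 * ((d_up - config.dip_offset) / config.dip_width) ** 2
                )
            shared = shared * dip

        # PMD = suppressed coverage: most enrichment blocks inside the
        # domain are silenced, a fraction ~suppression keeps its normal
        # level (sparse methylated patches, the "partial" in PMD)
        for p in pmds:
            if p.chrom == chrom:
                n_pblocks = int(np.ceil((p.end - p.start) / config.region_block))
                keep = rng.random(n_pblocks) < p.suppression
                factor = np.where(keep, 1.0, 1e-4)
                shared[p.start:p.end] *= np.repeat(
                    factor, config.region_block)[: p.end - p.start]

        # unmappable blocks: zero depth for every cow, kept clear of genes
        # and planted DMRs so annotation-level signals stay intact
        if config.zero_fraction > 0:
            exclude = [(max(0, g.start - 1500), min(n, g.end + 1500))
                       for g in genes if g.chrom == chrom]
            exclude += [(max(0, d.start - 500), min(n, d.end + 500))
                        for d in dmrs if d.chrom == chrom]
            placed: list[tuple[int, int]] = []
            n_target = int(config.zero_fraction * n / config.zero_block_len)
            attempts = 0
            while len(placed) < n_target and attempts < 50 * n_target:
                attempts += 1
                s = int(rng.integers(0, n - config.zero_block_len))
                e = s + config.zero_block_len
                if any(s < b and e > a for a, b in exclude):
                    continue
                # keep zero blocks >=5 kb apart: back-to-back blocks would
                # leave sliver regions with too few reads to standardize
                if any(s < b + 5000 and e > a - 5000 for a, b in placed):
                    continue
                placed.append((s, e))
            for s, e in placed:
                shared[s:e] = 0.0

        for cow in cow_ids:
            # cow-specific local IP/library bias, piecewise over coarse blocks
            n_cblocks = int(np.ceil(n / config.cow_block))
            cclip = config.cow_effect_clip * config.cow_effect_sd
            cow_bias = np.repeat(
                np.exp(np.clip(rng.normal(0.0, config.cow_effect_sd, size=n_cblocks),
                               -cclip, cclip)),
                config.cow_block)[:n]
            mean = shared * lib[cow] * cow_bias
            for d in dmrs:
                if d.chrom == chrom and cow in d.affected_cows:
                    mean[d.start:d.end] *= d.fold
            mean = np.minimum(mean, 1e4)  # overflow guard
            r = config.dispersion
            depth = rng.negative_binomial(r, r / (r + mean))
            tracks.append(DepthTrack(cow, chrom, depth.astype(np.int64)))

    intervals = covered_intervals(tracks)
    return tracks, intervals, truth


def simulate_cohort(config: SimulationConfig) -> SimResult:
    """Generate genome, genes, depth tracks, covered intervals, and truth.

    All randomness flows from ``config.seed``; a fixed seed gives
    byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    genome, genes = generate_genome(config, rng)
    tracks, intervals, truth = simulate_depths(genome, genes, config, rng)
    return SimResult(config, genome, genes, config.design, tracks, intervals, truth)


# ---------------------------------------------------------------------------
# truth I/O
# ---------------------------------------------------------------------------

def write_truth(truth: TruthSet, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [(d.chrom, d.start, d.end, d.kind, d.fold, ",".join(d.affected_cows))
         for d in truth.dmrs],
        columns=["chrom", "start", "end", "kind", "fold", "affected_cows"],
    ).to_csv(out / "truth_dmrs.tsv", sep="\t", index=False)
    pd.DataFrame(
        [(p.chrom, p.start, p.end, p.suppression) for p in truth.pmds],
        columns=["chrom", "start", "end", "suppression"],
    ).to_csv(out / "truth_pmds.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(truth.library_scales.items()), columns=["cow_id", "scale"]
    ).to_csv(out / "truth_library_scales.tsv", sep="\t", index=False)


def read_truth(out_dir: str | Path) -> TruthSet:
    out = Path(out_dir)
    dmr_df = pd.read_csv(out / "truth_dmrs.tsv", sep="\t",
                         keep_default_na=False, dtype={"affected_cows": str})
    pmd_df = pd.read_csv(out / "truth_pmds.tsv", sep="\t")
    lib_df = pd.read_csv(out / "truth_library_scales.tsv", sep="\t")
    dmrs = [
        PlantedDmr(r.chrom, int(r.start), int(r.end), float(r.fold), r.kind,
                   tuple(x for x in str(r.affected_cows).split(",") if x))
        for r in dmr_df.itertuples()
    ]
    pmds = [PlantedPmd(r.chrom, int(r.start), int(r.end), float(r.suppression))
            for r in pmd_df.itertuples()]
    lib = {r.cow_id: float(r.scale) for r in lib_df.itertuples()}
    return TruthSet(dmrs=dmrs, pmds=pmds, library_scales=lib)


def write_cohort_dir(sim: SimResult, out_dir: str | Path) -> None:
    """Write FASTA, GTF, per-cow bedGraph, design, intervals, and truth files."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(sim.genome, out / "genome.fa")
    write_gene_models_gtf(sim.genes, out / "genes.gtf")
    write_cohort_design(sim.design, out / "design.tsv")
    sim.intervals.write_bed(out / "covered_regions.bed")
    for cow in sim.design.cow_ids:
        cow_tracks = [t for t in sim.tracks if t.cow_id == cow]
        write_depth_track(cow_tracks, out / f"{cow}.bedgraph")
    write_truth(sim.truth, out / "truth")
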