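"""Geometric-mean-reads (GMR) statistics and genome-wide descriptive summaries.

MeDIP-seq depth is skewed across animals and across the genome, so a plain
mean of per-nucleotide read counts is dominated by a few heavily enriched
positions or animals.  The GMR statistic summarises depth across a cohort of
n animals at one nucleotide as

    GMR = exp( mean_i ln(NR_i + 1) - ln(2)/n )

where NR_i is animal i's read count at that nucleotide.  The +1 makes the
log defined at zero and the -ln(2)/n correction removes it at the anchor
point: a single read in a single animal gives GMR exactly 1.  GMR is defined
as exactly 0 when no animal has any reads.

This module also provides windowed mean-GMR summaries, chromosome-end
comparisons, the gene-density correlation, CpG-context sequencing coverage,
and CpG-island detection.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import DepthTrack, GeneModel, pooled_depth

__all__ = [
    "compute_gmr",
    "gmr_track",
    "normalized_reads_count",
    "window_mean_gmr",
    "chromosome_segment_stats",
    "SegmentComparison",
    "gene_density_correlation",
    "cpg_site_coverage",
    "find_cpg_islands",
]

LN2 = np.log(2.0)


def compute_gmr(nr: Sequence[float] | np.ndarray, n_cows: int | None = None) -> float:
    """GMR at a single nucleotide from a vector of per-cow read counts.

    Returns ``exp(mean(ln(nr + 1)) - ln(2)/n)`` with n the number of cows,
    and exactly 0.0 when every cow has zero reads.
    """
    nr = np.asarray(nr, dtype=float)
    if nr.size == 0:
        raise ValueError("empty read-count vector")
    if np.any(nr < 0):
        raise ValueError("read counts must be non-negative")
    n = int(n_cows) if n_cows is not None else nr.size
    if n != nr.size:
        raise ValueError(f"n_cows={n} does not match vector length {nr.size}")
    if not np.any(nr > 0):
        return 0.0
    return float(np.exp(np.mean(np.log1p(nr)) - LN2 / n))


def gmr_track(depth_matrix: np.ndarray) -> np.ndarray:
    """Vectorised GMR along a chromosome.

    Parameters
    ----------
    depth_matrix
        (n_cows, length) integer read counts.

    Returns
    -------
    Length-long float vector; exactly 0 where all cows have zero reads.
    """
    depth_matrix = np.asarray(depth_matrix)
    if depth_matrix.ndim != 2:
        raise ValueError("expected an (n_cows, length) matrix")
    if np.any(depth_matrix < 0):
        raise ValueError("read counts must be non-negative")
    n = depth_matrix.shape[0]
    values = np.exp(np.mean(np.log1p(depth_matrix), axis=0) - LN2 / n)
    values[~np.any(depth_matrix > 0, axis=0)] = 0.0
    return values


def normalized_reads_count(rc: float, urc: float) -> float:
    """Reads in a region per million uniquely mapped reads: RC * 1e6 / URC."""
    if rc < 0:
        raise ValueError("region read count must be non-negative")
    if urc <= 0:
        raise ValueError("total uniquely mapped reads must be positive")
    return rc * 1_000_000.0 / urc


def window_mean_gmr(track: np.ndarray, chrom: str, width: int) -> pd.DataFrame:
    """Mean GMR in non-overlapping fixed-width windows along one chromosome.

    The terminal partial window is averaged over its actual length.  Returns
    a frame with columns chrom, start, end, mean_gmr.
    """
    if width < 1:
        raise ValueError("window width must be >= 1")
    track = np.asarray(track, dtype=float)
    n = len(track)
    starts = np.arange(0, n, width)
    ends = np.minimum(starts + width, n)
    cs = np.concatenate(([0.0], np.cumsum(track)))
    means = (cs[ends] - cs[starts]) / (ends - starts)
    return pd.DataFrame(
        {"chrom": chrom, "start": starts, "end": ends, "mean_gmr": means}
    )


def windows_for_cohort(tracks_by_chrom: Mapping[str, np.ndarray],
                       width: int) -> pd.DataFrame:
    """window_mean_gmr applied across chromosomes of a GMR track set."""
    frames = [window_mean_gmr(v, chrom, width) for chrom, v in tracks_by_chrom.items()]
    return pd.concat(frames, ignore_index=True)


@dataclass
class SegmentComparison:
    """Pooled centromeric / middle / distal window statistics and tests."""

    summary: pd.DataFrame    # segment, mean, sd, n
    location_tests: pd.DataFrame   # segment_a, segment_b, t, p (Welch)
    variance_tests: pd.DataFrame   # segment_a, segment_b, F, p (folded F)


def _folded_f_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided folded-F test of variance homogeneity."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    p = min(1.0, 2.0 * stats.f.sf(f, dfn, dfd))
    return float(f), float(p)


def chromosome_segment_stats(windows: pd.DataFrame,
                             chrom_sizes: Mapping[str, int],
                             end_width: int = 500_000) -> SegmentComparison:
    """Compare window mean GMR between chromosome ends and middles.

    Windows wholly inside the first *end_width* bp are pooled as
    "centromeric", those wholly inside the last *end_width* bp as "distal",
    and the rest as "middle", across all chromosomes at least 2*end_width
    long (shorter chromosomes are excluded with a warning).  Location is
    compared with Welch's unequal-variance t-test and variance heterogeneity
    with a two-sided folded-F test for each segment pair.
    """
    labels = []
    for row in windows.itertuples():
        size = chrom_sizes.get(row.chrom)
        if size is None:
            raise ValueError(f"window on unknown chromosome {row.chrom!r}")
        if size < 2 * end_width:
            labels.append("excluded")
            continue
        if row.end <= end_width:
            labels.append("centromeric")
        elif row.start >= size - end_width:
            labels.append("distal")
        else:
            labels.append("middle")
    short = [c for c, s in chrom_sizes.items() if s < 2 * end_width]
    if short:
        warnings.warn(
            f"chromosomes shorter than 2x end_width excluded: {sorted(short)}",
            stacklevel=2,
        )
    windows = windows.assign(segment=labels)
    windows = windows[windows["segment"] != "excluded"]
    groups = {
        seg: windows.loc[windows["segment"] == seg, "mean_gmr"].to_numpy()
        for seg in ("centromeric", "middle", "distal")
    }
    summary = pd.DataFrame(
        [
            (seg, vals.mean() if len(vals) else np.nan,
             vals.std(ddof=1) if len(vals) > 1 else np.nan, len(vals))
            for seg, vals in groups.items()
        ],
        columns=["segment", "mean", "sd", "n"],
    )
    loc_rows, var_rows = [], []
    pairs = [("centromeric", "middle"), ("centromeric", "distal"), ("middle", "distal")]
    for a, b in pairs:
        xa, xb = groups[a], groups[b]
        if len(xa) < 2 or len(xb) < 2:
            loc_rows.append((a, b, np.nan, np.nan))
            var_rows.append((a, b, np.nan, np.nan))
            continue
        t, p = stats.ttest_ind(xa, xb, equal_var=False)
        loc_rows.append((a, b, float(t), float(p)))
        f, pf = _folded_f_test(xa, xb)
        var_rows.append((a, b, f, pf))
    return SegmentComparison(
        summary=summary,
        location_tests=pd.DataFrame(loc_rows, columns=["segment_a", "segment_b", "t", "p"]),
        variance_tests=pd.DataFrame(var_rows, columns=["segment_a", "segment_b", "F", "p"]),
    )


def gene_density_correlation(windows: pd.DataFrame,
                             genes: Sequence[GeneModel]) -> tuple[float, float, pd.DataFrame]:
    """Spearman correlation of window mean GMR with gene count per window.

    A gene is assigned to the window containing its TSS.  Returns
    (rho, p, windows-with-counts).  Raises on fewer than 3 windows; an
    all-tied input (zero variance in either variable) is flagged with NaN.
    """
    if len(windows) < 3:
        raise ValueError("need at least 3 windows for a rank correlation")
    windows = windows.reset_index(drop=True).copy()
    counts = np.zeros(len(windows), dtype=int)
    by_chrom = {c: g.reset_index() for c, g in windows.groupby("chrom")}
    for gene in genes:
        sub = by_chrom.get(gene.chrom)
        if sub is None:
            continue
        hit = sub[(sub["start"] <= gene.tss) & (gene.tss < sub["end"])]
        for idx in hit["index"]:
            counts[idx] += 1
    windows["n_genes"] = counts
    x, y = windows["mean_gmr"].to_numpy(), counts
    if np.all(x == x[0]) or np.all(y == y[0]):
        warnings.warn("rank correlation undefined on all-tied input", stacklevel=2)
        return float("nan"), float("nan"), windows
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p), windows


# ---------------------------------------------------------------------------
# sequence-context coverage and CpG islands
# ---------------------------------------------------------------------------

_H = frozenset("ACT")


def _context_positions(seq: str, context: str) -> np.ndarray:
    """Start positions of context sites on a forward-strand scan.

    CpG: positions of 'CG' dinucleotide starts.  CHG: 'C H G' trinucleotide
    starts; CHH: 'C H H', with H in {A, C, T}.
    """
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = arr == ord("C")
    is_g = arr == ord("G")
    is_h = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("T"))
    if context == "CpG":
        mask = is_c[:-1] & is_g[1:]
    elif context == "CHG":
        mask = is_c[:-2] & is_h[1:-1] & is_g[2:]
    elif context == "CHH":
        mask = is_c[:-2] & is_h[1:-1] & is_h[2:]
    else:
        raise ValueError(f"unknown context {context!r}")
    return np.flatnonzero(mask)


def cpg_site_coverage(tracks: Sequence[DepthTrack], genome: Mapping[str, str],
                      context: str = "CpG",
                      thresholds: Sequence[int] = (1, 5),
                      per_cow: bool = False) -> pd.DataFrame:
    """Fraction of context sites (and of all positions) sequenced at depth.

    Depth is pooled across cows by default (``per_cow=True`` instead reports
    the mean of per-cow fractions).  Site depth is taken at the cytosine of
    the context site.  Returns a frame with columns context, threshold,
    site_fraction, genome_fraction.
    """
    if per_cow:
        depth_sets = {}
        for t in tracks:
            depth_sets.setdefault(t.cow_id, []).append(t)
        frames = [
            cpg_site_coverage(sub, genome, context, thresholds, per_cow=False)
            for sub in depth_sets.values()
        ]
        merged = frames[0].copy()
        merged["site_fraction"] = np.mean([f["site_fraction"] for f in frames], axis=0)
        merged["genome_fraction"] = np.mean([f["genome_fraction"] for f in frames], axis=0)
        return merged

    pooled = pooled_depth(tracks)
    n_sites = n_positions = 0
    site_hits = {th: 0 for th in thresholds}
    genome_hits = {th: 0 for th in thresholds}
    for chrom, seq in genome.items():
        if chrom not in pooled:
            raise ValueError(f"no depth track for chromosome {chrom!r}")
        depth = pooled[chrom]
        if len(depth) != len(seq):
            raise ValueError(
                f"{chrom}: sequence length {len(seq)} != track length {len(depth)}"
            )
        pos = _context_positions(seq, context)
        n_sites += len(pos)
        n_positions += len(seq)
        for th in thresholds:
            site_hits[th] += int(np.count_nonzero(depth[pos] >= th))
            genome_hits[th] += int(np.count_nonzero(depth >= th))
    rows = [
        (
            context,
            th,
            site_hits[th] / n_sites if n_sites else float("nan"),
            genome_hits[th] / n_positions if n_positions else float("nan"),
        )
        for th in thresholds
    ]
    return pd.DataFrame(rows, columns=["context", "threshold",
                                       "site_fraction", "genome_fraction"])


def find_cpg_islands(seq: str, min_len: int = 200, gc_min: float = 0.5,
                     obs_exp_min: float = 0.6) -> list[tuple[int, int]]:
    """CpG islands: >=200 bp windows with GC >= 50% and obs/exp CpG > 0.6.

    A window of *min_len* slides one base at a time; windows meeting all
    three criteria are merged when they overlap, and each merged run is
    reported as one island.  obs/exp = (N_CpG * L) / (N_C * N_G); windows
    with no C or no G score 0.
    """
    n = len(seq)
    if n < min_len:
        return []
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    is_c = (arr == ord("C")).astype(np.int64)
    is_g = (arr == ord("G")).astype(np.int64)
    is_cg = np.zeros(n, dtype=np.int64)
    is_cg[:-1] = (arr[:-1] == ord("C")) & (arr[1:] == ord("G"))

    def winsum(x: np.ndarray) -> np.ndarray:
        cs = np.concatenate(([0], np.cumsum(x)))
        return cs[min_len:] - cs[:-min_len]

    c = winsum(is_c)
    g = winsum(is_g)
    # CpG count fully inside the window: dinucleotide starts in [i, i+L-1)
    cs = np.concatenate(([0], np.cumsum(is_cg)))
    cg = cs[min_len - 1:n] - cs[: n - min_len + 1]

    gc_ok = (c + g) >= gc_min * min_len
    denom = c * g
    with np.errstate(divide="ignore", invalid="ignore"):
        obs_exp = np.where(denom > 0, cg * min_len / np.where(denom > 0, denom, 1), 0.0)
    ok = gc_ok & (obs_exp > obs_exp_min)

    islands: list[tuple[int, int]] = []
    starts = np.flatnonzero(ok)
    if len(starts) == 0:
        return islands
    run_start = prev = starts[0]
    for s in starts[1:]:
        if s <= prev + min_len:  # windows overlap or touch -> same island
            prev = s
        else:
            islands.append((int(run_start), int(prev + min_len)))
            run_start = prev = s
    islands.append((int(run_start), int(prev + min_len)))
    return islands
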