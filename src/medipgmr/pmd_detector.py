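"""Detection of partially methylated domains (PMD).

A PMD is an extended (>= 100 kb) genomic stretch with suppressed methylation
coverage.  The genome is partitioned into non-overlapping 10-kb windows and
each window's fraction covered by methylated (read-covered) regions is
computed.  A moving average over ten consecutive windows smooths the signal;
its null distribution is estimated by drawing ten windows at random with
replacement (one million draws by default) and averaging, and the empirical
1% quantile of those draw means is the significance threshold: runs of
moving-average positions below it are significant PMDs at P < 0.01.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel, MethylatedIntervalSet

__all__ = [
    "window_coverage",
    "moving_average",
    "permutation_threshold",
    "call_pmds",
    "genes_in_pmds",
]


def window_coverage(intervals: MethylatedIntervalSet,
                    chrom_sizes: Mapping[str, int],
                    width: int = 10_000) -> pd.DataFrame:
    """Fraction of each non-overlapping window covered by any interval.

    Terminal windows shorter than *width* are dropped (they would bias
    coverage fractions and the permutation pool).  Returns a frame with
    chrom, window_index, start, end, covered_fraction.
    """
    rows = []
    for chrom, size in chrom_sizes.items():
        n_windows = size // width
        if n_windows == 0:
            continue
        cov = np.zeros(n_windows * width, dtype=bool)
        for s, e in intervals.intervals(chrom):
            s, e = int(s), min(int(e), len(cov))
            if s < len(cov):
                cov[s:e] = True
        frac = cov.reshape(n_windows, width).mean(axis=1)
        starts = np.arange(n_windows) * width
        rows.append(pd.DataFrame({
            "chrom": chrom,
            "window_index": np.arange(n_windows),
            "start": starts,
            "end": starts + width,
            "covered_fraction": frac,
        }))
    if not rows:
        return pd.DataFrame(columns=["chrom", "window_index", "start", "end",
                                     "covered_fraction"])
    return pd.concat(rows, ignore_index=True)


def moving_average(windows: pd.DataFrame, span: int = 10) -> pd.DataFrame:
    """Moving average of window coverage over *span* consecutive windows.

    Computed within chromosomes only; position i averages windows
    i..i+span-1, so a chromosome with n windows yields n-span+1 positions.
    Chromosomes with fewer than *span* windows contribute none (warning).
    """
    if span < 1:
        raise ValueError("span must be >= 1")
    frames = []
    for chrom, sub in windows.groupby("chrom", sort=False):
        vals = sub.sort_values("window_index")["covered_fraction"].to_numpy()
        if len(vals) < span:
            warnings.warn(f"{chrom}: fewer than {span} windows, no moving average",
                          stacklevel=2)
            continue
        kernel = np.ones(span) / span
        ma = np.convolve(vals, kernel, mode="valid")
        frames.append(pd.DataFrame({
            "chrom": chrom,
            "position": np.arange(len(ma)),
            "moving_average": ma,
        }))
    if not frames:
        return pd.DataFrame(columns=["chrom", "position", "moving_average"])
    return pd.concat(frames, ignore_index=True)


def permutation_threshold(windows: pd.DataFrame, span: int = 10,
                          n_draws: int = 1_000_000, alpha: float = 0.01,
                          seed: int | np.random.Generator = 0,
                          chunk_size: int = 200_000) -> float:
    """Empirical alpha-quantile of means of *span* windows drawn at random.

    Draws *span* windows uniformly with replacement from the genome-wide
    pool, averages their coverage, repeats *n_draws* times, and returns the
    level below which a fraction *alpha* of draw means fall.  Under the
    hypothesis that adjoining windows are independent, a moving average
    below this level is expected for a fraction alpha of positions.
    """
    pool = windows["covered_fraction"].to_numpy()
    if len(pool) < span:
        raise ValueError(f"need at least {span} windows, got {len(pool)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.empty(n_draws)
    done = 0
    while done < n_draws:
        m = min(chunk_size, n_draws - done)
        means[done:done + m] = pool[rng.integers(0, len(pool), size=(m, span))].mean(axis=1)
        done += m
    return float(np.quantile(means, alpha))


def call_pmds(ma: pd.DataFrame, threshold: float, windows: pd.DataFrame,
              span: int = 10) -> pd.DataFrame:
    """Convert below-threshold moving-average runs into PMD intervals.

    Each maximal run of positions with moving average < threshold becomes
    the genomic interval spanning the union of its member windows (two
    adjacent qualifying positions therefore extend the call by one window,
    not by a full span).  Returns chrom, start, end, n_windows,
    min_moving_average, alpha-bound columns.
    """
    calls = []
    win_by_chrom = {c: sub.sort_values("window_index").reset_index(drop=True)
                    for c, sub in windows.groupby("chrom", sort=False)}
    for chrom, sub in ma.groupby("chrom", sort=False):
        sub = sub.sort_values("position")
        below = (sub["moving_average"].to_numpy() < threshold).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], below, [0]))))
        wins = win_by_chrom[chrom]
        for rs, re in zip(edges[0::2], edges[1::2]):
            first_win, last_win = int(rs), int(re - 1 + span - 1)
            start = int(wins.loc[first_win, "start"])
            end = int(wins.loc[last_win, "end"])
            mavg = sub["moving_average"].to_numpy()[rs:re]
            calls.append((chrom, start, end, last_win - first_win + 1,
                          float(mavg.min())))
    df = pd.DataFrame(calls, columns=["chrom", "start", "end", "n_windows",
                                      "min_moving_average"])
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def genes_in_pmds(pmds: pd.DataFrame, genes: Sequence[GeneModel],
                  x_chroms: Sequence[str] = ("X", "chrX")
                  ) -> tuple[list[str], pd.DataFrame]:
    """Genes whose span overlaps a PMD, with autosome/X fractions.

    A gene is "in" a PMD when its [min(tss,tts), max(tss,tts)+1) span
    overlaps a PMD by at least 1 bp.  Returns (gene_ids, summary) where the
    summary reports per chromosome class the gene totals, the count in
    PMDs, and the fraction (NaN when a class has no genes).
    """
    by_chrom: dict[str, np.ndarray] = {}
    for chrom, sub in pmds.groupby("chrom", sort=False):
        arr = sub[["start", "end"]].to_numpy()
        by_chrom[chrom] = arr[np.argsort(arr[:, 0])]
    hits = []
    class_total = {"autosome": 0, "X": 0}
    class_hit = {"autosome": 0, "X": 0}
    for g in genes:
        lo = min(g.tss, g.tts)
        hi = max(g.tss, g.tts) + 1
        cls = "X" if g.chrom in x_chroms else "autosome"
        class_total[cls] += 1
        arr = by_chrom.get(g.chrom)
        if arr is None:
            continue
        overlap = np.any((arr[:, 0] < hi) & (arr[:, 1] > lo))
        if overlap:
            hits.append(g.gene_id)
            class_hit[cls] += 1
    summary = pd.DataFrame(
        [
            (cls, class_total[cls], class_hit[cls],
             class_hit[cls] / class_total[cls] if class_total[cls] else float("nan"))
            for cls in ("autosome", "X")
        ],
        columns=["class", "n_genes", "n_in_pmd", "fraction"],
    )
    return hits, summary
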