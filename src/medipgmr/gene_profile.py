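"""Length-standardized metagene methylation profiles.

Gene elements of variable length (exons, introns) are mapped onto fixed
standardized coordinates — the cohort median length of each element class —
so that exon/intron boundaries line up across genes.  An element longer than
its standardized length keeps its two flanks base-for-base and collapses the
interior onto the single midpoint slot; an element shorter than it keeps its
first half anchored at the element start and its second half anchored at the
element end, leaving interior slots empty for that gene.

The profile covers 1 kb upstream of the TSS; first, middle, and last exons;
first and last introns; and 1 kb downstream of the TTS, averaging the
per-nucleotide GMR over all genes that populate each standardized position.
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import GeneModel

__all__ = [
    "standardized_position",
    "element_medians",
    "profile_gene_set",
    "find_tss_nadir",
    "DEFAULT_MEDIANS",
    "ELEMENTS",
]

ELEMENTS = (
    "upstream",
    "exon_first",
    "exon_middle",
    "exon_last",
    "intron_first",
    "intron_last",
    "downstream",
)

#: Median element lengths of the reference bovine gene set; used as
#: standardized lengths when medians are not recomputed from the input genes.
DEFAULT_MEDIANS: dict[str, int] = {
    "exon_first": 159,
    "exon_middle": 128,
    "exon_last": 503,
    "intron_first": 2616,
    "intron_last": 1343,
}


def standardized_position(i: int, k: int, L: int) -> int:
    """Map nucleotide *i* (1-based) of a length-*k* element onto [1, L].

    k == L: identity.  k > L: the first floor(L/2) and last floor(L/2)
    nucleotides map base-for-base onto the two flanks and everything between
    collapses onto the midpoint slot floor(L/2)+1.  k < L: the first
    ceil(k/2) nucleotides map onto 1..ceil(k/2) and the remainder map onto
    the last positions, L-(k-i).
    """
    if not 1 <= i <= k:
        raise ValueError(f"position {i} out of range for element length {k}")
    if L < 1:
        raise ValueError("standardized length must be >= 1")
    if k == L:
        return i
    if k > L:
        half = L // 2
        if i <= half:
            return i
        if i > k - half:
            return L - (k - i)
        return half + 1
    # k < L
    if i <= (k + 1) // 2:
        return i
    return L - (k - i)


def _standardize_values(values: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-slot sums and occupancy of one element's values after mapping.

    Returns (slot_mean, populated_mask); slot_mean is 0 on unpopulated slots.
    """
    k = len(values)
    idx = np.array([standardized_position(i, k, L) for i in range(1, k + 1)]) - 1
    sums = np.bincount(idx, weights=values, minlength=L)
    counts = np.bincount(idx, minlength=L)
    populated = counts > 0
    means = np.zeros(L)
    means[populated] = sums[populated] / counts[populated]
    return means, populated


def element_medians(genes: Sequence[GeneModel]) -> dict[str, int]:
    """Median lengths of first/middle/last exons and first/last introns."""
    pools: dict[str, list[int]] = {k: [] for k in DEFAULT_MEDIANS}
    for g in genes:
        ex = g.exons if g.strand == "+" else g.exons[::-1]
        intr = g.introns if g.strand == "+" else g.introns[::-1]
        pools["exon_first"].append(ex[0][1] - ex[0][0])
        if len(ex) >= 2:
            pools["exon_last"].append(ex[-1][1] - ex[-1][0])
        for s, e in ex[1:-1]:
            pools["exon_middle"].append(e - s)
        if intr:
            pools["intron_first"].append(intr[0][1] - intr[0][0])
            pools["intron_last"].append(intr[-1][1] - intr[-1][0])
    medians = {}
    for key, vals in pools.items():
        medians[key] = int(np.median(vals)) if vals else DEFAULT_MEDIANS[key]
    return medians


def _gene_elements(gene: GeneModel, chrom_len: int,
                   flank: int) -> dict[str, list[tuple[int, int]]]:
    """Genomic intervals of each profiled element, in genomic coordinates.

    Exons/introns are labelled in transcriptional order.  Flank intervals
    are truncated at chromosome bounds (with a warning).
    """
    ex = gene.exons if gene.strand == "+" else gene.exons[::-1]
    intr = gene.introns if gene.strand == "+" else gene.introns[::-1]
    out: dict[str, list[tuple[int, int]]] = {"exon_first": [ex[0]]}
    if len(ex) >= 2:
        out["exon_last"] = [ex[-1]]
    if len(ex) >= 3:
        out["exon_middle"] = list(ex[1:-1])
    if intr:
        # a single intron of a 2-exon gene is both first and last by position
        out["intron_first"] = [intr[0]]
        out["intron_last"] = [intr[-1]]
    if gene.strand == "+":
        up = (gene.start - flank, gene.start)
        down = (gene.end, gene.end + flank)
    else:
        up = (gene.end, gene.end + flank)
        down = (gene.start - flank, gene.start)
    truncated = False
    flanks = {}
    for name, (s, e) in (("upstream", up), ("downstream", down)):
        s2, e2 = max(0, s), min(chrom_len, e)
        if (s2, e2) != (s, e):
            truncated = True
        if e2 > s2:
            flanks[name] = [(s2, e2)]
    if truncated:
        warnings.warn(f"gene {gene.gene_id}: flank truncated at chromosome bounds",
                      stacklevel=3)
    out.update(flanks)
    return out


def profile_gene_set(gmr: Mapping[str, np.ndarray], genes: Sequence[GeneModel],
                     flank: int = 1000,
                     medians: Mapping[str, int] | None = None) -> pd.DataFrame:
    """Average GMR over genes at each standardized element position.

    Parameters
    ----------
    gmr
        chromosome -> per-nucleotide GMR vector.
    genes
        gene models; genes with fewer than 3 exons contribute only to the
        elements they possess (2 exons: first+last exon and the shared
        intron; 1 exon: first exon and flanks only).
    flank
        upstream/downstream width in bp (standardized length = flank).
    medians
        standardized element lengths; recomputed from *genes* when None.

    Returns
    -------
    Frame with columns element, position (1-based, oriented 5'->3'
    transcriptionally; upstream position ``flank`` abuts the TSS), mean_gmr,
    n_genes.
    """
    if not genes:
        raise ValueError("no gene models supplied: nothing to profile")
    if medians is None:
        medians = element_medians(genes)
    lengths = {el: int(medians[el]) for el in DEFAULT_MEDIANS}
    lengths["upstream"] = flank
    lengths["downstream"] = flank

    sums = {el: np.zeros(L) for el, L in lengths.items()}
    ngen = {el: np.zeros(L, dtype=int) for el, L in lengths.items()}

    for gene in genes:
        if gene.chrom not in gmr:
            raise ValueError(f"no GMR track for chromosome {gene.chrom!r}")
        track = gmr[gene.chrom]
        elements = _gene_elements(gene, len(track), flank)
        for el, intervals in elements.items():
            L = lengths[el]
            acc = np.zeros(L)
            occ = np.zeros(L, dtype=int)
            for (s, e) in intervals:
                vals = np.asarray(track[s:e], dtype=float)
                if gene.strand == "-":
                    vals = vals[::-1]
                means, populated = _standardize_values(vals, L)
                acc[populated] += means[populated]
                occ += populated
            mask = occ > 0
            # multiple middle exons: average the exon-level profiles per gene
            sums[el][mask] += acc[mask] / occ[mask]
            ngen[el][mask] += 1

    rows = []
    for el in ELEMENTS:
        if el not in lengths:
            continue
        L = lengths[el]
        with np.errstate(invalid="ignore"):
            mean = np.where(ngen[el] > 0, sums[el] / np.maximum(ngen[el], 1), np.nan)
        for pos in range(L):
            rows.append((el, pos + 1, mean[pos], int(ngen[el][pos])))
    return pd.DataFrame(rows, columns=["element", "position", "mean_gmr", "n_genes"])


def find_tss_nadir(profile: pd.DataFrame, flank: int | None = None) -> int:
    """Offset (bp upstream of the TSS, 1..flank) of the upstream minimum.

    Upstream positions run 5'->3', so position ``flank`` is the base
    immediately upstream of the TSS (offset 1).  Ties are broken toward the
    TSS (smallest offset).  *flank* is inferred from the profile when None.
    """
    all_up = profile[profile["element"] == "upstream"]
    if all_up.empty:
        raise ValueError("profile has no upstream element")
    if flank is None:
        flank = int(all_up["position"].max())
    up = all_up[all_up["mean_gmr"].notna()]
    if up.empty:
        raise ValueError("profile has no populated upstream element")
    values = up.set_index("position")["mean_gmr"]
    min_val = values.min()
    # smallest offset = largest position index among the tied minima
    best_pos = int(values[values == min_val].index.max())
    return flank - best_pos + 1
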