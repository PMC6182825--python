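"""Readers and writers for the on-disk formats used throughout the pipeline.

All internal coordinates are 0-based half-open (BED/bedGraph native); GTF
records are converted on read.  Report tables are emitted 1-based inclusive,
the convention of the supplementary-table style they mirror.

Depth is stored densely: one integer vector per (cow, chromosome), one entry
per nucleotide.  The toy genomes this package targets make that affordable;
per-nucleotide access semantics are the contract, not the backing store.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthTrack",
    "GeneModel",
    "CohortDesign",
    "CowRecord",
    "MethylatedIntervalSet",
    "read_depth_track",
    "write_depth_track",
    "read_gene_models",
    "write_gene_models_gtf",
    "read_cohort_design",
    "write_cohort_design",
    "read_fasta",
    "write_fasta",
    "stack_tracks",
    "pooled_depth",
    "write_region_table",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class DepthTrack:
    """Per-nucleotide read counts (NR) for one cow on one chromosome."""

    cow_id: str
    chrom: str
    depths: np.ndarray  # int array, length = chromosome length

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 1:
            raise ValueError("depths must be a 1-D vector")
        if np.any(self.depths < 0):
            raise ValueError("read counts must be non-negative")


@dataclass
class GeneModel:
    """A protein-coding gene: ordered exons plus strand-aware TSS/TTS.

    Exons are stored in genomic order as 0-based half-open intervals.  The
    TSS is the first transcribed base (leftmost exon start on the plus
    strand, rightmost exon base on the minus strand); the TTS is the last.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: at least one exon required")
        exons = sorted((int(s), int(e)) for s, e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"gene {self.gene_id}: empty exon [{s}, {e})")
        for (_, e0), (s1, _) in zip(exons, exons[1:]):
            if s1 < e0:
                raise ValueError(f"gene {self.gene_id}: overlapping exons")
        self.exons = exons

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start

    @property
    def introns(self) -> list[tuple[int, int]]:
        """Gaps between consecutive exons, in genomic order."""
        return [
            (e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:]) if s1 > e0
        ]

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class CowRecord:
    cow_id: str
    farm_id: str
    role: str  # case | control | intermediate


@dataclass
class CohortDesign:
    """Cows grouped into farms with case/control/intermediate roles.

    The study layout pairs a high-yield (case) and a low-yield (control) cow
    on each of two farms, plus two intermediate cows housed alone on two
    further farms.  Scenario enumeration in :mod:`medipgmr.region_dmr`
    requires that layout; the container itself only enforces local
    consistency (one case matched by one control per farm, intermediates
    alone on their farm).
    """

    cows: list[CowRecord]

    VALID_ROLES = ("case", "control", "intermediate")

    def __post_init__(self) -> None:
        ids = [c.cow_id for c in self.cows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate cow_id in design")
        for c in self.cows:
            if c.role not in self.VALID_ROLES:
                raise ValueError(f"cow {c.cow_id}: unknown role {c.role!r}")
        for farm, members in self.by_farm().items():
            roles = sorted(m.role for m in members)
            if "intermediate" in roles:
                if roles != ["intermediate"]:
                    raise ValueError(
                        f"farm {farm}: intermediate cows must be alone on their farm"
                    )
            else:
                if roles != ["case", "control"]:
                    raise ValueError(
                        f"farm {farm}: expected exactly one case and one control, got {roles}"
                    )

    def by_farm(self) -> dict[str, list[CowRecord]]:
        farms: dict[str, list[CowRecord]] = {}
        for c in self.cows:
            farms.setdefault(c.farm_id, []).append(c)
        return farms

    @property
    def cow_ids(self) -> list[str]:
        return [c.cow_id for c in self.cows]

    def case_control_farms(self) -> list[str]:
        """Farm ids carrying a case-control pair, in design order."""
        seen: list[str] = []
        for c in self.cows:
            if c.role in ("case", "control") and c.farm_id not in seen:
                seen.append(c.farm_id)
        return seen

    def pair_for_farm(self, farm_id: str) -> tuple[str, str]:
        """(case_cow, control_cow) for a case-control farm."""
        members = {m.role: m.cow_id for m in self.by_farm()[farm_id]}
        return members["case"], members["control"]

    def intermediates(self) -> list[str]:
        return [c.cow_id for c in self.cows if c.role == "intermediate"]

    @classmethod
    def six_cow_default(cls) -> "CohortDesign":
        """The study layout: two case-control farm pairs plus two intermediates."""
        return cls(
            cows=[
                CowRecord("F1H", "farm1", "case"),
                CowRecord("F1L", "farm1", "control"),
                CowRecord("F2H", "farm2", "case"),
                CowRecord("F2L", "farm2", "control"),
                CowRecord("F3I", "farm3", "intermediate"),
                CowRecord("F4I", "farm4", "intermediate"),
            ]
        )


class MethylatedIntervalSet:
    """Sorted, merged genomic intervals (0-based half-open), per chromosome."""

    def __init__(self, intervals: Mapping[str, np.ndarray] | None = None,
                 label: str = "region"):
        self.label = label
        self._by_chrom: dict[str, np.ndarray] = {}
        if intervals:
            for chrom, arr in intervals.items():
                self._by_chrom[chrom] = _normalize_intervals(np.asarray(arr))

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int]],
                     label: str = "region") -> "MethylatedIntervalSet":
        grouped: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in records:
            grouped.setdefault(chrom, []).append((int(start), int(end)))
        return cls({c: np.array(v, dtype=np.int64).reshape(-1, 2)
                    for c, v in grouped.items()}, label=label)

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def intervals(self, chrom: str) -> np.ndarray:
        """(n, 2) start/end array for one chromosome (empty if absent)."""
        return self._by_chrom.get(chrom, np.empty((0, 2), dtype=np.int64))

    def total_bp(self) -> int:
        return int(sum((arr[:, 1] - arr[:, 0]).sum() for arr in self._by_chrom.values()))

    def __len__(self) -> int:
        return sum(len(a) for a in self._by_chrom.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MethylatedIntervalSet):
            return NotImplemented
        if set(self._by_chrom) != set(other._by_chrom):
            return False
        return all(np.array_equal(self._by_chrom[c], other._by_chrom[c])
                   for c in self._by_chrom)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in self.chroms:
                for start, end in self.intervals(chrom):
                    fh.write(f"{chrom}\t{start}\t{end}\t{self.label}\n")

    @classmethod
    def read_bed(cls, path: str | Path,
                 chrom_sizes: Mapping[str, int] | None = None) -> "MethylatedIntervalSet":
        records = []
        label = "region"
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                if len(parts) > 3:
                    label = parts[3]
                if chrom_sizes is not None:
                    _check_bounds(chrom, start, end, chrom_sizes, path)
                records.append((chrom, start, end))
        return cls.from_records(records, label=label)


def _normalize_intervals(arr: np.ndarray) -> np.ndarray:
    """Sort and merge overlapping/adjacent intervals."""
    arr = arr.reshape(-1, 2).astype(np.int64)
    if len(arr) == 0:
        return arr
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("empty or inverted interval")
    arr = arr[np.argsort(arr[:, 0])]
    merged = [list(arr[0])]
    for start, end in arr[1:]:
        if start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return np.array(merged, dtype=np.int64)


def _check_bounds(chrom: str, start: int, end: int,
                  chrom_sizes: Mapping[str, int], path) -> None:
    if chrom not in chrom_sizes:
        raise ValueError(f"{path}: unknown chromosome {chrom!r}")
    if start < 0 or end > chrom_sizes[chrom] or end <= start:
        raise ValueError(
            f"{path}: interval {chrom}:{start}-{end} outside chromosome "
            f"of length {chrom_sizes[chrom]}"
        )


# ---------------------------------------------------------------------------
# depth tracks (bedGraph)
# ---------------------------------------------------------------------------

def read_depth_track(path: str | Path, chrom_sizes: Mapping[str, int],
                     cow_id: str | None = None) -> list[DepthTrack]:
    """Read a 4-column bedGraph into dense per-nucleotide depth vectors.

    Positions absent from the file are 0.  One :class:`DepthTrack` is
    returned per chromosome in *chrom_sizes* (all-zero if the file has no
    intervals there).  Overlapping intervals and negative values are errors.
    """
    path = Path(path)
    if cow_id is None:
        cow_id = path.stem
    tracks = {c: np.zeros(size, dtype=np.int64) for c, size in chrom_sizes.items()}
    last_end: dict[str, int] = {}
    seen: dict[str, list[tuple[int, int]]] = {c: [] for c in chrom_sizes}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise ValueError(f"{path}:{ln}: expected 4 bedGraph columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), parts[3]
            val = int(float(value))
            if float(value) < 0:
                raise ValueError(f"{path}:{ln}: negative depth value")
            _check_bounds(chrom, start, end, chrom_sizes, path)
            seen[chrom].append((start, end))
            tracks[chrom][start:end] += val
    for chrom, ivals in seen.items():
        ivals.sort()
        for (s0, e0), (s1, e1) in zip(ivals, ivals[1:]):
            if s1 < e0:
                raise ValueError(f"{path}: overlapping bedGraph intervals on {chrom}")
    return [DepthTrack(cow_id, chrom, tracks[chrom]) for chrom in chrom_sizes]


def write_depth_track(tracks: Sequence[DepthTrack], path: str | Path,
                      include_zero: bool = False) -> None:
    """Write depth tracks as bedGraph, run-length encoding constant stretches."""
    with open(path, "w") as fh:
        for track in tracks:
            d = np.asarray(track.depths)
            if len(d) == 0:
                continue
            # boundaries where the value changes
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(d)]))
            for s, e in zip(starts, ends):
                v = int(d[s])
                if v == 0 and not include_zero:
                    continue
                fh.write(f"{track.chrom}\t{s}\t{e}\t{v}\n")


def stack_tracks(tracks: Sequence[DepthTrack], chrom: str,
                 cow_order: Sequence[str] | None = None) -> tuple[list[str], np.ndarray]:
    """Stack one chromosome's tracks into an (n_cows, length) matrix."""
    per_cow = {t.cow_id: t.depths for t in tracks if t.chrom == chrom}
    if not per_cow:
        raise ValueError(f"no tracks for chromosome {chrom!r}")
    if cow_order is None:
        cow_order = list(per_cow)
    lengths = {len(per_cow[c]) for c in cow_order}
    if len(lengths) != 1:
        raise ValueError(f"track length mismatch on {chrom}")
    return list(cow_order), np.vstack([per_cow[c] for c in cow_order])


def pooled_depth(tracks: Sequence[DepthTrack]) -> dict[str, np.ndarray]:
    """Sum depth across cows, per chromosome."""
    pooled: dict[str, np.ndarray] = {}
    for t in tracks:
        if t.chrom in pooled:
            pooled[t.chrom] = pooled[t.chrom] + t.depths
        else:
            pooled[t.chrom] = t.depths.copy()
    return pooled


# ---------------------------------------------------------------------------
# gene models (GTF / BED12)
# ---------------------------------------------------------------------------

_GTF_ATTR = re.compile(r'(\w+)\s+"([^"]*)"')


def read_gene_models(path: str | Path,
                     chrom_sizes: Mapping[str, int] | None = None) -> list[GeneModel]:
    """Read gene models from GTF (exon features) or BED12, sniffed by content."""
    path = Path(path)
    with open(path) as fh:
        first = ""
        for line in fh:
            if line.strip() and not line.startswith(("#", "track", "browser")):
                first = line
                break
    if not first:
        return []
    fields = first.rstrip("\n").split("\t")
    if len(fields) >= 9 and fields[3].isdigit() and fields[4].isdigit():
        genes = _read_gtf(path)
    elif len(fields) == 12:
        genes = _read_bed12(path)
    else:
        raise ValueError(f"{path}: not recognisable as GTF or BED12")
    if chrom_sizes is not None:
        for g in genes:
            _check_bounds(g.chrom, g.start, g.end, chrom_sizes, path)
    ids = [g.gene_id for g in genes]
    dup = {i for i in ids if ids.count(i) > 1}
    if dup:
        raise ValueError(f"{path}: duplicated gene_id(s): {sorted(dup)}")
    return genes


def _read_gtf(path: Path) -> list[GeneModel]:
    exons: dict[str, dict] = {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "exon":
                continue
            chrom, start, end, strand = f[0], int(f[3]) - 1, int(f[4]), f[6]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: exon without strand")
            attrs = dict(_GTF_ATTR.findall(f[8]))
            gid = attrs.get("gene_id")
            if gid is None:
                raise ValueError(f"{path}:{ln}: exon without gene_id")
            rec = exons.setdefault(gid, {"chrom": chrom, "strand": strand, "exons": []})
            if rec["chrom"] != chrom or rec["strand"] != strand:
                raise ValueError(f"{path}: gene {gid} spans chromosomes or strands")
            rec["exons"].append((start, end))
    return [
        GeneModel(gid, rec["chrom"], rec["strand"], rec["exons"])
        for gid, rec in exons.items()
    ]


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"{path}:{ln}: expected 12 BED columns")
            chrom, chrom_start, name, strand = f[0], int(f[1]), f[3], f[5]
            if strand not in ("+", "-"):
                raise ValueError(f"{path}:{ln}: missing strand")
            n_blocks = int(f[9])
            if n_blocks < 1:
                raise ValueError(f"{path}:{ln}: zero exon blocks")
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            starts = [int(x) for x in f[11].rstrip(",").split(",")]
            if len(sizes) != n_blocks or len(starts) != n_blocks:
                raise ValueError(f"{path}:{ln}: blockCount mismatch")
            ex = [(chrom_start + s, chrom_start + s + z) for s, z in zip(starts, sizes)]
            genes.append(GeneModel(name, chrom, strand, ex))
    return genes


def write_gene_models_gtf(genes: Sequence[GeneModel], path: str | Path,
                          source: str = "medipgmr") -> None:
    """Write exon features as GTF (1-based inclusive, per the format)."""
    with open(path, "w") as fh:
        for g in genes:
            for i, (s, e) in enumerate(g.exons, 1):
                attrs = (f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                         f'exon_number "{i}";')
                fh.write(f"{g.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n")


# ---------------------------------------------------------------------------
# cohort design
# ---------------------------------------------------------------------------

def read_cohort_design(path: str | Path) -> CohortDesign:
    """Read a tab-separated design file with columns cow_id, farm_id, role."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cow_id", "farm_id", "role"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    cows = [CowRecord(r.cow_id, r.farm_id, r.role) for r in df.itertuples()]
    return CohortDesign(cows)


def write_cohort_design(design: CohortDesign, path: str | Path) -> None:
    pd.DataFrame(
        [(c.cow_id, c.farm_id, c.role) for c in design.cows],
        columns=["cow_id", "farm_id", "role"],
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    seqs: dict[str, list[str]] = {}
    name = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                name = line[1:].split()[0]
                if name in seqs:
                    raise ValueError(f"{path}: duplicate sequence name {name!r}")
                seqs[name] = []
            else:
                if name is None:
                    raise ValueError(f"{path}: sequence data before header")
                seqs[name].append(line.upper())
    return {n: "".join(parts) for n, parts in seqs.items()}


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# result tables
# ---------------------------------------------------------------------------

def write_region_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a result table with 1-based inclusive start/end columns.

    Expects 0-based half-open ``start``/``end`` columns; all other columns
    pass through unchanged.
    """
    out = df.copy()
    out["start"] = out["start"] + 1  # 1-based inclusive
    out.to_csv(path, sep="\t", index=False)
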