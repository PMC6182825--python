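"""Permutation-based calling of differentially methylated regions (DMR).

The unit of testing is the read-covered region: a maximal stretch of
nucleotides where at least one cow has a read, with nearby stretches (gap
< 200 bp) merged, short remnants (< 200 bp) dropped, and long runs split
into ~4 kb pieces, giving region lengths of 200-4199 bp.  Per-cow region
read totals are log2(x+1)-transformed and standardized within cow to mean
100, SD 5, which puts cows with different library sizes on a common scale
and keeps ratios defined when a cow has zero reads in a region.

The cohort design — two case-control farm pairs plus two intermediate
cows — admits exactly 48 relabelling scenarios: the three cow pairs are
assigned to three herd-environment slots (3! = 6 combinations) and within
each slot either cow may be labelled the case (2^3 = 8), 6 x 8 = 48.  The
permutation null draws a region at random (with replacement) and a scenario
at random, and computes

* case-control statistic: mean over environment slots 1 and 2 of the
  case/control ratio of standardized reads (slot 3 is excluded because only
  two true farm pairs exist);
* environmental statistic: per slot, the mean standardized reads of the
  slot's two cows divided by the mean of the other four cows.

Observed statistics under the true design are converted to two-tailed
P-values with the empirical null mean and SD, and Benjamini-Hochberg
adjustment controls the genome-wide FDR.  Environmental P-values from all
three slots are pooled into one FDR data set, but only slots backed by a
true herd pair yield reportable calls.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_formats import CohortDesign, DepthTrack, MethylatedIntervalSet, stack_tracks

__all__ = [
    "Region",
    "StandardizedMatrix",
    "Scenario",
    "NullModel",
    "build_regions",
    "covered_intervals",
    "regions_to_frame",
    "standardize_log2_reads",
    "enumerate_scenarios",
    "case_control_statistic",
    "environmental_statistic",
    "permutation_null",
    "permutation_budget",
    "environmental_fdr_pool_size",
    "dmr_pvalues",
    "fdr_adjust",
    "observed_case_control",
    "observed_environmental",
    "call_dmrs",
]


# ---------------------------------------------------------------------------
# regions
# ---------------------------------------------------------------------------

@dataclass
class Region:
    """A read-covered interval with per-cow read totals."""

    chrom: str
    start: int
    end: int
    reads: np.ndarray  # per-cow totals, order = cow_ids of the region set

    @property
    def length(self) -> int:
        return self.end - self.start


def _merge_runs(starts: np.ndarray, ends: np.ndarray,
                merge_gap: int) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and s - merged[-1][1] < merge_gap:
            merged[-1][1] = e
        else:
            merged.append([int(s), int(e)])
    return [(s, e) for s, e in merged]


def _split_run(start: int, end: int, chunk: int, min_len: int) -> list[tuple[int, int]]:
    """Split a long run into chunk-sized pieces, last piece >= min_len.

    A final remainder shorter than *min_len* is folded into the preceding
    chunk, so piece lengths are *chunk* or, for the last piece, in
    [min_len, chunk + min_len - 1].
    """
    pieces = []
    pos = start
    while end - pos > chunk:
        if end - (pos + chunk) >= min_len:
            pieces.append((pos, pos + chunk))
            pos += chunk
        else:
            break
    pieces.append((pos, end))
    return pieces


def build_regions(tracks: Sequence[DepthTrack], min_len: int = 200,
                  merge_gap: int = 200, chunk: int = 4000,
                  cow_order: Sequence[str] | None = None
                  ) -> tuple[list[str], list[Region]]:
    """Construct read-covered regions from a cohort's depth tracks.

    Nucleotides where any cow has at least one read are marked; maximal
    covered runs with gaps < *merge_gap* are merged; merged runs shorter
    than *min_len* are dropped; runs longer than *chunk* are split (final
    remainder < *min_len* folds into the preceding piece).  Region lengths
    therefore fall in [min_len, chunk + min_len - 1].

    Returns (cow_ids, regions); ``Region.reads`` follows the cow order.
    """
    if cow_order is None:
        cow_order = []
        for t in tracks:
            if t.cow_id not in cow_order:
                cow_order.append(t.cow_id)
    chroms = sorted({t.chrom for t in tracks})
    regions: list[Region] = []
    for chrom in chroms:
        _, matrix = stack_tracks(tracks, chrom, cow_order)
        covered = np.any(matrix > 0, axis=0).astype(np.int8)
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered, [0]))))
        starts, ends = edges[0::2], edges[1::2]
        merged = _merge_runs(starts, ends, merge_gap)
        kept = [(s, e) for s, e in merged if e - s >= min_len]
        cs = np.concatenate(
            (np.zeros((matrix.shape[0], 1), dtype=np.int64),
             np.cumsum(matrix, axis=1, dtype=np.int64)), axis=1)
        for s, e in kept:
            for ps, pe in _split_run(s, e, chunk, min_len):
                reads = cs[:, pe] - cs[:, ps]
                regions.append(Region(chrom, ps, pe, reads))
    return list(cow_order), regions


def covered_intervals(tracks: Sequence[DepthTrack], min_len: int = 200,
                      merge_gap: int = 200) -> MethylatedIntervalSet:
    """The pre-split read-covered regions as an interval set (for PMD input)."""
    _, regions = build_regions(tracks, min_len=min_len, merge_gap=merge_gap,
                               chunk=10 ** 12)
    return MethylatedIntervalSet.from_records(
        (r.chrom, r.start, r.end) for r in regions)


def regions_to_frame(cow_ids: Sequence[str], regions: Sequence[Region]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "chrom": [r.chrom for r in regions],
            "start": [r.start for r in regions],
            "end": [r.end for r in regions],
        }
    )
    reads = np.array([r.reads for r in regions])
    for j, cow in enumerate(cow_ids):
        df[f"reads_{cow}"] = reads[:, j]
    return df


# ---------------------------------------------------------------------------
# standardization
# ---------------------------------------------------------------------------

@dataclass
class StandardizedMatrix:
    """Regions x cows matrix of within-cow standardized log2 reads."""

    values: np.ndarray           # (n_regions, n_cows)
    cow_ids: list[str]
    regions: list[Region] = field(default_factory=list)
    target_mean: float = 100.0
    target_sd: float = 5.0

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]

    def cow_index(self, cow_id: str) -> int:
        return self.cow_ids.index(cow_id)


def standardize_log2_reads(cow_ids: Sequence[str], regions: Sequence[Region],
                           offset: float = 1.0, target_mean: float = 100.0,
                           target_sd: float = 5.0) -> StandardizedMatrix:
    """Standardize log2(reads + offset) within cow to mean 100, SD 5.

    The offset keeps the log defined for zero-read regions.  Sample SD
    (n-1 denominator) is used.  A cow whose region totals are constant has
    no scale and is an error.
    """
    if len(regions) < 2:
        raise ValueError("need at least 2 regions to standardize")
    raw = np.array([r.reads for r in regions], dtype=float)
    logs = np.log2(raw + offset)
    mu = logs.mean(axis=0)
    sd = logs.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"cow {cow_ids[j]}: zero variance in log2 reads")
    values = target_mean + target_sd * (logs - mu) / sd
    return StandardizedMatrix(values, list(cow_ids), list(regions),
                              target_mean, target_sd)


# ---------------------------------------------------------------------------
# scenarios
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Scenario:
    """One relabelling: per environment slot, (case cow, control cow)."""

    slots: tuple[tuple[str, str], ...]  # ((case, control), ...) for slots 1..3


def enumerate_scenarios(design: CohortDesign) -> list[Scenario]:
    """All distinct relabelling scenarios for the paired-plus-intermediates design.

    The farm-1 pair, farm-2 pair, and the pair formed by the two
    intermediate cows are assigned to the three environment slots in every
    order (3! = 6) and within each slot either member may be the case
    (2^3 = 8): 48 scenarios for the 6-cow design.
    """
    cc_farms = design.case_control_farms()
    inter = design.intermediates()
    if len(cc_farms) != 2 or len(inter) != 2:
        raise ValueError(
            "scenario enumeration requires 2 case-control farms and 2 intermediates"
        )
    pairs = [design.pair_for_farm(cc_farms[0]), design.pair_for_farm(cc_farms[1]),
             tuple(inter)]
    scenarios = []
    for order in itertools.permutations(range(3)):
        for flips in itertools.product((0, 1), repeat=3):
            slots = []
            for slot in range(3):
                a, b = pairs[order[slot]]
                slots.append((b, a) if flips[slot] else (a, b))
            scenarios.append(Scenario(tuple(slots)))
    return scenarios


def _scenario_indices(scenarios: Sequence[Scenario],
                      cow_ids: Sequence[str]) -> dict[str, np.ndarray]:
    """Integer cow-index arrays per scenario for vectorised statistics."""
    pos = {c: i for i, c in enumerate(cow_ids)}
    n = len(scenarios)
    case = np.zeros((n, 3), dtype=np.intp)
    ctrl = np.zeros((n, 3), dtype=np.intp)
    for i, sc in enumerate(scenarios):
        for j, (a, b) in enumerate(sc.slots):
            case[i, j] = pos[a]
            ctrl[i, j] = pos[b]
    # per slot: the 2 member cows and the 4 others
    members = np.stack([case, ctrl], axis=2)      # (n, 3, 2)
    others = np.zeros((n, 3, len(cow_ids) - 2), dtype=np.intp)
    all_idx = set(range(len(cow_ids)))
    for i in range(n):
        for j in range(3):
            rest = sorted(all_idx - set(members[i, j]))
            others[i, j] = rest
    return {"case": case, "ctrl": ctrl, "members": members, "others": others}


def case_control_statistic(row: np.ndarray, scenario: Scenario,
                           cow_ids: Sequence[str]) -> float:
    """Mean over slots 1 and 2 of the case/control standardized-reads ratio."""
    pos = {c: i for i, c in enumerate(cow_ids)}
    ratios = []
    for (case, ctrl) in scenario.slots[:2]:
        denom = row[pos[ctrl]]
        if denom <= 0:
            raise ValueError("non-positive standardized control value")
        ratios.append(row[pos[case]] / denom)
    return float(np.mean(ratios))


def environmental_statistic(row: np.ndarray, scenario: Scenario, env_slot: int,
                            cow_ids: Sequence[str]) -> float:
    """Mean standardized reads of one slot's pair over the mean of the rest."""
    if env_slot not in (1, 2, 3):
        raise ValueError("env_slot must be 1, 2, or 3")
    pos = {c: i for i, c in enumerate(cow_ids)}
    a, b = scenario.slots[env_slot - 1]
    inside = {pos[a], pos[b]}
    outside = [i for i in range(len(cow_ids)) if i not in inside]
    denom = row[list(outside)].mean()
    if denom <= 0:
        raise ValueError("non-positive standardized mean")
    return float(row[list(inside)].mean() / denom)


# ---------------------------------------------------------------------------
# permutation null
# ---------------------------------------------------------------------------

@dataclass
class NullModel:
    """Empirical moments of a permutation statistic."""

    kind: str          # case_control | environmental
    mu0: float
    sigma0: float
    n_draws: int

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")


def permutation_budget(n_regions: int, draws_per_region: float = 48.0) -> int:
    """Total permutation draws at the given per-region sampling rate."""
    if n_regions < 1:
        raise ValueError("no regions")
    return int(round(draws_per_region * n_regions))


def environmental_fdr_pool_size(n_regions: int, n_slots: int = 3) -> int:
    """Size of the pooled environmental FDR data set (slots x regions)."""
    return n_slots * n_regions


def permutation_null(matrix: StandardizedMatrix,
                     scenarios: Sequence[Scenario] | None = None,
                     draws_per_region: float = 48.0,
                     seed: int | np.random.Generator = 0,
                     design: CohortDesign | None = None,
                     return_draws: bool = False,
                     chunk_size: int = 2_000_000):
    """Estimate the empirical null of both statistics by random draws.

    Each draw samples one region uniformly with replacement and one of the
    48 scenarios uniformly, then evaluates the case-control statistic and
    the three environmental statistics (pooled into one environmental
    null).  Per-region draw counts therefore vary by chance.

    Returns {"case_control": NullModel, "environmental": NullModel}; with
    ``return_draws=True`` a third entry "draws" holds the raw case-control
    and pooled environmental draw vectors.
    """
    if matrix.n_regions == 0:
        raise ValueError("no regions")
    if scenarios is None:
        if design is None:
            raise ValueError("provide scenarios or a design to enumerate them from")
        scenarios = enumerate_scenarios(design)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    idx = _scenario_indices(scenarios, matrix.cow_ids)
    n_total = permutation_budget(matrix.n_regions, draws_per_region)

    cc_parts, env_parts = [], []
    remaining = n_total
    while remaining > 0:
        m = min(remaining, chunk_size)
        remaining -= m
        reg = rng.integers(0, matrix.n_regions, size=m)
        sc = rng.integers(0, len(scenarios), size=m)
        rows = matrix.values[reg]                      # (m, n_cows)
        ar = np.arange(m)
        case_vals = rows[ar[:, None], idx["case"][sc]]   # (m, 3)
        ctrl_vals = rows[ar[:, None], idx["ctrl"][sc]]
        cc = (case_vals[:, :2] / ctrl_vals[:, :2]).mean(axis=1)
        members = rows[ar[:, None, None], idx["members"][sc]].mean(axis=2)  # (m, 3)
        others = rows[ar[:, None, None], idx["others"][sc]].mean(axis=2)
        env = members / others                          # (m, 3)
        cc_parts.append(cc)
        env_parts.append(env.ravel())
    cc_draws = np.concatenate(cc_parts)
    env_draws = np.concatenate(env_parts)

    def moments(x: np.ndarray, kind: str) -> NullModel:
        mu, sd = float(x.mean()), float(x.std(ddof=1))
        if sd == 0:
            raise ValueError(f"degenerate {kind} null: zero spread across draws")
        return NullModel(kind, mu, sd, len(x))

    out = {
        "case_control": moments(cc_draws, "case_control"),
        "environmental": moments(env_draws, "environmental"),
    }
    if return_draws:
        out["draws"] = {"case_control": cc_draws, "environmental": env_draws}
    return out


# ---------------------------------------------------------------------------
# P-values, FDR, calls
# ---------------------------------------------------------------------------

def dmr_pvalues(observed: np.ndarray, null: NullModel) -> np.ndarray:
    """Two-tailed normal P-values against the empirical null moments."""
    if null.sigma0 <= 0:
        raise ValueError("degenerate null model")
    z = (np.asarray(observed, dtype=float) - null.mu0) / null.sigma0
    return np.clip(2.0 * stats.norm.sf(np.abs(z)), 0.0, 1.0)


def empirical_pvalues(observed: np.ndarray, draws: np.ndarray) -> np.ndarray:
    """Two-tailed empirical-quantile P-values (sensitivity alternative)."""
    observed = np.asarray(observed, dtype=float)
    draws = np.sort(np.asarray(draws, dtype=float))
    n = len(draws)
    upper = n - np.searchsorted(draws, observed, side="left")
    lower = np.searchsorted(draws, observed, side="right")
    tail = (np.minimum(upper, lower) + 1) / (n + 1)
    return np.clip(2.0 * tail, 0.0, 1.0)


def fdr_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values."""
    pvalues = np.asarray(pvalues, dtype=float)
    if len(pvalues) == 0:
        return pvalues
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("P-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]


def observed_case_control(matrix: StandardizedMatrix,
                          design: CohortDesign) -> np.ndarray:
    """Observed mean case/control ratio over the two true farm pairs."""
    farms = design.case_control_farms()
    ratios = []
    for farm in farms:
        case, ctrl = design.pair_for_farm(farm)
        ratios.append(matrix.values[:, matrix.cow_index(case)]
                      / matrix.values[:, matrix.cow_index(ctrl)])
    return np.mean(ratios, axis=0)


def observed_environmental(matrix: StandardizedMatrix,
                           design: CohortDesign) -> pd.DataFrame:
    """Per-environment observed ratios under the true design.

    Environments are the two case-control farms plus the joint
    intermediate slot; each row set gives mean(pair)/mean(other four).
    Intermediate-slot values are computed (they enter the FDR pool) but are
    flagged non-reportable: its two cows are not herd-mates.
    """
    farms = design.case_control_farms()
    envs = [(farm, list(design.pair_for_farm(farm)), True) for farm in farms]
    envs.append(("intermediate", design.intermediates(), False))
    n_cows = len(matrix.cow_ids)
    frames = []
    for label, members, reportable in envs:
        inside = [matrix.cow_index(c) for c in members]
        outside = [i for i in range(n_cows) if i not in inside]
        stat = (matrix.values[:, inside].mean(axis=1)
                / matrix.values[:, outside].mean(axis=1))
        frames.append(pd.DataFrame({
            "region_index": np.arange(matrix.n_regions),
            "environment": label,
            "statistic": stat,
            "reportable": reportable,
        }))
    return pd.concat(frames, ignore_index=True)


def call_dmrs(matrix: StandardizedMatrix, design: CohortDesign,
              nulls: Mapping[str, NullModel],
              alpha: float = 0.05) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Call case-control and environmental DMRs at the genome-wide FDR.

    Case-control calls: regions whose observed mean pair ratio is extreme
    against the case-control null, BH-adjusted over all regions.
    Environmental calls: per-environment ratios with P-values from all
    three environments pooled into a single BH adjustment; calls are
    reported only for environments backed by a true herd pair.

    Returns (case_control_calls, environmental_calls) — only rows with
    q < alpha (environmental calls additionally reportable).  Both frames
    carry region coordinates, the statistic, raw P, and q.
    """
    coords = pd.DataFrame({
        "chrom": [r.chrom for r in matrix.regions],
        "start": [r.start for r in matrix.regions],
        "end": [r.end for r in matrix.regions],
    })

    cc_stat = observed_case_control(matrix, design)
    cc_p = dmr_pvalues(cc_stat, nulls["case_control"])
    cc_q = fdr_adjust(cc_p)
    cc = coords.copy()
    cc["statistic"] = cc_stat
    cc["p"] = cc_p
    cc["q"] = cc_q
    cc_calls = cc[cc["q"] < alpha].reset_index(drop=True)

    env = observed_environmental(matrix, design)
    env["p"] = dmr_pvalues(env["statistic"].to_numpy(), nulls["environmental"])
    env["q"] = fdr_adjust(env["p"].to_numpy())   # pooled across all slots
    env = env.join(coords, on="region_index")
    env_calls = env[(env["q"] < alpha) & env["reportable"]].reset_index(drop=True)
    env_calls = env_calls[["chrom", "start", "end", "environment",
                           "statistic", "p", "q"]]
    return cc_calls, env_calls
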