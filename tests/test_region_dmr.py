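import numpy as np
import pytest

from conftest import brute_force_regions
from medipgmr.io_formats import CohortDesign, CowRecord, DepthTrack
from medipgmr.region_dmr import (
    NullModel,
    Region,
    build_regions,
    case_control_statistic,
    dmr_pvalues,
    enumerate_scenarios,
    environmental_fdr_pool_size,
    environmental_statistic,
    fdr_adjust,
    permutation_budget,
    permutation_null,
    standardize_log2_reads,
)

COWS = ["F1H", "F1L", "F2H", "F2L", "F3I", "F4I"]


def _tracks_from_matrix(matrix, chrom="chr1"):
    return [DepthTrack(c, chrom, row) for c, row in zip(COWS, matrix)]


def _tracks_with_runs(runs, length=10_000):
    """One cow covers the given (start, end) runs with depth 1."""
    m = np.zeros((6, length), dtype=int)
    for s, e in runs:
        m[0, s:e] = 1
    return _tracks_from_matrix(m)


class TestBuildRegions:
    def test_nearby_runs_merge(self):
        _, regions = build_regions(_tracks_with_runs([(0, 150), (300, 500)]))
        assert [(r.start, r.end) for r in regions] == [(0, 500)]

    def test_isolated_short_run_dropped(self):
        _, regions = build_regions(_tracks_with_runs([(1000, 1150)]))
        assert regions == []

    def test_gap_of_exactly_200_not_merged(self):
        _, regions = build_regions(_tracks_with_runs([(0, 300), (500, 800)]))
        assert [(r.start, r.end) for r in regions] == [(0, 300), (500, 800)]

    def test_long_run_split_with_remainder(self):
        _, regions = build_regions(_tracks_with_runs([(0, 9000)]))
        assert [(r.start, r.end) for r in regions] == [
            (0, 4000), (4000, 8000), (8000, 9000)]

    def test_small_remainder_folds_into_last_chunk(self):
        _, regions = build_regions(_tracks_with_runs([(0, 8100)]))
        assert [(r.start, r.end) for r in regions] == [(0, 4000), (4000, 8100)]

    def test_per_cow_read_totals(self):
        m = np.zeros((6, 1000), dtype=int)
        m[0, 100:400] = 2
        m[3, 200:350] = 5
        _, regions = build_regions(_tracks_from_matrix(m))
        (r,) = regions
        assert list(r.reads) == [600, 0, 0, 750, 0, 0]

    def test_matches_brute_force_oracle_on_random_tracks(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            length = 20_000
            m = np.zeros((3, length), dtype=int)
            # sparse random coverage plus engineered long runs and near gaps
            for c in range(3):
                hits = rng.integers(0, length, size=rng.integers(20, 200))
                m[c, hits] = rng.integers(1, 4, size=len(hits))
            s = int(rng.integers(0, length - 9000))
            m[0, s:s + rng.integers(4200, 9000)] = 1
            tracks = [DepthTrack(f"c{c}", "chr1", m[c]) for c in range(3)]
            _, regions = build_regions(tracks)
            expected = brute_force_regions(m)
            assert [(r.start, r.end) for r in regions] == expected
            lens = np.array([r.length for r in regions])
            if len(lens):
                assert lens.min() >= 200 and lens.max() <= 4199


class TestStandardize:
    def _regions(self, reads_matrix):
        return [Region("chr1", i * 1000, i * 1000 + 500, row)
                for i, row in enumerate(np.asarray(reads_matrix))]

    def test_two_region_closed_form(self):
        # one cow, two regions: standardized values are 100 -+ 5/sqrt(2)
        regions = self._regions([[3], [12]])
        m = standardize_log2_reads(["c1"], regions)
        assert m.values[:, 0] == pytest.approx(
            [100 - 5 / np.sqrt(2), 100 + 5 / np.sqrt(2)])

    def test_fixed_point(self):
        target = np.array([[100 - 5 / np.sqrt(2)], [100 + 5 / np.sqrt(2)]])
        reads = 2 ** target - 1  # log2(reads+1) already has mean 100, SD 5
        m = standardize_log2_reads(["c1"], self._regions(reads))
        assert np.allclose(m.values, target)

    def test_columns_have_exact_moments(self):
        rng = np.random.default_rng(8)
        reads = rng.integers(0, 500, size=(40, 6))
        m = standardize_log2_reads(COWS, self._regions(reads))
        assert np.allclose(m.values.mean(axis=0), 100, atol=1e-9)
        assert np.allclose(m.values.std(axis=0, ddof=1), 5, atol=1e-9)

    def test_zero_variance_column_names_cow(self):
        reads = np.array([[1, 7], [1, 9], [1, 30]])
        with pytest.raises(ValueError, match="cowA"):
            standardize_log2_reads(["cowA", "cowB"], self._regions(reads))


class TestScenarios:
    def test_forty_eight_distinct_scenarios(self):
        scenarios = enumerate_scenarios(CohortDesign.six_cow_default())
        assert len(scenarios) == 48
        assert len(set(scenarios)) == 48

    def test_six_environment_combinations(self):
        scenarios = enumerate_scenarios(CohortDesign.six_cow_default())
        combos = {tuple(frozenset(slot) for slot in sc.slots) for sc in scenarios}
        assert len(combos) == 6

    def test_eight_case_control_designations_per_combination(self):
        scenarios = enumerate_scenarios(CohortDesign.six_cow_default())
        by_combo = {}
        for sc in scenarios:
            key = tuple(frozenset(slot) for slot in sc.slots)
            by_combo.setdefault(key, set()).add(sc.slots)
        assert all(len(v) == 8 for v in by_combo.values())

    def test_non_conforming_design_rejected(self):
        design = CohortDesign([
            CowRecord("a", "f1", "case"), CowRecord("b", "f1", "control"),
            CowRecord("c", "f2", "intermediate"),
        ])
        with pytest.raises(ValueError):
            enumerate_scenarios(design)


class TestStatistics:
    def setup_method(self):
        self.scenario = enumerate_scenarios(CohortDesign.six_cow_default())[0]

    def test_all_equal_gives_one(self):
        row = np.full(6, 100.0)
        assert case_control_statistic(row, self.scenario, COWS) == 1.0
        for slot in (1, 2, 3):
            assert environmental_statistic(row, self.scenario, slot, COWS) == 1.0

    def test_case_control_arithmetic(self):
        row = np.array([105.0, 100.0, 105.0, 100.0, 100.0, 100.0])
        # first scenario keeps the true labelling: cases F1H, F2H
        assert case_control_statistic(row, self.scenario, COWS) == pytest.approx(1.05)

    def test_environmental_arithmetic(self):
        row = np.array([110.0, 110.0, 100.0, 100.0, 100.0, 100.0])
        assert environmental_statistic(row, self.scenario, 1, COWS) == pytest.approx(1.10)

    def test_environmental_conservation_identity(self):
        rng = np.random.default_rng(9)
        row = 100 + rng.normal(0, 5, size=6)
        for slot in (1, 2, 3):
            s_num = row[[COWS.index(c) for c in self.scenario.slots[slot - 1]]].mean()
            inside = set(self.scenario.slots[slot - 1])
            s_den = row[[i for i, c in enumerate(COWS) if c not in inside]].mean()
            assert (2 * s_num + 4 * s_den) / 6 == pytest.approx(row.mean())

    def test_label_swap_gives_reciprocal_ratios(self):
        rng = np.random.default_rng(10)
        row = 100 + rng.normal(0, 5, size=6)
        scenarios = enumerate_scenarios(CohortDesign.six_cow_default())
        sc = scenarios[0]
        swapped = next(
            s for s in scenarios
            if s.slots == tuple((b, a) for a, b in sc.slots)
        )
        pos = {c: i for i, c in enumerate(COWS)}
        r = [row[pos[a]] / row[pos[b]] for a, b in sc.slots[:2]]
        r_swapped = [row[pos[a]] / row[pos[b]] for a, b in swapped.slots[:2]]
        assert r_swapped == pytest.approx([1 / x for x in r])


class TestPermutationNull:
    def _matrix(self, seed=0, n=60):
        rng = np.random.default_rng(seed)
        reads = rng.integers(10, 500, size=(n, 6))
        regions = [Region("chr1", i * 1000, i * 1000 + 500, row)
                   for i, row in enumerate(reads)]
        return standardize_log2_reads(COWS, regions)

    def test_same_seed_bitwise_identical(self):
        m = self._matrix()
        design = CohortDesign.six_cow_default()
        a = permutation_null(m, design=design, seed=123, return_draws=True)
        b = permutation_null(m, design=design, seed=123, return_draws=True)
        assert a["case_control"] == b["case_control"]
        assert np.array_equal(a["draws"]["case_control"],
                              b["draws"]["case_control"])

    def test_exchangeable_matrix_null_mean_near_one(self):
        m = self._matrix(seed=4, n=200)
        nulls = permutation_null(m, design=CohortDesign.six_cow_default(),
                                 draws_per_region=200, seed=1)
        assert nulls["case_control"].mu0 == pytest.approx(1.0, abs=0.02)
        assert nulls["environmental"].mu0 == pytest.approx(1.0, abs=0.02)

    def test_degenerate_matrix_flagged(self):
        regions = [Region("chr1", 0, 500, np.array([7, 7, 7, 7, 7, 7])),
                   Region("chr1", 1000, 1500, np.array([3, 3, 3, 3, 3, 3]))]
        m = standardize_log2_reads(COWS, regions)
        with pytest.raises(ValueError, match="degenerate"):
            permutation_null(m, design=CohortDesign.six_cow_default(), seed=0)

    def test_budget_arithmetic(self):
        assert permutation_budget(10, 48) == 480
        assert environmental_fdr_pool_size(10) == 30
        with pytest.raises(ValueError):
            permutation_budget(0)


class TestPvaluesAndFdr:
    def test_pvalue_reference_points(self):
        null = NullModel("case_control", 1.0, 0.02, 1000)
        assert dmr_pvalues(np.array([1.0]), null)[0] == pytest.approx(1.0)
        up = dmr_pvalues(np.array([1.0 + 1.959964 * 0.02]), null)[0]
        dn = dmr_pvalues(np.array([1.0 - 1.959964 * 0.02]), null)[0]
        assert up == pytest.approx(0.05, abs=1e-6)
        assert dn == pytest.approx(up)

    def test_degenerate_null_rejected(self):
        with pytest.raises(ValueError):
            dmr_pvalues(np.array([1.0]), NullModel("case_control", 1.0, 0.0, 10))

    def test_bh_by_hand(self):
        assert fdr_adjust([0.03]) == pytest.approx([0.03])
        assert fdr_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)
        assert fdr_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        # monotone in P-rank
        q = fdr_adjust([0.001, 0.5, 0.04, 0.9])
        order = np.argsort([0.001, 0.5, 0.04, 0.9])
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.2])
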