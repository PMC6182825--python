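import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from medipgmr.io_formats import DepthTrack, GeneModel
from medipgmr.methylation_stats import (
    chromosome_segment_stats,
    compute_gmr,
    cpg_site_coverage,
    find_cpg_islands,
    gene_density_correlation,
    gmr_track,
    normalized_reads_count,
    window_mean_gmr,
)


class TestComputeGmr:
    @pytest.mark.parametrize(
        "nr, expected",
        [
            ((1, 0, 0, 0, 0, 0), 1.0),               # single read anchors GMR at 1
            ((0, 0, 0, 0, 0, 0), 0.0),               # all-zero rule
            ((1, 1, 1, 1, 1, 1), 2 ** (5 / 6)),
            ((3, 3, 3, 3, 3, 3), 4 * 2 ** (-1 / 6)),
        ],
    )
    def test_reference_values(self, nr, expected):
        assert compute_gmr(nr) == pytest.approx(expected, abs=1e-12)

    def test_all_zero_is_exactly_zero(self):
        assert compute_gmr([0, 0, 0, 0, 0, 0]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            compute_gmr([])
        with pytest.raises(ValueError):
            compute_gmr([1, -1, 0, 0, 0, 0])

    @given(st.lists(st.integers(0, 50), min_size=2, max_size=8))
    def test_permutation_invariant(self, nr):
        rng = np.random.default_rng(0)
        shuffled = rng.permutation(nr)
        assert compute_gmr(nr) == pytest.approx(compute_gmr(shuffled))

    @given(
        st.lists(st.integers(0, 50), min_size=2, max_size=8),
        st.integers(0, 7),
    )
    def test_monotone_in_each_coordinate(self, nr, idx):
        idx = idx % len(nr)
        bumped = list(nr)
        bumped[idx] += 1
        assert compute_gmr(bumped) >= compute_gmr(nr)

    @given(st.integers(1, 100), st.integers(1, 8))
    def test_constant_vector_closed_form(self, x, k):
        assert compute_gmr([x] * k) == pytest.approx((x + 1) * 2 ** (-1 / k))

    def test_track_matches_scalar_and_zero_rule(self):
        matrix = np.array([[1, 0, 2], [0, 0, 5], [3, 0, 0]])
        values = gmr_track(matrix)
        assert values[1] == 0.0
        for j in (0, 2):
            assert values[j] == pytest.approx(compute_gmr(matrix[:, j]))


class TestNormalizedReadsCount:
    def test_values(self):
        assert normalized_reads_count(7, 7) == 1_000_000
        assert normalized_reads_count(0, 123) == 0
        assert normalized_reads_count(250, 50_000_000) == pytest.approx(5.0)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            normalized_reads_count(1, 0)


class TestWindows:
    def test_constant_track(self):
        df = window_mean_gmr(np.full(35, 2.5), "chr1", 10)
        assert np.allclose(df["mean_gmr"], 2.5)

    def test_hand_example_with_partial_window(self):
        track = np.zeros(25)
        track[:10] = 1.0
        df = window_mean_gmr(track, "chr1", 10)
        assert list(df["mean_gmr"]) == [1.0, 0.0, 0.0]
        assert list(df["end"] - df["start"]) == [10, 10, 5]

    @given(st.integers(1, 40), st.integers(2, 97))
    def test_conserves_track_mean(self, width, length):
        rng = np.random.default_rng(length * 100 + width)
        track = rng.random(length)
        df = window_mean_gmr(track, "chr1", width)
        w = (df["end"] - df["start"]).to_numpy()
        assert np.average(df["mean_gmr"], weights=w) == pytest.approx(track.mean())


class TestSegmentStats:
    def test_variance_heterogeneity_detected(self):
        rng = np.random.default_rng(1)
        sizes = {"chr1": 3_000_000}
        rows = []
        for start in range(0, 3_000_000, 10_000):
            in_end = start < 500_000 or start >= 2_500_000
            val = rng.normal(1.0, 1.0 if in_end else 0.05)
            rows.append(("chr1", start, start + 10_000, val))
        import pandas as pd

        windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_gmr"])
        cmp = chromosome_segment_stats(windows, sizes)
        var = cmp.variance_tests.set_index(["segment_a", "segment_b"])["p"]
        assert var[("centromeric", "middle")] < 0.001
        assert var[("middle", "distal")] < 0.001

    def test_location_shift_detected(self):
        rng = np.random.default_rng(2)
        sizes = {"chr1": 3_000_000}
        rows = []
        for start in range(0, 3_000_000, 10_000):
            shift = -0.25 if start < 500_000 else 0.0
            rows.append(("chr1", start, start + 10_000,
                         rng.normal(1.0 + shift, 0.3)))
        import pandas as pd

        windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "mean_gmr"])
        cmp = chromosome_segment_stats(windows, sizes)
        loc = cmp.location_tests.set_index(["segment_a", "segment_b"])["p"]
        assert loc[("centromeric", "middle")] < 0.05

    def test_short_chromosome_excluded_with_warning(self):
        import pandas as pd

        windows = pd.DataFrame(
            [("chrS", 0, 10_000, 1.0)],
            columns=["chrom", "start", "end", "mean_gmr"],
        )
        with pytest.warns(UserWarning, match="shorter"):
            cmp = chromosome_segment_stats(windows, {"chrS": 600_000})
        assert cmp.summary["n"].sum() == 0


class TestGeneDensityCorrelation:
    def _windows(self, values):
        import pandas as pd

        return pd.DataFrame(
            {
                "chrom": "chr1",
                "start": np.arange(len(values)) * 1000,
                "end": (np.arange(len(values)) + 1) * 1000,
                "mean_gmr": values,
            }
        )

    def test_monotone_relationship_gives_rho_one(self):
        windows = self._windows([0.1, 0.2, 0.3, 0.4])
        genes = []
        gid = 0
        for w, n in enumerate([0, 1, 2, 3]):
            for _ in range(n):
                s = w * 1000 + 10 * gid
                genes.append(GeneModel(f"g{gid}", "chr1", "+", [(s, s + 5)]))
                gid += 1
        rho, p, out = gene_density_correlation(windows, genes)
        assert rho == pytest.approx(1.0)
        assert list(out["n_genes"]) == [0, 1, 2, 3]

    def test_all_tied_flagged(self):
        windows = self._windows([1.0, 1.0, 1.0])
        with pytest.warns(UserWarning, match="tied"):
            rho, p, _ = gene_density_correlation(windows, [])
        assert np.isnan(rho)

    def test_too_few_windows_rejected(self):
        with pytest.raises(ValueError):
            gene_density_correlation(self._windows([1.0, 2.0]), [])


class TestContextCoverage:
    def _tracks(self, depths):
        return [DepthTrack("c1", "chr1", np.asarray(depths))]

    def test_full_depth_covers_all_cpg(self):
        seq = "CGCGCG"
        df = cpg_site_coverage(self._tracks([1] * 6), {"chr1": seq})
        assert df.loc[df.threshold == 1, "site_fraction"].item() == 1.0

    def test_zero_depth_covers_nothing(self):
        df = cpg_site_coverage(self._tracks([0] * 8), {"chr1": "ACGTACGT"})
        assert (df["site_fraction"] == 0).all()
        assert (df["genome_fraction"] == 0).all()

    def test_half_of_two_sites_at_depth_five(self):
        seq = "ACGTACGT"  # CpG sites start at 1 and 5
        depths = [0, 5, 5, 0, 0, 0, 0, 0]
        df = cpg_site_coverage(self._tracks(depths), {"chr1": seq})
        by_th = df.set_index("threshold")["site_fraction"]
        assert by_th[5] == 0.5
        assert by_th[1] == 0.5

    def test_fractions_monotone_in_threshold(self):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=400))
        depths = rng.integers(0, 8, size=400)
        df = cpg_site_coverage(self._tracks(depths), {"chr1": seq},
                               thresholds=(1, 3, 5))
        assert df["site_fraction"].is_monotonic_decreasing
        assert ((df["site_fraction"] >= 0) & (df["site_fraction"] <= 1)).all()

    def test_chg_context_counts_h_bases(self):
        # CAG at 0 is CHG; CGG at 4 is not (middle base G)
        seq = "CAGTCGGA"
        depths = [9] * 8
        df = cpg_site_coverage(self._tracks(depths), {"chr1": seq}, context="CHG")
        assert df.loc[df.threshold == 1, "site_fraction"].item() == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            cpg_site_coverage(self._tracks([1, 1]), {"chr1": "ACGT"})


class TestCpgIslands:
    def test_cg_repeat_is_one_island(self):
        assert find_cpg_islands("CG" * 100) == [(0, 200)]

    def test_poly_a_has_no_island(self):
        assert find_cpg_islands("A" * 200) == []

    def test_length_boundary(self):
        assert find_cpg_islands(("CG" * 100)[:199]) == []

    def test_island_embedded_in_at_background(self):
        seq = "AT" * 300 + "CG" * 150 + "AT" * 300
        islands = find_cpg_islands(seq)
        assert len(islands) == 1
        s, e = islands[0]
        # the island must cover the CG block; window merging may extend
        # at most one window beyond it on either side
        assert s <= 600 and e >= 900
        assert 600 - s < 200 and e - 900 < 200
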