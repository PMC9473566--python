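"""Epoch comparison statistics and zonal summaries.

The Kruskal-Wallis implementation is checked against an independent
brute-force oracle that ranks the pooled sample explicitly (midranks for
ties) and applies the tie-corrected H formula.
"""

import itertools

import numpy as np
import pytest

from nightshift.change import (
    GridView,
    compare_epochs,
    distribution_report,
    percent_change_of_medians,
    report_to_csv,
    zonal_summary,
)
from nightshift.raster import GridGeometry, RegionSet
from nightshift.scene import make_regions


def kruskal_oracle(*samples):
    """Brute-force tie-corrected Kruskal-Wallis H via explicit midranks."""
    pooled = np.concatenate(samples)
    n = pooled.size
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    i = 0
    while i < n:
        j = i
        while j < n and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + 1 + j)  # midrank of the tied block
        i = j
    h = 0.0
    start = 0
    for s in samples:
        r = ranks[start : start + s.size]
        h += r.sum() ** 2 / s.size
        start += s.size
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
    # tie correction
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - np.sum(counts**3 - counts) / (n**3 - n)
    if correction == 0:
        return float("nan")
    return h / correction


class TestCompareEpochs:
    def test_identical_samples_are_a_null_result(self):
        x = np.arange(1.0, 50.0)
        c = compare_epochs(x, x.copy())
        assert c.percent_change == 0.0
        assert c.kruskal_h == pytest.approx(0.0, abs=1e-9)
        assert c.p_value == pytest.approx(1.0)
        assert c.df == 1

    def test_shifted_sample_matches_brute_force_oracle(self):
        pre = np.arange(1.0, 1001.0)
        post = pre + 100.0
        c = compare_epochs(pre, post)
        # medians 500.5 -> 600.5 in closed form
        assert c.median_pre == 500.5
        assert c.median_post == 600.5
        assert c.percent_change == pytest.approx(100.0 / 500.5 * 100.0)
        assert c.kruskal_h == pytest.approx(kruskal_oracle(pre, post), abs=1e-9)

    def test_printed_style_medians_round_to_published_percent(self):
        # 10.59 -> 11.77 nW cm^-2 sr^-1 is an 11.1% increase
        assert round(percent_change_of_medians(10.59, 11.77), 1) == 11.1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compare_epochs(np.array([]), np.array([1.0]))

    def test_nonfinite_values_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            compare_epochs(np.array([1.0, np.nan]), np.array([1.0]))

    def test_degenerate_identical_values_warn(self):
        with pytest.warns(UserWarning, match="degenerate"):
            c = compare_epochs(np.ones(5), np.ones(7))
        assert c.kruskal_h == 0.0 and c.p_value == 1.0

    def test_exhaustive_small_samples_match_oracle(self):
        """All two-sample splits with values in {1,2,3} and pooled size <= 8
        agree with the brute-force midrank oracle to 1e-9."""
        checked = 0
        for n1 in range(1, 8):
            for n2 in range(1, 9 - n1):
                for v1 in itertools.combinations_with_replacement([1.0, 2.0, 3.0], n1):
                    for v2 in itertools.combinations_with_replacement(
                        [1.0, 2.0, 3.0], n2
                    ):
                        a, b = np.array(v1), np.array(v2)
                        if np.ptp(np.concatenate([a, b])) == 0:
                            continue  # degenerate: handled separately
                        c = compare_epochs(a, b)
                        assert c.kruskal_h == pytest.approx(
                            kruskal_oracle(a, b), abs=1e-9
                        )
                        checked += 1
        assert checked > 1000

    def test_median_and_iqr_invariant_under_permutation(self, rng):
        x = rng.normal(size=101)
        y = rng.normal(size=77)
        c1 = compare_epochs(x, y)
        c2 = compare_epochs(rng.permutation(x), rng.permutation(y))
        assert (c1.median_pre, c1.iqr_pre) == (c2.median_pre, c2.iqr_pre)
        assert c1.kruskal_h == pytest.approx(c2.kruskal_h)


class TestZonalSummary:
    GRID = GridGeometry.study_grid(shape=(40, 40))

    def grids(self, rng, delta=0.0):
        pre = rng.uniform(0.3, 0.7, self.GRID.shape)
        post = pre + delta
        valid = np.ones(self.GRID.shape, bool)
        return (
            GridView(pre, valid, self.GRID),
            GridView(post, valid, self.GRID),
        )

    def test_single_region_matches_epoch_comparison(self, rng):
        pre, post = self.grids(rng, delta=0.1)
        regions = make_regions(1, self.GRID, seed=0)
        table = zonal_summary(pre, post, regions, "median")
        c = compare_epochs(pre.values.ravel(), post.values.ravel())
        assert table.loc[0, "median_pre"] == pytest.approx(c.median_pre)
        assert table.loc[0, "median_post"] == pytest.approx(c.median_post)

    def test_region_without_valid_pixels_is_flagged_not_dropped(self, rng):
        pre, post = self.grids(rng)
        pre.valid[:] = False
        post.valid[:] = False
        regions = make_regions(3, self.GRID, seed=1)
        table = zonal_summary(pre, post, regions)
        assert len(table) == 3
        assert table["empty"].all()

    def test_partition_conserves_pixel_count(self, rng):
        pre, post = self.grids(rng)
        regions = make_regions(6, self.GRID, seed=2)
        table = zonal_summary(pre, post, regions)
        assert table["n_pixels"].sum() == pre.values.size
        assert table["n_valid_pre"].sum() == int(pre.valid.sum())

    def test_crs_mismatch_rejected(self, rng):
        pre, post = self.grids(rng)
        regions = make_regions(2, self.GRID, seed=3)
        bad = RegionSet(regions.names, regions.geometries, crs="EPSG:4326")
        with pytest.raises(ValueError, match="CRS"):
            zonal_summary(pre, post, bad)

    def test_three_unshifted_ranges_out_of_38_are_identified(self, rng):
        """38 overlapping species ranges, 35 constructed over the shifted
        area and 3 held at zero change: exactly those 3 show non-positive
        mean change."""
        regions = make_regions(38, self.GRID, seed=4, mode="ranges")
        exempt = ["species_005", "species_017", "species_030"]
        x, y = self.GRID.pixel_centers()
        from shapely import contains_xy

        exempt_mask = np.zeros(self.GRID.shape, bool)
        for name, poly in regions:
            if name in exempt:
                exempt_mask |= contains_xy(poly, x, y)
        pre = rng.uniform(0.3, 0.7, self.GRID.shape)
        delta = np.where(exempt_mask, 0.0, 0.08)
        valid = np.ones(self.GRID.shape, bool)
        table = zonal_summary(
            GridView(pre, valid, self.GRID),
            GridView(pre + delta, valid, self.GRID),
            regions,
            "mean",
        )
        nonpositive = set(table.loc[table["change"] <= 0, "region"])
        assert nonpositive == set(exempt)


class TestDistributionReport:
    def test_single_comparison_gives_single_row(self):
        c = compare_epochs(np.arange(10.0), np.arange(10.0) + 1)
        rep = distribution_report([c])
        assert len(rep["table"]) == 1

    def test_histogram_counts_conserve_sample_sizes(self, rng):
        pre, post = rng.normal(size=500), rng.normal(size=400)
        c = compare_epochs(pre, post, "q")
        rep = distribution_report([c], samples={"q": (pre, post)})
        h = rep["histograms"]["q"]
        assert h["counts_pre"].sum() == 500
        assert h["counts_post"].sum() == 400

    def test_report_is_deterministic(self, tmp_path, rng):
        pre, post = rng.normal(size=100), rng.normal(size=100)
        c = compare_epochs(pre, post, "q")
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        report_to_csv(distribution_report([c]), p1)
        report_to_csv(distribution_report([c]), p2)
        assert p1.read_bytes() == p2.read_bytes()


def test_epoch_histogram_plot_is_written(tmp_path, rng):
    from nightshift.change import plot_epoch_histograms

    pre, post = rng.normal(size=200), rng.normal(0.2, 1.0, size=250)
    c = compare_epochs(pre, post, "q")
    rep = distribution_report([c], samples={"q": (pre, post)})
    out = tmp_path / "hist.png"
    plot_epoch_histograms(rep, out)
    assert out.stat().st_size > 0
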