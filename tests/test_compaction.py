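"""Vicinity ratio R, fold change, and UP/DOWN region calling tests."""

import numpy as np
import pandas as pd
import pytest

from aneuhic import (
    BinnedContactMap,
    ChromSizes,
    ChromosomeClassification,
    GenomicIntervalSet,
    call_altered_regions,
    coverage_summary,
    local_ratio_track,
    ratio_fold_change,
)
from aneuhic.compaction import AlteredRegionSet, CompactionFoldChange
from conftest import random_contact_map

RES = 50_000
WINDOW = 1_000_000  # +-20 bins


def uniform_map(n_bins, fill=1.0, resolution=RES):
    cs = ChromSizes.from_dict({"chrU": n_bins * resolution})
    return BinnedContactMap(cs, resolution, np.full((n_bins, n_bins), fill))


def fc_from_vector(vec, resolution=RES):
    n = len(vec)
    cs = ChromSizes.from_dict({"chrU": n * resolution})
    bins = pd.DataFrame(
        {
            "chrom": "chrU",
            "start": np.arange(n) * resolution,
            "end": (np.arange(n) + 1) * resolution,
        }
    )
    return CompactionFoldChange(bins, np.asarray(vec, float), WINDOW, resolution, cs)


class TestLocalRatio:
    def test_uniform_interior_and_edge_values(self):
        """100 uniform bins, +-20-bin window: interior R=41/100, edge R=21/100."""
        track = local_ratio_track(uniform_map(100), WINDOW)
        assert track.R[50] == pytest.approx(0.41)
        assert track.R[0] == pytest.approx(0.21)
        assert track.R[99] == pytest.approx(0.21)

    def test_chromosome_inside_window_all_ones(self):
        track = local_ratio_track(uniform_map(21), WINDOW)
        assert np.allclose(track.R, 1.0)

    def test_resolution_must_divide_window(self):
        with pytest.raises(ValueError, match="divide"):
            local_ratio_track(uniform_map(30, resolution=30_000), WINDOW)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_double_loop(self, seed):
        rng = np.random.default_rng(seed)
        cmap = random_contact_map(rng, n_chroms=2, max_bins_per_chrom=100, resolution=RES)
        w = WINDOW // RES
        track = local_ratio_track(cmap, WINDOW)
        k = 0
        for chrom, sl in cmap.chrom_slices().items():
            block = cmap.counts[sl, sl]
            nb = block.shape[0]
            for i in range(nb):
                total = sum(block[i, j] for j in range(nb))
                near = sum(block[i, j] for j in range(nb) if abs(i - j) <= w)
                expected = near / total if total > 0 else np.nan
                if np.isnan(expected):
                    assert np.isnan(track.R[k])
                else:
                    assert track.R[k] == pytest.approx(expected, abs=1e-12)
                k += 1

    def test_invariant_to_global_rescaling(self):
        rng = np.random.default_rng(10)
        cmap = random_contact_map(rng, n_chroms=1, max_bins_per_chrom=80, resolution=RES)
        scaled = BinnedContactMap(cmap.chromsizes, RES, cmap.counts * 7.5)
        np.testing.assert_allclose(
            local_ratio_track(cmap, WINDOW).R, local_ratio_track(scaled, WINDOW).R
        )

    def test_zero_cis_bin_missing(self):
        cmap = uniform_map(30)
        cmap.counts[5, :] = 0.0
        cmap.counts[:, 5] = 0.0
        track = local_ratio_track(cmap, WINDOW)
        assert np.isnan(track.R[5])
        assert np.isfinite(track.R[6])


class TestRatioFoldChange:
    def test_identity_all_ones(self):
        t = local_ratio_track(uniform_map(50), WINDOW)
        fc = ratio_fold_change(t, t)
        assert np.allclose(fc.fc, 1.0)

    def test_missing_propagates(self):
        t = local_ratio_track(uniform_map(50), WINDOW)
        n = local_ratio_track(uniform_map(50), WINDOW)
        n.R[7] = np.nan
        fc = ratio_fold_change(t, n)
        assert np.isnan(fc.fc[7])

    def test_scaled_ratio(self):
        t = local_ratio_track(uniform_map(50), WINDOW)
        n = local_ratio_track(uniform_map(50), WINDOW)
        t2 = local_ratio_track(uniform_map(50), WINDOW)
        t2.R = n.R * 1.3
        fc = ratio_fold_change(t2, n)
        assert np.allclose(fc.fc, 1.3)

    def test_bin_table_mismatch_rejected(self):
        t = local_ratio_track(uniform_map(50), WINDOW)
        n = local_ratio_track(uniform_map(40), WINDOW)
        with pytest.raises(ValueError):
            ratio_fold_change(t, n)


class TestCallRegions:
    def test_worked_example(self):
        """[1.0,1.3,1.3,1.0,0.7,1.0,1.3]: one UP region over bins 1-2;
        singleton DOWN and trailing UP bins discarded."""
        regions = call_altered_regions(fc_from_vector([1.0, 1.3, 1.3, 1.0, 0.7, 1.0, 1.3]))
        assert len(regions) == 1
        row = regions.regions.iloc[0]
        assert row.direction == "UP"
        assert (row.start, row.end) == (RES, 3 * RES)
        assert row.mean_fc == pytest.approx(1.3)
        assert row.n_bins == 2
        assert len(regions.direction("DOWN")) == 0

    def test_gap_of_one_bin_merged(self):
        regions = call_altered_regions(fc_from_vector([1.3, 1.0, 1.3, 1.0]))
        assert len(regions) == 1
        row = regions.regions.iloc[0]
        assert (row.start, row.end) == (0, 3 * RES)
        assert row.n_bins == 2  # gap bin does not contribute

    def test_gap_of_two_bins_not_merged(self):
        regions = call_altered_regions(fc_from_vector([1.3, 1.0, 1.0, 1.3]))
        assert len(regions) == 0  # two singletons, both discarded

    def test_all_unchanged_empty(self):
        regions = call_altered_regions(fc_from_vector([1.0] * 10))
        assert len(regions) == 0

    def test_inverted_thresholds_rejected(self):
        with pytest.raises(ValueError, match="thresholds"):
            call_altered_regions(fc_from_vector([1.0] * 4), low=1.23, high=0.78)

    def test_nan_bins_act_as_gap_distance(self):
        vec = [1.3, np.nan, 1.3, 1.0]
        regions = call_altered_regions(fc_from_vector(vec))
        assert len(regions) == 1  # 1-bin (50 kb) gap still merges

    @pytest.mark.parametrize("seed", range(5))
    def test_region_invariants(self, seed):
        rng = np.random.default_rng(seed)
        vec = rng.choice([0.7, 1.0, 1.3], size=200, p=[0.15, 0.7, 0.15])
        regions = call_altered_regions(fc_from_vector(vec))
        df = regions.regions
        assert ((df["end"] - df["start"]) % RES == 0).all()
        assert (df["n_bins"] >= 2).all()
        assert ((df.loc[df.direction == "UP", "mean_fc"] > 1)).all()
        assert ((df.loc[df.direction == "DOWN", "mean_fc"] < 1)).all()
        # same-direction regions never overlap (merge rule closes them);
        # opposite-direction *spans* may interleave through gap bins, but a
        # single bin can never be a candidate for both directions
        for direction in ("UP", "DOWN"):
            sub = df[df.direction == direction].sort_values("start")
            assert (sub["start"].to_numpy()[1:] >= sub["end"].to_numpy()[:-1]).all()
        assert not ((vec >= 1.23) & (vec <= 0.78)).any()


def region_set(rows, cs):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end", "direction", "mean_fc", "n_bins"])
    return AlteredRegionSet(df, cs)


class TestCoverageSummary:
    def test_simple_percent(self):
        cs = ChromSizes.from_dict({"c1": 1_500_000, "c2": 1_000_000})
        cls = ChromosomeClassification.make({"c1"}, {"c2"})
        regions = region_set([("c1", 0, 150_000, "UP", 1.3, 3)], cs)
        cov = coverage_summary(regions, cs, cls)
        tab = cov.table.set_index("chrom")
        assert tab.loc["c1", "up_percent"] == pytest.approx(10.0)
        assert tab.loc["c2", "up_percent"] == 0.0

    def test_monotone_coverage_gives_perfect_group_correlation(self):
        sizes = {f"c{i}": 1_000_000 for i in range(8)}
        cs = ChromSizes.from_dict(sizes)
        cls = ChromosomeClassification.make({"c0", "c1", "c2", "c3"}, {"c4", "c5", "c6", "c7"})
        rows, clad_rows = [], []
        for i, c in enumerate(sizes):
            up_len = 50_000 * (i + 1)
            rows.append((c, 0, up_len, "UP", 1.3, up_len // RES))
            clad_rows.append((c, 0, 2 * up_len, "cLAD"))
        regions = region_set(rows, cs)
        clads = GenomicIntervalSet.from_records(clad_rows, cs)
        cov = coverage_summary(regions, cs, cls, clads)
        up_corr = cov.correlations.query("direction == 'UP'")
        assert np.allclose(up_corr["spearman_r"], 1.0)

    def test_empty_regions_zero_coverage_missing_correlations(self):
        cs = ChromSizes.from_dict({"c1": 1_000_000, "c2": 1_000_000})
        cls = ChromosomeClassification.make({"c1"}, {"c2"})
        clads = GenomicIntervalSet.from_records([("c1", 0, 100_000, "cLAD")], cs)
        cov = coverage_summary(region_set([], cs), cs, cls, clads)
        assert (cov.table[["up_percent", "down_percent"]] == 0).all().all()
        assert cov.correlations["spearman_r"].isna().all()


# -- property-based checks -----------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=40, deadline=None, derandomize=True)
@given(
    vec=st.lists(
        st.sampled_from([0.5, 0.7, 0.78, 1.0, 1.23, 1.3, 1.6]),
        min_size=3, max_size=120,
    )
)
def test_region_calling_structural_invariants(vec):
    regions = call_altered_regions(fc_from_vector(vec))
    df = regions.regions
    vec = np.asarray(vec)
    assert (df["n_bins"] >= 2).all()
    assert ((df["end"] - df["start"]) % RES == 0).all()
    # every region's member-bin count is consistent with candidates in span
    for row in df.itertuples(index=False):
        b0, b1 = row.start // RES, row.end // RES
        inside = vec[b0:b1]
        cand = (inside >= 1.23) if row.direction == "UP" else (inside <= 0.78)
        assert cand.sum() == row.n_bins
        assert cand[0] and cand[-1]  # spans start/end on candidate bins
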