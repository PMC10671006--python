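"""Contact-map I/O, subsampling, balancing, and expected-curve tests."""

import numpy as np
import pytest
from scipy import stats

from aneuhic import (
    BinnedContactMap,
    ChromSizes,
    balance,
    expected_cis,
    read_contact_map,
    subsample_to_depth,
    write_contact_map,
)
from conftest import random_contact_map


def write_triplet(tmp_path, body, chroms=(("chrA", 20_000),), resolution=10_000):
    lines = [f"#chromsizes\t{n}\t{l}" for n, l in chroms]
    lines.append(f"#resolution\t{resolution}")
    lines.extend(body)
    path = tmp_path / "map.tsv"
    path.write_text("\n".join(lines) + "\n")
    return path


class TestTripletIO:
    def test_single_pair_symmetrized(self, tmp_path):
        cmap = read_contact_map(write_triplet(tmp_path, ["0\t1\t5"]))
        assert cmap.counts[0, 1] == cmap.counts[1, 0] == 5
        assert cmap.counts[0, 0] == 0

    def test_empty_body_gives_zero_matrix(self, tmp_path):
        cmap = read_contact_map(write_triplet(tmp_path, [], chroms=(("chrA", 30_000),)))
        assert cmap.counts.shape == (3, 3)
        assert not cmap.counts.any()

    def test_out_of_range_bin_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="out of range"):
            read_contact_map(write_triplet(tmp_path, ["0\t2\t1"]))

    def test_conflicting_duplicates_rejected(self, tmp_path):
        with pytest.raises(ValueError, match="conflicting"):
            read_contact_map(write_triplet(tmp_path, ["0\t1\t5", "1\t0\t6"]))

    def test_wrong_resolution_unavailable(self, tmp_path):
        with pytest.raises(ValueError, match="resolution unavailable"):
            read_contact_map(write_triplet(tmp_path, []), resolution=5_000)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        cmap = random_contact_map(rng)
        path = tmp_path / "rt.tsv"
        write_contact_map(cmap, path)
        back = read_contact_map(path)
        assert back.chromsizes == cmap.chromsizes
        np.testing.assert_array_equal(back.counts, cmap.counts)

    def test_asymmetric_counts_rejected(self, toy_chromsizes):
        n = 80
        counts = np.zeros((n, n))
        counts[0, 1] = 3  # mirror missing
        with pytest.raises(ValueError, match="symmetric"):
            BinnedContactMap(toy_chromsizes, 10_000, counts)


class TestSubsample:
    def test_full_depth_returns_identical_map(self):
        rng = np.random.default_rng(1)
        cmap = random_contact_map(rng)
        total = int(cmap.total)
        sub = subsample_to_depth(cmap, total, seed=0)
        np.testing.assert_array_equal(sub.counts, cmap.counts)

    def test_total_exact_and_bounded_by_original(self):
        rng = np.random.default_rng(2)
        cmap = random_contact_map(rng)
        sub = subsample_to_depth(cmap, 100, seed=0)
        assert sub.total == 100
        assert (sub.counts <= cmap.counts).all()

    def test_deterministic_per_seed(self):
        rng = np.random.default_rng(3)
        cmap = random_contact_map(rng)
        a = subsample_to_depth(cmap, 100, seed=42)
        b = subsample_to_depth(cmap, 100, seed=42)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_single_pixel_only_outcome(self):
        cs = ChromSizes.from_dict({"chrA": 20_000})
        counts = np.array([[0.0, 50.0], [50.0, 0.0]])
        sub = subsample_to_depth(BinnedContactMap(cs, 10_000, counts), 20, seed=0)
        assert sub.counts[0, 1] == 20

    @pytest.mark.parametrize("bad_n", [-1, 10**9])
    def test_invalid_depth_rejected(self, bad_n):
        rng = np.random.default_rng(4)
        cmap = random_contact_map(rng)
        with pytest.raises(ValueError):
            subsample_to_depth(cmap, bad_n)

    def test_pixel_proportions_preserved(self):
        """Goodness-of-fit: subsampled pixel proportions match originals.

        Hypergeometric sampling has sub-multinomial variance, so a
        chi-square test at alpha=0.001 should essentially never reject.
        """
        rng = np.random.default_rng(5)
        cs = ChromSizes.from_dict({"chrA": 450_000})  # 45 bins -> ~1000 pixels
        upper = rng.integers(5, 50, size=(45, 45)).astype(float)
        counts = np.triu(upper) + np.triu(upper, 1).T
        cmap = BinnedContactMap(cs, 10_000, counts)
        iu = np.triu_indices(45)
        orig = cmap.counts[iu]
        p = orig / orig.sum()
        n = 20_000
        rejections = 0
        for seed in range(20):
            sub = subsample_to_depth(cmap, n, seed=seed)
            obs = sub.counts[iu]
            chi2 = ((obs - n * p) ** 2 / (n * p)).sum()
            if stats.chi2.sf(chi2, len(p) - 1) < 0.001:
                rejections += 1
        assert rejections == 0


def reference_iterative_correction(S, tol=1e-10, max_iter=10_000):
    """Independent fixed-point iteration oracle (no masking, positive marginals)."""
    n = S.shape[0]
    w = np.ones(n)
    for _ in range(max_iter):
        m = w * (S @ w)
        if m.std() / m.mean() <= tol:
            break
        w = w / (m / m.mean())
    return w / np.sqrt((w * (S @ w)).mean())


class TestBalance:
    def test_two_bin_trans_already_balanced(self):
        cs = ChromSizes.from_dict({"chrA": 10_000, "chrB": 10_000})
        cmap = BinnedContactMap(cs, 10_000, np.array([[0.0, 2.0], [2.0, 0.0]]))
        out = balance(cmap, "trans", mad_max=None)
        w = out.weights["trans"]
        m = w * (np.array([[0.0, 2.0], [2.0, 0.0]]) @ w)
        assert np.allclose(m, m[0])
        assert np.allclose(w, 1 / np.sqrt(2))

    def test_three_bin_cis_matches_reference_fixed_point(self):
        cs = ChromSizes.from_dict({"chrA": 30_000})
        S = np.array([[0.0, 4.0, 1.0], [4.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        out = balance(BinnedContactMap(cs, 10_000, S), "cis", tol=1e-10, mad_max=None)
        np.testing.assert_allclose(out.weights["cis"], reference_iterative_correction(S), rtol=1e-6)

    def test_zero_row_masked_others_converge(self):
        cs = ChromSizes.from_dict({"chrA": 40_000})
        S = np.zeros((4, 4))
        S[np.triu_indices(4, 1)] = 3.0
        S = S + S.T
        S[0, :] = S[:, 0] = 0.0
        out = balance(BinnedContactMap(cs, 10_000, S), "genomewide", mad_max=None)
        w = out.weights["genomewide"]
        assert np.isnan(w[0]) and np.isfinite(w[1:]).all()
        assert out.balance_info["genomewide"]["converged"]

    def test_marginal_cv_within_tol(self):
        rng = np.random.default_rng(7)
        cmap = random_contact_map(rng, positive=True)
        for mode in ("genomewide", "cis", "trans"):
            out = balance(cmap, mode, tol=1e-6)
            assert out.balance_info[mode]["cv"] <= 1e-6

    def test_doubling_counts_same_balanced_matrix_up_to_scale(self):
        rng = np.random.default_rng(8)
        cmap = random_contact_map(rng, positive=True)
        doubled = BinnedContactMap(cmap.chromsizes, cmap.resolution, cmap.counts * 2)
        a = balance(cmap, "genomewide", tol=1e-8).weighted_counts("genomewide")
        b = balance(doubled, "genomewide", tol=1e-8).weighted_counts("genomewide")
        ratio = b[a > 0] / a[a > 0]
        assert np.allclose(ratio, ratio.flat[0], rtol=1e-5)

    def test_all_zero_map_rejected(self, toy_chromsizes):
        n = 80
        cmap = BinnedContactMap(toy_chromsizes, 10_000, np.zeros((n, n)))
        with pytest.raises(ValueError, match="no unmasked bins"):
            balance(cmap, "genomewide")

    def test_non_convergence_warns_not_silent(self):
        rng = np.random.default_rng(9)
        cmap = random_contact_map(rng, positive=True)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            out = balance(cmap, "genomewide", tol=1e-14, max_iter=2)
        assert not out.balance_info["genomewide"]["converged"]


def brute_force_expected(cmap):
    """Per-offset mean over all intra-chromosomal pairs, by flat enumeration."""
    sums, counts = {}, {}
    for chrom, sl in cmap.chrom_slices().items():
        block = cmap.counts[sl, sl]
        nb = block.shape[0]
        for i in range(nb):
            for j in range(i + 1, nb):
                s = j - i
                sums[s] = sums.get(s, 0.0) + block[i, j]
                counts[s] = counts.get(s, 0) + 1
    return {s: sums[s] / counts[s] for s in sums}


class TestExpectedCis:
    def test_constant_off_diagonal(self):
        cs = ChromSizes.from_dict({"chrA": 50_000})
        counts = np.full((5, 5), 3.0)
        np.fill_diagonal(counts, 7.0)
        curve = expected_cis(BinnedContactMap(cs, 10_000, counts))
        assert np.allclose(curve.values, 3.0)

    def test_four_bin_diagonal_means(self):
        cs = ChromSizes.from_dict({"chrA": 40_000})
        counts = np.zeros((4, 4))
        for (i, j), v in {(0, 1): 3, (1, 2): 5, (2, 3): 7, (0, 2): 2, (1, 3): 4, (0, 3): 9}.items():
            counts[i, j] = counts[j, i] = v
        curve = expected_cis(BinnedContactMap(cs, 10_000, counts))
        np.testing.assert_allclose(curve.values, [5.0, 3.0, 9.0])
        np.testing.assert_array_equal(curve.separations, [10_000, 20_000, 30_000])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_maps(self, seed):
        rng = np.random.default_rng(seed)
        cmap = random_contact_map(rng)
        curve = expected_cis(cmap)
        expected = brute_force_expected(cmap)
        got = dict(zip(curve.separations // cmap.resolution, curve.values))
        assert set(got) == set(expected)
        for s, v in expected.items():
            assert got[s] == pytest.approx(v, abs=1e-12)

    def test_log_binned_aggregation_monotone_separations(self):
        rng = np.random.default_rng(11)
        cmap = random_contact_map(rng, n_chroms=1, max_bins_per_chrom=60)
        curve = expected_cis(cmap, log_bins=True)
        assert curve.aggregation == "log-binned"
        assert (np.diff(curve.separations) > 0).all()


class TestSymmetryPreservation:
    @pytest.mark.parametrize("seed", range(3))
    def test_operations_preserve_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        cmap = random_contact_map(rng, positive=True)
        sub = subsample_to_depth(cmap, int(cmap.total) // 2, seed=seed)
        np.testing.assert_array_equal(sub.counts, sub.counts.T)
        bal = balance(cmap, "genomewide")
        W = bal.weighted_counts("genomewide")
        np.testing.assert_array_equal(W, W.T)


# -- property-based checks -----------------------------------------------

from hypothesis import given, settings, strategies as st
from hypothesis.extra import numpy as hnp


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    upper=hnp.arrays(np.int64, (12, 12), elements=st.integers(0, 30)),
    frac=st.floats(0.1, 1.0),
)
def test_subsample_conserves_total_and_symmetry(upper, frac):
    cs = ChromSizes.from_dict({"chrA": 70_000, "chrB": 50_000})
    counts = np.triu(upper.astype(float)) + np.triu(upper.astype(float), 1).T
    cmap = BinnedContactMap(cs, 10_000, counts)
    total = int(cmap.total)
    n = int(total * frac)
    sub = subsample_to_depth(cmap, n, seed=0)
    assert sub.total == n
    np.testing.assert_array_equal(sub.counts, sub.counts.T)
    assert (sub.counts <= cmap.counts).all()
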