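"""Binned genome-wide Hi-C contact maps: I/O, subsampling, balancing, expected curves.

The on-disk matrix format is a plain-text triplet dialect (documented in the
README): header lines declare the chromosome table and resolution, body lines
give ``bin_i<TAB>bin_j<TAB>count`` for the upper triangle (any orientation is
accepted and symmetrized on read).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .genome import ChromSizes

__all__ = [
    "BinnedContactMap",
    "ExpectedCurve",
    "read_contact_map",
    "write_contact_map",
    "subsample_to_depth",
    "balance",
    "expected_cis",
]

BalanceMode = Literal["genomewide", "cis", "trans"]

_TRIU_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


def triu_indices_cached(n: int) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle (incl. diagonal) indices, cached per matrix size."""
    if n not in _TRIU_CACHE:
        if len(_TRIU_CACHE) > 8:
            _TRIU_CACHE.clear()
        _TRIU_CACHE[n] = np.triu_indices(n)
    return _TRIU_CACHE[n]


def symmetrize_upper(vals: np.ndarray, n: int) -> np.ndarray:
    """Dense symmetric matrix from an upper-triangle value vector."""
    iu = triu_indices_cached(n)
    out = np.zeros((n, n), dtype=np.float64)
    out[iu] = vals
    out.T[iu] = vals
    return out


def make_bin_table(chromsizes: ChromSizes, resolution: int) -> pd.DataFrame:
    """Tile each chromosome with half-open bins; the last bin may be short."""
    rows = []
    for name, length in chromsizes.items():
        starts = np.arange(0, length, resolution, dtype=np.int64)
        ends = np.minimum(starts + resolution, length)
        rows.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass
class BinnedContactMap:
    """Symmetric binned contact matrix with bin table and balancing weights.

    ``weights`` maps a balancing mode (genomewide / cis / trans) to a per-bin
    multiplicative correction vector; masked (filtered) bins carry NaN.
    """

    chromsizes: ChromSizes
    resolution: int
    counts: np.ndarray
    weights: dict[str, np.ndarray] = field(default_factory=dict)
    balance_info: dict[str, dict] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.float64)
        n = self.n_bins
        if self.counts.shape != (n, n):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match {n} bins"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be nonnegative")
        if not np.array_equal(self.counts, self.counts.T):
            # exact check is cheap; fall back to tolerance before rejecting
            if not np.allclose(self.counts, self.counts.T):
                raise ValueError("counts must be symmetric")

    # -- bin bookkeeping -------------------------------------------------
    @property
    def n_bins(self) -> int:
        return sum(-(-l // self.resolution) for l in self.chromsizes.lengths)

    @property
    def bins(self) -> pd.DataFrame:
        return make_bin_table(self.chromsizes, self.resolution)

    def chrom_slices(self) -> dict[str, slice]:
        out, offset = {}, 0
        for name, length in self.chromsizes.items():
            n = -(-length // self.resolution)
            out[name] = slice(offset, offset + n)
            offset += n
        return out

    def cis_mask_matrix(self) -> np.ndarray:
        """Boolean matrix, True where both bins lie on the same chromosome."""
        labels = np.repeat(
            np.arange(len(self.chromsizes)),
            [-(-l // self.resolution) for l in self.chromsizes.lengths],
        )
        return labels[:, None] == labels[None, :]

    @property
    def total(self) -> float:
        """Total contact sum counting each unordered bin pair (and the diagonal) once."""
        return float((self.counts.sum() + np.trace(self.counts)) / 2)

    def weighted_counts(self, mode: str | None = None) -> np.ndarray:
        """counts[i,j] * w_i * w_j; NaN on masked bins. mode=None returns raw counts."""
        if mode is None:
            return self.counts
        if mode not in self.weights:
            raise ValueError(f"no '{mode}' weights on this map; run balance() first")
        w = self.weights[mode]
        return self.counts * np.outer(w, w)

    def copy(self) -> "BinnedContactMap":
        return BinnedContactMap(
            self.chromsizes,
            self.resolution,
            self.counts.copy(),
            {k: v.copy() for k, v in self.weights.items()},
            {k: dict(v) for k, v in self.balance_info.items()},
        )

    @classmethod
    def from_dense(
        cls, chromsizes: ChromSizes, resolution: int, counts: np.ndarray
    ) -> "BinnedContactMap":
        return cls(chromsizes, resolution, counts)


# -- triplet TSV I/O -----------------------------------------------------

def read_contact_map(
    path: str | Path,
    resolution: int | None = None,
    chromsizes: ChromSizes | None = None,
) -> BinnedContactMap:
    """Read a triplet-TSV contact map.

    Header lines: ``#chromsizes<TAB>name<TAB>length`` (repeated) and
    ``#resolution<TAB>N``; body lines ``bin_i<TAB>bin_j<TAB>count``.
    A ``chromsizes`` argument overrides / replaces header chromsizes.
    """
    names, lengths = [], []
    file_resolution = None
    triplets: list[tuple[int, int, float]] = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#chromsizes"):
            _, name, length = line.split("\t")
            names.append(name)
            lengths.append(int(length))
        elif line.startswith("#resolution"):
            file_resolution = int(line.split("\t")[1])
        elif line.startswith("#"):
            continue
        else:
            i, j, c = line.split("\t")
            triplets.append((int(i), int(j), float(c)))

    if chromsizes is None:
        if not names:
            raise ValueError(f"{path}: no chromsizes header and none supplied")
        chromsizes = ChromSizes(tuple(names), tuple(lengths))
    if file_resolution is None and resolution is None:
        raise ValueError(f"{path}: resolution unavailable")
    if resolution is not None and file_resolution is not None and resolution != file_resolution:
        raise ValueError(
            f"{path}: resolution unavailable (file has {file_resolution}, requested {resolution})"
        )
    res = file_resolution if file_resolution is not None else resolution

    n = sum(-(-l // res) for l in chromsizes.lengths)
    counts = np.zeros((n, n))
    seen: dict[tuple[int, int], float] = {}
    for i, j, c in triplets:
        if not (0 <= i < n and 0 <= j < n):
            raise ValueError(f"{path}: bin index ({i},{j}) out of range for {n} bins")
        key = (min(i, j), max(i, j))
        if key in seen:
            if seen[key] != c:
                raise ValueError(
                    f"{path}: conflicting duplicate counts for bin pair {key}"
                )
            continue
        seen[key] = c
        counts[key[0], key[1]] = c
        counts[key[1], key[0]] = c
    return BinnedContactMap(chromsizes, res, counts)


def write_contact_map(cmap: BinnedContactMap, path: str | Path) -> None:
    """Write the upper triangle (nonzero pixels) as triplet TSV."""
    with open(path, "w") as fh:
        for name, length in cmap.chromsizes.items():
            fh.write(f"#chromsizes\t{name}\t{length}\n")
        fh.write(f"#resolution\t{cmap.resolution}\n")
        iu = triu_indices_cached(cmap.counts.shape[0])
        vals = cmap.counts[iu]
        nz = vals != 0
        for i, j, c in zip(iu[0][nz], iu[1][nz], vals[nz]):
            c = float(c)
            fh.write(f"{i}\t{j}\t{c:.10g}\n")


# -- subsampling ---------------------------------------------------------

def subsample_to_depth(
    cmap: BinnedContactMap,
    n: int,
    seed: int | np.random.Generator | None = None,
    method: Literal["hypergeometric", "multinomial"] = "hypergeometric",
) -> BinnedContactMap:
    """Downsample to exactly ``n`` total contacts (unordered pairs counted once).

    Default draws contacts without replacement (multivariate hypergeometric
    over pixels), matching read-subsampling semantics; ``multinomial`` is a
    faster with-replacement approximation.
    """
    if n < 0:
        raise ValueError("n must be nonnegative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    iu = triu_indices_cached(cmap.counts.shape[0])
    vals = cmap.counts[iu]
    total = vals.sum()
    if n > total:
        raise ValueError(f"requested depth {n} exceeds total {total:g}")
    if method == "hypergeometric":
        colors = np.round(vals).astype(np.int64)
        if not np.allclose(vals, colors):
            raise ValueError("hypergeometric subsampling requires integer counts")
        if n > colors.sum():
            raise ValueError(f"requested depth {n} exceeds total {colors.sum()}")
        new_vals = rng.multivariate_hypergeometric(colors, int(n), method="marginals")
    elif method == "multinomial":
        p = vals / total
        new_vals = rng.multinomial(int(n), p)
    else:
        raise ValueError(f"unknown method {method!r}")
    counts = symmetrize_upper(np.asarray(new_vals, dtype=np.float64), cmap.counts.shape[0])
    return BinnedContactMap(cmap.chromsizes, cmap.resolution, counts)


# -- balancing (iterative correction) ------------------------------------

def _mode_matrix(cmap: BinnedContactMap, mode: BalanceMode) -> np.ndarray:
    if mode == "genomewide":
        return cmap.counts
    cis = cmap.cis_mask_matrix()
    if mode == "cis":
        return np.where(cis, cmap.counts, 0.0)
    if mode == "trans":
        return np.where(cis, 0.0, cmap.counts)
    raise ValueError(f"unknown balance mode {mode!r}")


def balance(
    cmap: BinnedContactMap,
    mode: BalanceMode = "genomewide",
    tol: float = 1e-5,
    max_iter: int = 500,
    mad_max: float = 5.0,
) -> BinnedContactMap:
    """Iterative correction restricted to the pixels selected by ``mode``.

    Repeatedly divides weights by the (rescaled) weighted marginals until
    their coefficient of variation over unmasked bins drops below ``tol``.
    Bins with zero raw marginal, or whose log marginal falls more than
    ``mad_max`` MADs below the median, are masked (weight NaN). Returns a
    copy of the map carrying the new weight vector; non-convergence is
    recorded in ``balance_info`` and warned about, never silent.
    """
    S = _mode_matrix(cmap, mode)
    raw_marg = S.sum(axis=1)
    mask = raw_marg > 0
    if mad_max is not None and mask.any():
        # rescale by each chromosome's median marginal before the MAD rule,
        # so chromosomes with genuinely low overall coverage are not wiped out
        scaled = np.full_like(raw_marg, np.nan)
        for sl in cmap.chrom_slices().values():
            sub = raw_marg[sl]
            ok = mask[sl]
            if ok.any():
                scaled[sl] = sub / np.median(sub[ok])
        logm = np.log(scaled[mask])
        med = np.median(logm)
        mad = np.median(np.abs(logm - med))
        if mad > 0:
            mask[mask] &= logm >= med - mad_max * mad
    if not mask.any():
        raise ValueError("no unmasked bins; cannot balance")

    S = np.where(np.outer(mask, mask), S, 0.0)
    w = mask.astype(np.float64)
    cv = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        marg = w * (S @ w)
        m = marg[mask]
        mean = m.mean()
        cv = m.std() / mean
        if cv <= tol:
            break
        scale = marg / mean
        scale[~mask] = 1.0
        scale[scale == 0] = 1.0
        # damped update: full division can oscillate on decoupled cis blocks
        w = w / np.sqrt(scale)
    converged = cv <= tol
    if not converged:
        warnings.warn(
            f"{mode} balancing did not converge in {max_iter} iterations "
            f"(marginal CV {cv:.3g} > tol {tol:g})",
            RuntimeWarning,
        )
    # scale so the mean weighted marginal over unmasked bins is 1
    marg = w * (S @ w)
    mean = marg[mask].mean()
    if mean > 0:
        w = w / np.sqrt(mean)
    w = np.where(mask, w, np.nan)

    out = cmap.copy()
    out.weights[mode] = w
    out.balance_info[mode] = {"converged": bool(converged), "n_iter": n_iter, "cv": float(cv)}
    return out


# -- expected cis contact curve ------------------------------------------

@dataclass
class ExpectedCurve:
    """Mean cis contact frequency as a function of genomic separation."""

    separations: np.ndarray  # bp, strictly increasing
    values: np.ndarray
    aggregation: Literal["raw-diagonal", "log-binned"] = "raw-diagonal"

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"separation": self.separations, "value": self.values})


def expected_cis(
    cmap: BinnedContactMap,
    use_weights: BalanceMode | None = None,
    log_bins: bool = False,
    log_bin_ratio: float = 1.25,
) -> ExpectedCurve:
    """Average contact frequency per diagonal offset, pooled across chromosomes.

    The value at separation ``s * resolution`` is the mean (optionally
    weight-corrected) pixel value over all intra-chromosomal bin pairs at
    offset ``s >= 1``; masked bins are excluded from both numerator and
    denominator. With ``log_bins`` the raw diagonals are averaged within
    geometrically growing distance bins.
    """
    M = cmap.weighted_counts(use_weights)
    slices = cmap.chrom_slices()
    max_n = max(s.stop - s.start for s in slices.values())
    if max_n < 2:
        raise ValueError("need at least one chromosome with >= 2 bins")
    sums = np.zeros(max_n)
    counts = np.zeros(max_n)
    for sl in slices.values():
        block = M[sl, sl]
        nb = block.shape[0]
        for s in range(1, nb):
            d = np.diagonal(block, offset=s)
            valid = ~np.isnan(d)
            sums[s] += d[valid].sum()
            counts[s] += valid.sum()
    offsets = np.arange(1, max_n)
    have = counts[1:] > 0
    offsets = offsets[have]
    values = sums[1:][have] / counts[1:][have]
    pair_counts = counts[1:][have]

    if not log_bins:
        return ExpectedCurve(offsets * cmap.resolution, values, "raw-diagonal")

    edges = [1.0]
    while edges[-1] <= offsets[-1]:
        edges.append(max(edges[-1] * log_bin_ratio, edges[-1] + 1))
    edges = np.array(edges)
    idx = np.searchsorted(edges, offsets, side="right") - 1
    seps, vals = [], []
    for b in np.unique(idx):
        sel = idx == b
        wsum = pair_counts[sel].sum()
        vals.append((values[sel] * pair_counts[sel]).sum() / wsum)
        seps.append((offsets[sel] * pair_counts[sel]).sum() / wsum * cmap.resolution)
    return ExpectedCurve(np.array(seps), np.array(vals), "log-binned")
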