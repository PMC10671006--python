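"""Chromosome-level trans contact matrices and small/large cluster comparison.

Human chromosomes partition spatially into a gene-dense "small" cluster
(chr16-chr22) and a "large" cluster (chr1-chr15, chrX); trisomies shift
contact frequencies between and within these clusters. This module builds
the chromosome x chromosome mean interchromosomal contact matrix, the
trisomy/normal fold-change matrix (FCCF entries), and rank-based tests
comparing fold-change distributions between cluster pair groups.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BinnedContactMap
from .genome import ChromSizes

__all__ = [
    "ChromosomeClassification",
    "TransContactMatrix",
    "PairFoldChange",
    "ClusterComparisonResult",
    "trans_frequency_matrix",
    "pair_fold_change",
    "cluster_comparison",
]

HUMAN_SMALL = tuple(f"chr{i}" for i in range(16, 23))
HUMAN_LARGE = tuple(f"chr{i}" for i in range(1, 16)) + ("chrX",)
HUMAN_EXCLUDED = ("chrY", "chrM")


@dataclass(frozen=True)
class ChromosomeClassification:
    """Partition of chromosomes into small / large clusters plus exclusions."""

    small: frozenset[str]
    large: frozenset[str]
    excluded: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.small & self.large:
            raise ValueError("small and large sets overlap")

    @classmethod
    def make(cls, small, large, excluded=()) -> "ChromosomeClassification":
        return cls(frozenset(small), frozenset(large), frozenset(excluded))

    @classmethod
    def human_default(cls, extra_excluded=()) -> "ChromosomeClassification":
        """chr16-22 small; chr1-15 + chrX large; chrY/chrM always excluded."""
        return cls.make(HUMAN_SMALL, HUMAN_LARGE, set(HUMAN_EXCLUDED) | set(extra_excluded))

    def validate_cover(self, chromsizes: ChromSizes) -> None:
        missing = set(chromsizes.names) - (self.small | self.large | self.excluded)
        if missing:
            raise ValueError(f"chromosomes unclassified: {sorted(missing)}")

    def group_of(self, chrom: str) -> str:
        if chrom in self.excluded:
            return "excluded"
        if chrom in self.small:
            return "small"
        if chrom in self.large:
            return "large"
        raise KeyError(chrom)

    def pair_group(self, a: str, b: str) -> str | None:
        ga, gb = self.group_of(a), self.group_of(b)
        if "excluded" in (ga, gb):
            return None
        return {"smallsmall": "small-small", "largelarge": "large-large"}.get(
            ga + gb, "small-large"
        )


@dataclass
class _ChromMatrix:
    chromosomes: tuple[str, ...]
    values: np.ndarray  # symmetric, NaN diagonal / missing entries

    def __post_init__(self) -> None:
        n = len(self.chromosomes)
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match chromosome list")

    def index(self, chrom: str) -> int:
        return self.chromosomes.index(chrom)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        return float(self.values[self.index(pair[0]), self.index(pair[1])])

    def as_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.chromosomes, columns=self.chromosomes)

    def to_tsv(self, path) -> None:
        self.as_dataframe().to_csv(path, sep="\t", float_format="%.10g")


class TransContactMatrix(_ChromMatrix):
    """Mean interchromosomal contact frequency per chromosome pair."""


class PairFoldChange(_ChromMatrix):
    """Trisomy/normal ratio of mean trans contact frequency per pair."""


def trans_frequency_matrix(
    cmap: BinnedContactMap, weights_mode: str | None = "trans"
) -> TransContactMatrix:
    """Mean (weighted) pixel value over unmasked bin pairs for each chromosome pair.

    By default uses trans-only balancing weights; pass ``weights_mode=None``
    for raw counts (explicit opt-out).
    """
    M = cmap.weighted_counts(weights_mode)
    slices = cmap.chrom_slices()
    names = tuple(slices)
    n = len(names)
    values = np.full((n, n), np.nan)
    for (ia, a), (ib, b) in itertools.combinations(enumerate(names), 2):
        block = M[slices[a], slices[b]]
        valid = ~np.isnan(block)
        if valid.any():
            v = block[valid].mean()
        else:
            v = np.nan
            warnings.warn(f"all bin pairs masked for {a} x {b}", RuntimeWarning)
        values[ia, ib] = values[ib, ia] = v
    return TransContactMatrix(names, values)


def pair_fold_change(
    tr: TransContactMatrix,
    norm: TransContactMatrix,
    excluded: frozenset[str] | set[str] = frozenset(),
) -> PairFoldChange:
    """Elementwise trisomy/normal ratio; missing where either operand is 0 or missing."""
    keep_tr = [c for c in tr.chromosomes if c not in excluded]
    keep_no = [c for c in norm.chromosomes if c not in excluded]
    if set(keep_tr) != set(keep_no):
        raise ValueError("chromosome sets differ between the two matrices")
    names = tuple(keep_tr)
    it = [tr.index(c) for c in names]
    ino = [norm.index(c) for c in names]
    t = tr.values[np.ix_(it, it)]
    m = norm.values[np.ix_(ino, ino)]
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where((m > 0) & (t > 0), t / m, np.nan)
    np.fill_diagonal(fc, np.nan)
    return PairFoldChange(names, fc)


@dataclass
class ClusterComparisonResult:
    """Fold-change samples per pair group and rank tests between/within groups."""

    samples: dict[str, np.ndarray]
    tests: pd.DataFrame = field(default=None)  # contrast, statistic, p

    def p_value(self, contrast: str) -> float:
        row = self.tests[self.tests["contrast"] == contrast]
        return float(row["p"].iloc[0]) if len(row) else np.nan


GROUPS = ("small-small", "large-large", "small-large")


def cluster_comparison(
    fc: PairFoldChange, cls: ChromosomeClassification
) -> ClusterComparisonResult:
    """Partition unordered chromosome-pair fold changes by cluster group and test.

    Each group is tested against 1.0 (Wilcoxon signed-rank, two-sided) and
    groups are compared pairwise with two-sided Mann-Whitney U (exact
    distribution for small tie-free samples, normal approximation with tie
    correction otherwise). Excluded chromosomes contribute no pairs.
    """
    samples: dict[str, list[float]] = {g: [] for g in GROUPS}
    names = fc.chromosomes
    for (ia, a), (ib, b) in itertools.combinations(enumerate(names), 2):
        g = cls.pair_group(a, b)
        v = fc.values[ia, ib]
        if g is not None and np.isfinite(v):
            samples[g].append(float(v))
    arrays = {g: np.array(v) for g, v in samples.items()}

    rows = []
    for g, x in arrays.items():
        if len(x) >= 2 and np.any(x != 1.0):
            res = stats.wilcoxon(x - 1.0, alternative="two-sided")
            rows.append((f"{g} vs 1.0", float(res.statistic), float(res.pvalue)))
        elif len(x) >= 2:
            rows.append((f"{g} vs 1.0", np.nan, 1.0))
        else:
            rows.append((f"{g} vs 1.0", np.nan, np.nan))
    for ga, gb in itertools.combinations(GROUPS, 2):
        xa, xb = arrays[ga], arrays[gb]
        if len(xa) >= 2 and len(xb) >= 2:
            method = (
                "exact"
                if len(xa) <= 8 and len(xb) <= 8 and len(np.unique(np.concatenate([xa, xb]))) == len(xa) + len(xb)
                else "asymptotic"
            )
            res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
            rows.append((f"{ga} vs {gb}", float(res.statistic), float(res.pvalue)))
        else:
            rows.append((f"{ga} vs {gb}", np.nan, np.nan))
    tests = pd.DataFrame(rows, columns=["contrast", "statistic", "p"])
    return ClusterComparisonResult(arrays, tests)
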