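"""Local chromatin compaction: the vicinity ratio R and UP/DOWN region calling.

For each genomic bin, R is the fraction of the bin's cis contacts that fall
within a +-1 Mb vicinity — higher R means locally denser chromatin. The
trisomy/normal fold change of R is thresholded (defaults 0.78 / 1.23),
candidate bins within 50 kb of each other are merged per direction, and
single-bin clusters are discarded; each surviving region carries the mean
fold change of its member bins.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BinnedContactMap
from .genome import ChromSizes, GenomicIntervalSet
from .interchrom import ChromosomeClassification

__all__ = [
    "CompactionTrack",
    "CompactionFoldChange",
    "AlteredRegionSet",
    "local_ratio_track",
    "ratio_fold_change",
    "call_altered_regions",
    "coverage_summary",
]


@dataclass
class CompactionTrack:
    """Per-bin vicinity ratio R in [0, 1] (NaN where undefined)."""

    bins: pd.DataFrame  # chrom, start, end
    R: np.ndarray
    window_bp: int
    resolution: int
    chromsizes: ChromSizes

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for (row, v) in zip(self.bins.itertuples(index=False), self.R):
                if np.isfinite(v):
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{v:.6g}\n")


@dataclass
class CompactionFoldChange:
    """Per-bin trisomy/normal ratio of R."""

    bins: pd.DataFrame
    fc: np.ndarray
    window_bp: int
    resolution: int
    chromsizes: ChromSizes

    def to_bedgraph(self, path) -> None:
        with open(path, "w") as fh:
            for (row, v) in zip(self.bins.itertuples(index=False), self.fc):
                if np.isfinite(v):
                    fh.write(f"{row.chrom}\t{row.start}\t{row.end}\t{v:.6g}\n")


@dataclass
class AlteredRegionSet:
    """Merged UP (compacted) / DOWN (decompacted) regions."""

    regions: pd.DataFrame  # chrom, start, end, direction, mean_fc, n_bins
    chromsizes: ChromSizes

    COLUMNS = ("chrom", "start", "end", "direction", "mean_fc", "n_bins")

    def __len__(self) -> int:
        return len(self.regions)

    def direction(self, which: str) -> pd.DataFrame:
        return self.regions[self.regions["direction"] == which]

    def as_interval_set(self, direction: str | None = None) -> GenomicIntervalSet:
        df = self.regions if direction is None else self.direction(direction)
        return GenomicIntervalSet(
            df.rename(columns={"direction": "label"})[["chrom", "start", "end", "label"]],
            self.chromsizes,
        )

    def to_bed(self, path) -> None:
        """BED6: name=direction, score=mean_fc*100."""
        with open(path, "w") as fh:
            for row in self.regions.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\t{row.start}\t{row.end}\t{row.direction}"
                    f"\t{row.mean_fc * 100:.0f}\t.\n"
                )


def local_ratio_track(
    cmap: BinnedContactMap,
    window_bp: int = 1_000_000,
    use_weights: str | None = None,
) -> CompactionTrack:
    """Per-bin ratio of vicinity cis contacts to all cis contacts.

    R_i = sum of v(i, j) over same-chromosome j with |pos_j - pos_i| <=
    window_bp, divided by the bin's total cis contacts; the diagonal pixel
    enters both sums. Raw counts are the default — the ratio is self-
    normalized per bin, so balancing is unnecessary (available via
    ``use_weights="cis"``).
    """
    if window_bp % cmap.resolution != 0:
        raise ValueError("resolution must divide window_bp")
    w = window_bp // cmap.resolution
    M = cmap.weighted_counts(use_weights)
    R = np.full(cmap.n_bins, np.nan)
    for chrom, sl in cmap.chrom_slices().items():
        block = M[sl, sl]
        nb = block.shape[0]
        if nb < 1:
            warnings.warn(f"{chrom} shorter than one bin; skipped", RuntimeWarning)
            continue
        # row-wise sliding-window sums via cumulative sums
        nan = np.isnan(block)
        filled = np.where(nan, 0.0, block)  # masked pixels excluded from sums
        csum = np.zeros((nb, nb + 1))
        np.cumsum(filled, axis=1, out=csum[:, 1:])
        idx = np.arange(nb)
        lo = np.maximum(idx - w, 0)
        hi = np.minimum(idx + w, nb - 1) + 1
        near = csum[idx, hi] - csum[idx, lo]
        total = csum[:, -1]
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(total > 0, near / total, np.nan)
        r[nan.all(axis=1)] = np.nan  # masked bin itself
        R[sl] = r
    return CompactionTrack(cmap.bins, R, window_bp, cmap.resolution, cmap.chromsizes)


def ratio_fold_change(
    tr: CompactionTrack, norm: CompactionTrack
) -> CompactionFoldChange:
    """Per-bin tr.R / norm.R; missing where either side is missing."""
    if tr.window_bp != norm.window_bp or tr.resolution != norm.resolution:
        raise ValueError("window/resolution mismatch")
    if not tr.bins.equals(norm.bins):
        raise ValueError("bin tables differ")
    with np.errstate(invalid="ignore", divide="ignore"):
        fc = np.where(
            np.isfinite(tr.R) & np.isfinite(norm.R) & (norm.R > 0),
            tr.R / norm.R,
            np.nan,
        )
    return CompactionFoldChange(tr.bins, fc, tr.window_bp, tr.resolution, tr.chromsizes)


def call_altered_regions(
    fc: CompactionFoldChange,
    low: float = 0.78,
    high: float = 1.23,
    min_dist_bp: int = 50_000,
) -> AlteredRegionSet:
    """Threshold, merge, and filter altered-compaction regions.

    Bins with fold change >= ``high`` (UP) or <= ``low`` (DOWN) are
    candidates; within each direction, candidates whose genomic gap is at
    most ``min_dist_bp`` merge into one cluster; single-bin clusters are
    discarded. ``mean_fc`` averages the member candidate bins only (gap
    bins do not contribute).
    """
    if not (0 < low < 1 < high):
        raise ValueError(f"thresholds must satisfy 0 < low < 1 < high, got {low}, {high}")
    bins = fc.bins
    out = []
    for chrom, sub in bins.groupby("chrom", sort=False):
        idx = sub.index.to_numpy()
        vals = fc.fc[idx]
        for direction, cand in (
            ("UP", np.isfinite(vals) & (vals >= high)),
            ("DOWN", np.isfinite(vals) & (vals <= low)),
        ):
            where = np.flatnonzero(cand)
            if len(where) == 0:
                continue
            starts = sub["start"].to_numpy()[where]
            ends = sub["end"].to_numpy()[where]
            v = vals[where]
            cluster = [0]
            clusters = []
            for k in range(1, len(where)):
                if starts[k] - ends[cluster[-1]] <= min_dist_bp:
                    cluster.append(k)
                else:
                    clusters.append(cluster)
                    cluster = [k]
            clusters.append(cluster)
            for cl in clusters:
                if len(cl) < 2:  # singletons discarded
                    continue
                out.append(
                    (
                        chrom,
                        int(starts[cl[0]]),
                        int(ends[cl[-1]]),
                        direction,
                        float(v[cl].mean()),
                        len(cl),
                    )
                )
    df = pd.DataFrame(out, columns=list(AlteredRegionSet.COLUMNS))
    df = df.sort_values(["chrom", "start"]).reset_index(drop=True)
    return AlteredRegionSet(df, fc.chromsizes)


@dataclass
class CoverageSummary:
    table: pd.DataFrame  # chrom, group, up_percent, down_percent [, clad_percent]
    correlations: pd.DataFrame  # group, direction, spearman_r, p
    tests: pd.DataFrame  # direction, U, p (small vs large coverage)


def coverage_summary(
    regions: AlteredRegionSet,
    chromsizes: ChromSizes,
    cls: ChromosomeClassification,
    clads: GenomicIntervalSet | None = None,
) -> CoverageSummary:
    """Percent of each chromosome covered by UP/DOWN regions, with group stats.

    When a cLAD track is supplied, reports the Spearman correlation between
    UP coverage and cLAD coverage separately within the small and large
    chromosome groups, plus Mann-Whitney comparisons of coverage between
    groups.
    """
    rows = []
    for chrom, length in chromsizes.items():
        if chrom in cls.excluded:
            continue
        row = {"chrom": chrom, "group": cls.group_of(chrom)}
        for direction in ("UP", "DOWN"):
            iv = regions.as_interval_set(direction)
            row[f"{direction.lower()}_percent"] = 100.0 * iv.union_length(chrom) / length
        if clads is not None:
            row["clad_percent"] = 100.0 * clads.union_length(chrom) / length
        rows.append(row)
    table = pd.DataFrame(rows)

    corr_rows = []
    if clads is not None and len(table):
        for group in ("small", "large"):
            sub = table[table["group"] == group]
            for direction in ("UP", "DOWN"):
                x = sub[f"{direction.lower()}_percent"]
                y = sub["clad_percent"]
                if len(sub) >= 3 and x.nunique() > 1 and y.nunique() > 1:
                    r, p = stats.spearmanr(x, y)
                    corr_rows.append((group, direction, float(r), float(p)))
                else:
                    corr_rows.append((group, direction, np.nan, np.nan))
    correlations = pd.DataFrame(
        corr_rows, columns=["group", "direction", "spearman_r", "p"]
    )

    test_rows = []
    for direction in ("UP", "DOWN"):
        col = f"{direction.lower()}_percent"
        xs = table.loc[table["group"] == "small", col].to_numpy()
        xl = table.loc[table["group"] == "large", col].to_numpy()
        if len(xs) >= 2 and len(xl) >= 2 and (np.ptp(np.concatenate([xs, xl])) > 0):
            res = stats.mannwhitneyu(xs, xl, alternative="two-sided")
            test_rows.append((direction, float(res.statistic), float(res.pvalue)))
        else:
            test_rows.append((direction, np.nan, np.nan))
    tests = pd.DataFrame(test_rows, columns=["direction", "U", "p"])
    return CoverageSummary(table, correlations, tests)
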