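"""Interval-overlap profiles and permutation (shuffle) enrichment tests.

Altered-compaction regions are profiled against annotation tracks (cLADs,
A/B compartments) by the fraction of each region's length they cover, and
tested for gene enrichment by comparing the observed region x gene
intersection count against counts from length-preserving random placements.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .compaction import AlteredRegionSet
from .genome import ChromSizes, GenomicIntervalSet

__all__ = [
    "OverlapProfile",
    "EnrichmentResult",
    "overlap_profile",
    "count_intersections",
    "shuffle_enrichment",
    "chromosome_annotation_content",
]


def _region_frame(regions) -> pd.DataFrame:
    if isinstance(regions, AlteredRegionSet):
        return regions.regions[["chrom", "start", "end"]]
    if isinstance(regions, GenomicIntervalSet):
        return regions.df[["chrom", "start", "end"]]
    return pd.DataFrame(regions, columns=["chrom", "start", "end"])


@dataclass
class OverlapProfile:
    """Per-region fraction of length covered by a (merged) annotation."""

    fractions: np.ndarray  # one entry per region, in [0, 1]
    hist_counts: np.ndarray
    hist_edges: np.ndarray
    percent_none: float  # % of regions with fraction exactly 0
    percent_full: float  # % of regions with fraction exactly 1
    label: str | None = None


def overlap_profile(
    regions,
    annotation: GenomicIntervalSet,
    label: str | None = None,
    n_hist_bins: int = 10,
) -> OverlapProfile:
    """Fraction of each region covered by the union of annotation intervals.

    Overlapping annotation intervals are merged first, so the fraction is
    invariant to how the annotation is split into abutting pieces.
    """
    ann = annotation if label is None else annotation.filter_label(label)
    df = _region_frame(regions)
    fractions = np.array(
        [
            ann.overlap_bp(row.chrom, row.start, row.end) / (row.end - row.start)
            for row in df.itertuples(index=False)
        ]
    )
    edges = np.linspace(0.0, 1.0, n_hist_bins + 1)
    counts, _ = np.histogram(fractions, bins=edges) if len(fractions) else (np.zeros(n_hist_bins, int), edges)
    pct_none = 100.0 * np.mean(fractions == 0.0) if len(fractions) else np.nan
    pct_full = 100.0 * np.mean(fractions == 1.0) if len(fractions) else np.nan
    return OverlapProfile(fractions, counts, edges, pct_none, pct_full, label)


def count_intersections(regions, genes: GenomicIntervalSet) -> int:
    """Number of (region, gene) pairs sharing at least 1 bp.

    Genes are *not* merged: nested or overlapping genes are each counted.
    """
    df = _region_frame(regions)
    total = 0
    for chrom, sub in df.groupby("chrom", sort=False):
        gs, ge = genes.chrom_arrays(chrom)
        if len(gs) == 0:
            continue
        starts_sorted = np.sort(gs)
        ends_sorted = np.sort(ge)
        rs = sub["start"].to_numpy()
        re = sub["end"].to_numpy()
        # genes overlapping [rs, re): start < re and end > rs
        n_start_before_end = np.searchsorted(starts_sorted, re, side="left")
        n_end_before_start = np.searchsorted(ends_sorted, rs, side="right")
        total += int((n_start_before_end - n_end_before_start).sum())
    return total


@dataclass
class EnrichmentResult:
    observed: int
    null: np.ndarray
    p_enrich: float
    p_deplete: float
    n_iterations: int

    @property
    def null_mean(self) -> float:
        return float(self.null.mean())

    @property
    def null_std(self) -> float:
        return float(self.null.std(ddof=1)) if len(self.null) > 1 else np.nan

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "observed": [self.observed],
                "null_mean": [self.null_mean],
                "null_std": [self.null_std],
                "p_enrich": [self.p_enrich],
                "p_deplete": [self.p_deplete],
                "n_iterations": [self.n_iterations],
            }
        )


def _shuffle_once(
    lengths: np.ndarray,
    chrom_idx: np.ndarray,
    chrom_lengths: np.ndarray,
    rng: np.random.Generator,
    mode: str,
    max_rounds: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Place regions uniformly at random, lengths preserved, no self-overlap.

    Returns (chromosome index, start) arrays. Placement is batched: all
    regions are drawn at once, then overlapping ones are redrawn until the
    placement is overlap-free (rejection sampling).
    """
    m = len(lengths)
    restricted = False  # some chromosomes too short for some regions
    if mode == "chrom":
        ci = chrom_idx.copy()
        if (chrom_lengths[ci] < lengths).any():
            raise ValueError("a region exceeds its own chromosome")
    else:
        fits = chrom_lengths[None, :] >= lengths[:, None]
        if (~fits.any(axis=1)).any():
            raise ValueError("a region exceeds every chromosome")
        restricted = bool((~fits).any())
        if restricted:
            ci = np.empty(m, dtype=np.int64)
            for k in range(m):
                cand = np.flatnonzero(fits[k])
                w = chrom_lengths[cand] / chrom_lengths[cand].sum()
                ci[k] = cand[rng.choice(len(cand), p=w)]
        else:
            p = chrom_lengths / chrom_lengths.sum()
            ci = rng.choice(len(chrom_lengths), size=m, p=p)
    starts = rng.integers(0, chrom_lengths[ci] - lengths + 1)

    for _ in range(max_rounds):
        # sort by (chrom, start) and flag regions overlapping a predecessor
        order = np.lexsort((starts, ci))
        cs, ss, ls = ci[order], starts[order], lengths[order]
        bad_sorted = np.zeros(m, dtype=bool)
        run_end = np.int64(-1)
        run_chrom = np.int64(-1)
        for k in range(m):
            if cs[k] != run_chrom:
                run_chrom, run_end = cs[k], ss[k] + ls[k]
            elif ss[k] < run_end:
                bad_sorted[k] = True
            else:
                run_end = ss[k] + ls[k]
        bad = np.zeros(m, dtype=bool)
        bad[order] = bad_sorted
        if not bad.any():
            return ci, starts
        if mode != "chrom":
            if restricted:
                for k in np.flatnonzero(bad):
                    cand = np.flatnonzero(chrom_lengths >= lengths[k])
                    w = chrom_lengths[cand] / chrom_lengths[cand].sum()
                    ci[k] = cand[rng.choice(len(cand), p=w)]
            else:
                p = chrom_lengths / chrom_lengths.sum()
                ci[bad] = rng.choice(len(chrom_lengths), size=int(bad.sum()), p=p)
        starts[bad] = rng.integers(0, chrom_lengths[ci[bad]] - lengths[bad] + 1)
    raise RuntimeError("could not place regions without self-overlap")


def shuffle_enrichment(
    regions,
    genes: GenomicIntervalSet,
    chromsizes: ChromSizes,
    n: int = 1000,
    seed: int | np.random.Generator | None = None,
    mode: str = "genome",
) -> EnrichmentResult:
    """Empirical enrichment of region-gene intersections under random placement.

    ``mode="genome"`` relocates each region anywhere (chromosome chosen with
    probability proportional to length among those long enough);
    ``mode="chrom"`` keeps each region on its own chromosome. Empirical
    p-values use the add-one rule, p = (1 + #{null >= observed}) / (n + 1),
    so they are never zero.
    """
    if n < 1:
        raise ValueError("need at least 1 shuffle iteration")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    df = _region_frame(regions)
    lengths = (df["end"] - df["start"]).to_numpy()
    names = list(chromsizes.names)
    chrom_idx = np.array([names.index(c) for c in df["chrom"]], dtype=np.int64)
    chrom_lengths = np.array(chromsizes.lengths, dtype=np.int64)
    # per-chromosome sorted gene endpoints, extracted once
    gene_arrays = []
    for c in names:
        gs, ge = genes.chrom_arrays(c)
        gene_arrays.append((np.sort(gs), np.sort(ge)))

    def _count(ci: np.ndarray, starts: np.ndarray) -> int:
        total = 0
        ends = starts + lengths
        for k in np.unique(ci):
            ss, ee = gene_arrays[k]
            if len(ss) == 0:
                continue
            sel = ci == k
            total += int(
                (
                    np.searchsorted(ss, ends[sel], side="left")
                    - np.searchsorted(ee, starts[sel], side="right")
                ).sum()
            )
        return total

    observed = _count(chrom_idx, df["start"].to_numpy())
    null = np.empty(n, dtype=np.int64)
    for it in range(n):
        ci, starts = _shuffle_once(lengths, chrom_idx, chrom_lengths, rng, mode)
        null[it] = _count(ci, starts)
    p_enrich = (1 + int((null >= observed).sum())) / (n + 1)
    p_deplete = (1 + int((null <= observed).sum())) / (n + 1)
    return EnrichmentResult(observed, null, p_enrich, p_deplete, n)


def chromosome_annotation_content(
    annotation: GenomicIntervalSet, chromsizes: ChromSizes
) -> pd.Series:
    """Percent of each chromosome covered by the annotation union."""
    return annotation.coverage_percent(chromsizes)
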