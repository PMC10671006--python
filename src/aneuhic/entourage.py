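"""Chromosome-entourage (CE) statistics.

A chromosome's entourage is its spectrum of trans contact frequencies with
all other chromosomes. For each focal chromosome we correlate (Spearman) its
normal-karyotype trans frequencies against the trisomy/normal fold changes
(FCCF): a significant positive r means the entourage is *enforced* (close
partners get relatively closer), a significant negative r means *reversal*.
Non-significant r with high FCCF dispersion (above the third quartile of a
normal-vs-normal baseline) is called *stochastic*; otherwise *unchanged*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .interchrom import ChromosomeClassification, PairFoldChange, TransContactMatrix, pair_fold_change

__all__ = [
    "FCCFProfile",
    "EntourageResult",
    "DispersionBaseline",
    "fccf_profile",
    "ce_correlation",
    "fccf_dispersion",
    "dispersion_baseline",
    "ce_classify",
    "analyze_entourage",
]

CATEGORIES = ("enforced", "reversed", "stochastic", "unchanged")


@dataclass
class FCCFProfile:
    """Aligned per-partner (normal trans frequency, fold change) vectors."""

    focal: str
    partners: tuple[str, ...]
    normal_freqs: np.ndarray
    fccf: np.ndarray

    def __post_init__(self) -> None:
        if not (len(self.partners) == len(self.normal_freqs) == len(self.fccf)):
            raise ValueError("partner/value vectors misaligned")

    @property
    def n(self) -> int:
        return len(self.partners)


@dataclass
class EntourageResult:
    focal: str
    r: float  # NaN when undefined (constant ranks)
    p: float
    dispersion: float
    category: str


@dataclass
class DispersionBaseline:
    """Pooled FCCF dispersions from pairwise normal-vs-normal comparisons."""

    dispersions: pd.DataFrame  # columns: sample_a, sample_b, chrom, dispersion
    threshold: float  # Q3 (linear-interpolation quantile) of the pooled set
    per_chromosome: dict[str, float] | None = None


def fccf_profile(
    norm: TransContactMatrix,
    fc: PairFoldChange,
    focal: str,
    cls: ChromosomeClassification,
) -> FCCFProfile:
    """Extract the focal chromosome's aligned (normal freq, fold change) vectors.

    Partners with a missing frequency or fold change are dropped from both
    vectors; fewer than 3 surviving partners is an error.
    """
    if focal in cls.excluded:
        raise ValueError(f"focal chromosome {focal} is excluded")
    if focal not in norm.chromosomes or focal not in fc.chromosomes:
        raise ValueError(f"focal chromosome {focal} absent from input matrices")
    partners, freqs, folds = [], [], []
    for p in fc.chromosomes:
        if p == focal or p in cls.excluded or p not in norm.chromosomes:
            continue
        f = norm[focal, p]
        g = fc[focal, p]
        if np.isfinite(f) and np.isfinite(g):
            partners.append(p)
            freqs.append(f)
            folds.append(g)
    if len(partners) < 3:
        raise ValueError(f"{focal}: fewer than 3 valid partners")
    return FCCFProfile(focal, tuple(partners), np.array(freqs), np.array(folds))


def _spearman_r(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)  # mid-ranks for ties
    ry = stats.rankdata(y)
    if np.all(rx == rx[0]) or np.all(ry == ry[0]):
        return np.nan
    return float(np.corrcoef(rx, ry)[0, 1])


def ce_correlation(
    profile: FCCFProfile, exact_max_n: int = 9
) -> tuple[float, float]:
    """Spearman r between normal frequencies and FCCF, with two-sided p.

    Exact permutation p (all n! rank permutations) for n <= ``exact_max_n``;
    t approximation otherwise. Constant vectors give (nan, nan).
    """
    x, y = profile.normal_freqs, profile.fccf
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 partners")
    r = _spearman_r(x, y)
    if np.isnan(r):
        return np.nan, np.nan
    if n <= exact_max_n:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rx = (rx - rx.mean()) / rx.std()
        ry = (ry - ry.mean()) / ry.std()
        perms = np.array(list(itertools.permutations(range(n))))
        r_null = (rx[perms] * ry).sum(axis=1) / n
        p = float(np.mean(np.abs(r_null) >= np.abs(r) - 1e-12))
    else:
        t = r * np.sqrt((n - 2) / (1 - r * r)) if abs(r) < 1 else np.inf * np.sign(r)
        p = float(2 * stats.t.sf(np.abs(t), n - 2))
    return r, p


def fccf_dispersion(profile: FCCFProfile | np.ndarray) -> float:
    """Sample variance (ddof=1) of the fold-change vector."""
    y = profile.fccf if isinstance(profile, FCCFProfile) else np.asarray(profile, float)
    if len(y) < 2:
        raise ValueError("need at least 2 fold changes")
    return float(np.var(y, ddof=1))


def dispersion_baseline(
    normal_maps: list[TransContactMatrix],
    cls: ChromosomeClassification,
    per_chromosome: bool = False,
) -> DispersionBaseline:
    """Q3 threshold from all pairwise normal-vs-normal FCCF dispersions.

    Every unordered pair of normal samples is compared once (first over
    second, in list order); dispersions are pooled over chromosomes by
    default, with a per-chromosome option.
    """
    if len(normal_maps) < 2:
        raise ValueError("need at least 2 normal samples for a baseline")
    rows = []
    for (ia, ma), (ib, mb) in itertools.combinations(enumerate(normal_maps), 2):
        fc = pair_fold_change(ma, mb, cls.excluded)
        for chrom in fc.chromosomes:
            if chrom in cls.excluded:
                continue
            try:
                prof = fccf_profile(ma, fc, chrom, cls)
            except ValueError:
                continue
            rows.append((ia, ib, chrom, fccf_dispersion(prof)))
    df = pd.DataFrame(rows, columns=["sample_a", "sample_b", "chrom", "dispersion"])
    threshold = float(np.quantile(df["dispersion"], 0.75))  # type-7 linear interpolation
    per_chrom = None
    if per_chromosome:
        per_chrom = {
            c: float(np.quantile(g["dispersion"], 0.75))
            for c, g in df.groupby("chrom")
        }
    return DispersionBaseline(df, threshold, per_chrom)


def ce_classify(
    r: float,
    p: float,
    dispersion: float,
    baseline: DispersionBaseline | float | None,
    alpha: float = 0.05,
    chrom: str | None = None,
) -> str:
    """Apply the CE decision rule.

    Significant positive r -> enforced; significant negative -> reversed;
    otherwise stochastic if the dispersion exceeds the baseline threshold,
    else unchanged. Without a baseline only enforced/reversed/unchanged are
    reachable.
    """
    if np.isfinite(r) and np.isfinite(p) and p < alpha:
        if r > 0:
            return "enforced"
        if r < 0:
            return "reversed"
    if baseline is None:
        return "unchanged"
    if isinstance(baseline, DispersionBaseline):
        thr = baseline.threshold
        if chrom is not None and baseline.per_chromosome:
            thr = baseline.per_chromosome.get(chrom, baseline.threshold)
    else:
        thr = float(baseline)
    return "stochastic" if dispersion > thr else "unchanged"


def analyze_entourage(
    norm: TransContactMatrix,
    fc: PairFoldChange,
    cls: ChromosomeClassification,
    baseline: DispersionBaseline | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-chromosome CE report: r, p, dispersion, category (ranked by signed r)."""
    rows = []
    for chrom in fc.chromosomes:
        if chrom in cls.excluded:
            continue
        try:
            prof = fccf_profile(norm, fc, chrom, cls)
        except ValueError:
            continue
        r, p = ce_correlation(prof)
        d = fccf_dispersion(prof)
        cat = ce_classify(r, p, d, baseline, alpha, chrom=chrom)
        rows.append((chrom, r, p, d, cat))
    df = pd.DataFrame(rows, columns=["chrom", "r", "p", "dispersion", "category"])
    return df.sort_values("r", ascending=False, na_position="last").reset_index(drop=True)
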