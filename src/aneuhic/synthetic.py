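"""Synthetic Hi-C study generator with machine-readable ground truth.

Emulates the features the analysis stages consume: power-law cis contact
decay, A/B compartment checkerboard, chromosome-pair trans affinities with
an elevated small-small cluster, trisomy dosage (1.5x one chromosome's cis
and trans rates), per-chromosome entourage perturbations (enforced /
reversed / stochastic), and injected local compaction changes. Pixel counts
are independent Poisson draws around the expected-rate matrix (negative
binomial over-dispersion available), symmetrized, scaled to a requested
sequencing depth.

Donor-level biological variability is modeled as a per-pair lognormal
jitter on trans affinities; a trisomy map shares its matched control's
jitter (comparisons within one genetic background), whereas baseline
normal-vs-normal comparisons pair different donors and therefore carry the
jitter in their dispersion — this is what makes the third-quartile
dispersion threshold meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .contacts import BinnedContactMap, symmetrize_upper, triu_indices_cached
from .genome import ChromSizes, GenomicIntervalSet
from .interchrom import ChromosomeClassification

__all__ = [
    "SyntheticGenomeSpec",
    "ContactModelParams",
    "CEPerturbation",
    "PerturbationPlan",
    "GroundTruth",
    "Genome",
    "generate_genome",
    "build_affinity",
    "expected_matrix",
    "simulate_contact_map",
    "simulate_study",
    "score_region_recovery",
    "score_ce_recovery",
]

DEFAULT_LENGTHS = {
    "chrS1": 20_000_000,
    "chrS2": 18_000_000,
    "chrS3": 16_000_000,
    "chrS4": 14_000_000,
    "chrS5": 12_000_000,
    "chrS6": 10_000_000,
    "chrS7": 8_000_000,
    "chrS8": 6_000_000,
    "chrS9": 4_000_000,
    "chrS10": 2_500_000,
}


@dataclass
class SyntheticGenomeSpec:
    """Toy genome layout: chromosome lengths, annotation densities, clusters."""

    chrom_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LENGTHS))
    resolution: int = 50_000
    compartment_mean_segment: int = 1_500_000
    compartment_min_segment: int = 500_000
    clad_coverage: dict[str, float] | float = 0.25  # fraction of chromosome length
    gene_density_base: float = 8.0  # genes per Mb on a cLAD-free chromosome
    gene_mean_length: int = 30_000
    housekeeping_fraction: float = 0.15
    n_small: int = 4  # the n shortest chromosomes form the "small" cluster

    def __post_init__(self) -> None:
        for name, L in self.chrom_lengths.items():
            if L < 2 * self.resolution:
                raise ValueError(f"{name}: length must be >= 2 x resolution")
        for c, v in self.clad_coverage_map().items():
            if not 0 <= v <= 1:
                raise ValueError(f"{c}: cLAD coverage {v} outside [0, 1]")

    def clad_coverage_map(self) -> dict[str, float]:
        if isinstance(self.clad_coverage, dict):
            return dict(self.clad_coverage)
        return {c: float(self.clad_coverage) for c in self.chrom_lengths}

    def chromsizes(self) -> ChromSizes:
        return ChromSizes.from_dict(self.chrom_lengths)

    def classification(self) -> ChromosomeClassification:
        ordered = sorted(self.chrom_lengths, key=self.chrom_lengths.__getitem__)
        small = set(ordered[: self.n_small])
        large = set(self.chrom_lengths) - small
        return ChromosomeClassification.make(small, large)


@dataclass
class Genome:
    """A generated toy genome with its annotation tracks."""

    spec: SyntheticGenomeSpec
    chromsizes: ChromSizes
    compartments: GenomicIntervalSet  # labels "A"/"B"
    clads: GenomicIntervalSet
    genes: GenomicIntervalSet
    housekeeping: GenomicIntervalSet
    classification: ChromosomeClassification


def generate_genome(spec: SyntheticGenomeSpec, seed: int | None = None) -> Genome:
    """Sample compartments, cLADs, and gene tracks for the toy genome.

    Compartment labels alternate A/B in exponential-length segments; cLADs
    are sub-intervals of B segments hitting the requested per-chromosome
    coverage; genes scatter uniformly with density anti-correlated with
    cLAD coverage (gene-poor chromosomes are lamina-rich, as in the human
    karyotype). Deterministic for a fixed seed.
    """
    rng = np.random.default_rng(seed)
    cs = spec.chromsizes()
    res = spec.resolution
    cov_map = spec.clad_coverage_map()

    comp_rows, clad_rows, gene_rows = [], [], []
    gene_id = 0
    for chrom, length in cs.items():
        # compartment segmentation
        label = "A" if rng.random() < 0.5 else "B"
        pos = 0
        segments = []
        while pos < length:
            seg = spec.compartment_min_segment + rng.exponential(
                max(spec.compartment_mean_segment - spec.compartment_min_segment, 1)
            )
            seg = int(round(seg / res)) * res
            seg = max(seg, res)
            end = min(pos + seg, length)
            segments.append((pos, end, label))
            comp_rows.append((chrom, pos, end, label))
            label = "B" if label == "A" else "A"
            pos = end

        # cLADs inside B segments
        b_segs = [(s, e) for s, e, l in segments if l == "B"]
        b_total = sum(e - s for s, e in b_segs)
        target = cov_map[chrom] * length
        if b_total > 0 and target > 0:
            q = min(target / b_total, 1.0)
            for s, e in b_segs:
                take = int(round(q * (e - s) / res)) * res
                if take <= 0:
                    continue
                take = min(take, e - s)
                offset = int(rng.integers(0, (e - s - take) // res + 1)) * res
                clad_rows.append((chrom, s + offset, s + offset + take, "cLAD"))

        # genes: density shrinks with cLAD coverage
        density = spec.gene_density_base * max(1.0 - 2.0 * cov_map[chrom], 0.1)
        n_genes = int(round(density * length / 1e6))
        for _ in range(n_genes):
            glen = int(
                np.clip(rng.lognormal(np.log(spec.gene_mean_length), 0.6), 2_000, length / 2)
            )
            start = int(rng.integers(0, length - glen + 1))
            gene_rows.append((chrom, start, start + glen, f"gene{gene_id:05d}"))
            gene_id += 1

    compartments = GenomicIntervalSet.from_records(comp_rows, cs)
    clads = GenomicIntervalSet.from_records(clad_rows, cs)
    genes = GenomicIntervalSet.from_records(
        sorted(gene_rows, key=lambda r: (r[0], r[1])), cs
    )
    n_hk = int(round(spec.housekeeping_fraction * len(genes)))
    hk_idx = np.sort(rng.choice(len(genes), size=n_hk, replace=False)) if n_hk else []
    housekeeping = GenomicIntervalSet(genes.df.iloc[list(hk_idx)], cs)
    return Genome(spec, cs, compartments, clads, genes, housekeeping, spec.classification())


@dataclass
class ContactModelParams:
    """Rates of the generative contact model.

    cis pixel rate at bin offset s: magnitude * (s+1)^-alpha, times the
    compartment boost when both bins share a label, times any compaction
    effect. trans pixel rate: per-pair affinity (lognormal heterogeneity
    around a base, small-small pairs boosted), times donor jitter, CE fold
    and trisomy dosage. The whole rate matrix is rescaled to ``depth``
    expected contacts before sampling.
    """

    cis_alpha: float = 1.0
    cis_magnitude: float = 1.0
    compartment_boost: float = 1.3
    trans_base: float = 0.004
    small_small_multiplier: float = 1.8
    affinity_sd: float = 0.35  # lognormal sd of per-pair affinity heterogeneity
    donor_sd: float = 0.05  # lognormal sd of per-donor per-pair jitter
    depth: int = 5_000_000
    noise: str = "poisson"  # or "negative-binomial"
    nb_dispersion: float = 0.1  # 1/size; only used for negative binomial

    def __post_init__(self) -> None:
        if self.cis_alpha <= 0:
            raise ValueError("cis decay exponent must be positive")
        if min(self.cis_magnitude, self.trans_base, self.depth) <= 0:
            raise ValueError("rates and depth must be positive")


@dataclass
class CEPerturbation:
    mode: str  # "enforced" | "reversed" | "stochastic"
    rho: float = 0.8  # target |rank correlation| for enforced/reversed
    amplitude: float = 0.3  # lognormal sd of the fold factors


@dataclass
class PerturbationPlan:
    """What the simulated trisomy does on top of the normal-karyotype model."""

    trisomic_chrom: str | None = None
    ce_modes: dict[str, CEPerturbation] = field(default_factory=dict)
    compaction_regions: list[tuple[str, int, int, float]] = field(default_factory=list)
    compaction_window: int = 1_000_000
    # multiplies trans rates between small-cluster chromosome pairs (models
    # gain/loss of contacts within the small-chromosome contact cluster)
    small_small_trans_multiplier: float = 1.0

    def validate(self, chromsizes: ChromSizes) -> None:
        if self.trisomic_chrom is not None and self.trisomic_chrom not in chromsizes:
            raise ValueError(f"unknown trisomic chromosome {self.trisomic_chrom}")
        for chrom, start, end, effect in self.compaction_regions:
            if effect <= 0:
                raise ValueError("compaction effects must be positive")
            if not (0 <= start < end <= chromsizes[chrom]):
                raise ValueError(f"region {chrom}:{start}-{end} outside chromosome")


@dataclass
class GroundTruth:
    """Everything needed to score recovery without re-deriving the model."""

    ce_category: dict[str, str]  # per-chromosome truth incl. "unchanged"
    ce_rho: dict[str, float]
    regions: pd.DataFrame  # chrom, start, end, direction, effect
    trisomic_chrom: str | None
    seed: int | None

    def regions_interval_set(self, chromsizes: ChromSizes) -> GenomicIntervalSet:
        df = self.regions.rename(columns={"direction": "label"})
        return GenomicIntervalSet(df[["chrom", "start", "end", "label"]], chromsizes)


def build_affinity(
    genome: Genome, params: ContactModelParams, seed: int | None = None
) -> pd.DataFrame:
    """Symmetric chromosome-pair trans affinity matrix (a genome property).

    base * small_small_multiplier on small-small pairs, with lognormal
    per-pair heterogeneity — the heterogeneity is what gives each
    chromosome a structured entourage of close and distal partners.
    """
    rng = np.random.default_rng(seed)
    names = list(genome.chromsizes.names)
    n = len(names)
    A = np.full((n, n), np.nan)
    small = genome.classification.small
    for i in range(n):
        for j in range(i + 1, n):
            v = params.trans_base * rng.lognormal(0.0, params.affinity_sd)
            if names[i] in small and names[j] in small:
                v *= params.small_small_multiplier
            A[i, j] = A[j, i] = v
    return pd.DataFrame(A, index=names, columns=names)


def _ce_fold_factors(
    genome: Genome,
    affinity: pd.DataFrame,
    plan: PerturbationPlan,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Per-(focal, partner) multiplicative fold factors realizing the CE plan.

    For an enforced/reversed chromosome the log fold factors follow a
    Gaussian copula against the chromosome's baseline affinities with
    Pearson rho chosen so the rank correlation matches the target
    (rho_pearson = 2 sin(pi * rho_spearman / 6)); stochastic chromosomes get
    independent lognormal factors. The realized pair fold is the product of
    the two chromosomes' factors.
    """
    names = list(genome.chromsizes.names)
    G = pd.DataFrame(1.0, index=names, columns=names)
    for chrom, pert in plan.ce_modes.items():
        partners = [c for c in names if c != chrom]
        f = affinity.loc[chrom, partners].to_numpy()
        k = len(partners)
        eps = rng.standard_normal(k)
        if pert.mode in ("enforced", "reversed"):
            ranks = stats.rankdata(f)
            z_f = stats.norm.ppf((ranks - 0.5) / k)
            rho_s = pert.rho if pert.mode == "enforced" else -pert.rho
            rho_p = 2 * np.sin(np.pi * rho_s / 6)
            z = rho_p * z_f + np.sqrt(1 - rho_p**2) * eps
        elif pert.mode == "stochastic":
            z = eps
        else:
            raise ValueError(f"unknown CE mode {pert.mode!r}")
        G.loc[chrom, partners] = np.exp(pert.amplitude * z)
    return G


def expected_matrix(
    genome: Genome,
    params: ContactModelParams,
    plan: PerturbationPlan | None,
    affinity: pd.DataFrame,
    donor_jitter: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Noiseless expected-rate matrix (scaled to depth), before sampling."""
    spec = genome.spec
    res = spec.resolution
    cs = genome.chromsizes
    names = list(cs.names)
    n_per = {c: -(-cs[c] // res) for c in names}
    n = sum(n_per.values())
    offsets = {}
    off = 0
    for c in names:
        offsets[c] = off
        off += n_per[c]

    # per-bin compartment label (bin takes the label at its midpoint)
    comp_label = np.zeros(n, dtype=np.int8)
    for row in genome.compartments.df.itertuples(index=False):
        if row.label != "A":
            continue
        o = offsets[row.chrom]
        nb = n_per[row.chrom]
        mids = np.arange(nb) * res + res // 2
        sel = (mids >= row.start) & (mids < row.end)
        comp_label[o : o + nb][sel] = 1

    lam = np.zeros((n, n))
    # cis blocks
    for c in names:
        nb = n_per[c]
        sl = slice(offsets[c], offsets[c] + nb)
        idx = np.arange(nb)
        s = np.abs(idx[:, None] - idx[None, :])
        block = params.cis_magnitude * (s + 1.0) ** (-params.cis_alpha)
        same = comp_label[sl][:, None] == comp_label[sl][None, :]
        block = block * np.where(same, params.compartment_boost, 1.0)
        lam[sl, sl] = block
    # trans blocks
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            v = float(affinity.loc[a, b])
            if donor_jitter is not None:
                v *= float(donor_jitter.loc[a, b])
            sla = slice(offsets[a], offsets[a] + n_per[a])
            slb = slice(offsets[b], offsets[b] + n_per[b])
            lam[sla, slb] = v
            lam[slb, sla] = v

    if plan is not None:
        if rng is None:
            rng = np.random.default_rng()
        # CE fold factors on trans blocks
        G = _ce_fold_factors(genome, affinity, plan, rng)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                fold = float(G.loc[a, b] * G.loc[b, a])
                if fold != 1.0:
                    sla = slice(offsets[a], offsets[a] + n_per[a])
                    slb = slice(offsets[b], offsets[b] + n_per[b])
                    lam[sla, slb] *= fold
                    lam[slb, sla] *= fold
        # small-cluster trans shift
        if plan.small_small_trans_multiplier != 1.0:
            small = genome.classification.small
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    if a in small and b in small:
                        sla = slice(offsets[a], offsets[a] + n_per[a])
                        slb = slice(offsets[b], offsets[b] + n_per[b])
                        lam[sla, slb] *= plan.small_small_trans_multiplier
                        lam[slb, sla] *= plan.small_small_trans_multiplier
        # compaction injections on cis vicinities
        w = plan.compaction_window // res
        for chrom, start, end, effect in plan.compaction_regions:
            nb = n_per[chrom]
            o = offsets[chrom]
            b0 = start // res
            b1 = -(-end // res)  # exclusive
            inside = np.zeros(nb, dtype=bool)
            inside[b0:b1] = True
            idx = np.arange(nb)
            s = np.abs(idx[:, None] - idx[None, :])
            both = inside[:, None] & inside[None, :]
            one = (inside[:, None] ^ inside[None, :]) & (s <= w)
            sel = both | one
            lam[o : o + nb, o : o + nb][sel] *= effect
        # trisomy dosage: 1.5x on the extra chromosome's cis and trans rates
        t = plan.trisomic_chrom
        if t is not None:
            slt = slice(offsets[t], offsets[t] + n_per[t])
            lam[slt, :] *= 1.5
            lam[:, slt] *= 1.5
            lam[slt, slt] /= 1.5  # cis block scales 1.5x, not 2.25x

    # scale expected total (upper triangle incl. diagonal) to depth
    total = (lam.sum() + np.trace(lam)) / 2
    lam *= params.depth / total
    return lam


def simulate_contact_map(
    genome: Genome,
    params: ContactModelParams,
    plan: PerturbationPlan | None = None,
    seed: int | None = None,
    affinity: pd.DataFrame | None = None,
    donor_jitter: pd.DataFrame | None = None,
) -> tuple[BinnedContactMap, GroundTruth]:
    """Sample one contact map (and its ground truth) from the model.

    ``affinity`` should be shared between the maps of one study; when
    omitted it is derived from the same seed, so identical seeds give
    identical maps.
    """
    if plan is not None:
        plan.validate(genome.chromsizes)
    ss = np.random.SeedSequence(seed)
    s_aff, s_plan, s_counts = ss.spawn(3)
    if affinity is None:
        affinity = build_affinity(genome, params, np.random.default_rng(s_aff))
    lam = expected_matrix(
        genome, params, plan, affinity, donor_jitter, np.random.default_rng(s_plan)
    )
    rng = np.random.default_rng(s_counts)
    iu = triu_indices_cached(lam.shape[0])
    mu = lam[iu]
    if params.noise == "poisson":
        vals = rng.poisson(mu)
    elif params.noise == "negative-binomial":
        size = 1.0 / params.nb_dispersion
        p = size / (size + mu)
        vals = rng.negative_binomial(size, p)
    else:
        raise ValueError(f"unknown noise model {params.noise!r}")
    counts = symmetrize_upper(np.asarray(vals, dtype=np.float64), lam.shape[0])
    cmap = BinnedContactMap(genome.chromsizes, genome.spec.resolution, counts)
    truth = _ground_truth(genome, plan, seed)
    return cmap, truth


def _ground_truth(genome: Genome, plan: PerturbationPlan | None, seed) -> GroundTruth:
    names = list(genome.chromsizes.names)
    cats = {c: "unchanged" for c in names}
    rhos = {c: 0.0 for c in names}
    regions = pd.DataFrame(columns=["chrom", "start", "end", "direction", "effect"])
    tchrom = None
    if plan is not None:
        for c, pert in plan.ce_modes.items():
            cats[c] = pert.mode
            rhos[c] = pert.rho if pert.mode == "enforced" else (
                -pert.rho if pert.mode == "reversed" else 0.0
            )
        if plan.compaction_regions:
            regions = pd.DataFrame(
                [
                    (c, s, e, "UP" if eff > 1 else "DOWN", eff)
                    for c, s, e, eff in plan.compaction_regions
                ],
                columns=["chrom", "start", "end", "direction", "effect"],
            )
        tchrom = plan.trisomic_chrom
    return GroundTruth(cats, rhos, regions, tchrom, seed)


def simulate_study(
    genome: Genome,
    params: ContactModelParams,
    plan: PerturbationPlan,
    seed: int | None = None,
    n_normal: int = 2,
) -> dict:
    """Simulate a matched study: normal donor maps plus one trisomy map.

    All maps share one affinity matrix; each normal donor gets its own
    trans jitter, and the trisomy map reuses donor 0's jitter (same genetic
    background as its control).
    """
    ss = np.random.SeedSequence(seed)
    s_aff, s_jit, *s_maps = ss.spawn(2 + n_normal + 1)
    affinity = build_affinity(genome, params, np.random.default_rng(s_aff))
    names = list(genome.chromsizes.names)
    jit_rng = np.random.default_rng(s_jit)
    jitters = []
    for _ in range(n_normal):
        J = np.exp(jit_rng.normal(0.0, params.donor_sd, (len(names), len(names))))
        J = np.triu(J, 1)
        J = J + J.T
        np.fill_diagonal(J, 1.0)
        jitters.append(pd.DataFrame(J, index=names, columns=names))
    normals = []
    for k in range(n_normal):
        cmap, _ = simulate_contact_map(
            genome, params, None, s_maps[k].generate_state(1)[0] % (2**31),
            affinity=affinity, donor_jitter=jitters[k],
        )
        normals.append(cmap)
    tri, truth = simulate_contact_map(
        genome, params, plan, s_maps[-1].generate_state(1)[0] % (2**31),
        affinity=affinity, donor_jitter=jitters[0],
    )
    return {"normals": normals, "trisomy": tri, "truth": truth, "affinity": affinity}


def sample_compaction_regions(
    genome: Genome,
    n: int = 20,
    min_len: int = 150_000,
    max_len: int = 500_000,
    effects: tuple[float, float] = (1.4, 0.7),
    min_gap: int = 2_000_000,
    seed: int | None = None,
    max_tries: int = 10_000,
) -> list[tuple[str, int, int, float]]:
    """Draw non-overlapping injection regions, well separated so their
    1 Mb vicinities do not interact; effects alternate between the given
    UP and DOWN multipliers."""
    rng = np.random.default_rng(seed)
    res = genome.spec.resolution
    names = list(genome.chromsizes.names)
    lengths = np.array([genome.chromsizes[c] for c in names], dtype=float)
    placed: list[tuple[str, int, int, float]] = []
    tries = 0
    while len(placed) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError("could not place injection regions; genome too small")
        ci = rng.choice(len(names), p=lengths / lengths.sum())
        chrom = names[ci]
        L = int(np.round(rng.uniform(min_len, max_len) / res)) * res
        L = max(L, res)
        if genome.chromsizes[chrom] < L + 2 * min_gap:
            continue
        start = int(rng.integers(min_gap // res, (genome.chromsizes[chrom] - L - min_gap) // res + 1)) * res
        end = start + L
        if any(
            c == chrom and start - min_gap < e and s < end + min_gap
            for c, s, e, _ in placed
        ):
            continue
        effect = effects[len(placed) % 2]
        placed.append((chrom, start, end, effect))
    return placed


# -- recovery scoring ----------------------------------------------------

def score_ce_recovery(truth: GroundTruth, entourage_table: pd.DataFrame) -> pd.DataFrame:
    """Confusion matrix of true vs called CE categories."""
    called = dict(zip(entourage_table["chrom"], entourage_table["category"]))
    cats = ("enforced", "reversed", "stochastic", "unchanged")
    conf = pd.DataFrame(0, index=cats, columns=cats)
    for chrom, true_cat in truth.ce_category.items():
        if chrom in called:
            conf.loc[true_cat, called[chrom]] += 1
    return conf


def score_region_recovery(truth: GroundTruth, called) -> dict:
    """Recall/precision of called regions at >=1 bp overlap with matching direction."""
    called_df = called.regions if hasattr(called, "regions") else pd.DataFrame(called)
    truth_df = truth.regions
    n_truth = len(truth_df)
    n_called = len(called_df)
    hit_truth = np.zeros(n_truth, dtype=bool)
    hit_called = np.zeros(n_called, dtype=bool)
    for ti, t in enumerate(truth_df.itertuples(index=False)):
        for ci, c in enumerate(called_df.itertuples(index=False)):
            if (
                t.chrom == c.chrom
                and t.direction == c.direction
                and t.start < c.end
                and c.start < t.end
            ):
                hit_truth[ti] = True
                hit_called[ci] = True
    recall = float(hit_truth.mean()) if n_truth else np.nan
    precision = float(hit_called.mean()) if n_called else np.nan
    return {
        "recall": recall,
        "precision": precision,
        "n_truth": n_truth,
        "n_called": n_called,
    }
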