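"""Self-validation benchmarks: oracle equivalence, recovery and calibration.

Each function here recomputes a headline property of the pipeline from
scratch on freshly simulated data — naive reference implementations
(explicit double loops) stand against the vectorized production code, and
the synthetic generator provides ground truth for recovery rates. Used by
the acceptance test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import itertools
import os
import tempfile
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import BinnedContactMap, balance, expected_cis, write_contact_map
from .genome import ChromSizes, GenomicIntervalSet
from .interchrom import cluster_comparison, pair_fold_change, trans_frequency_matrix
from .entourage import ce_classify, ce_correlation, dispersion_baseline, fccf_dispersion, fccf_profile
from .compaction import call_altered_regions, local_ratio_track, ratio_fold_change
from .enrichment import count_intersections, shuffle_enrichment
from .pipeline import RunConfig, run_comparison
from .synthetic import (
    CEPerturbation,
    ContactModelParams,
    PerturbationPlan,
    SyntheticGenomeSpec,
    generate_genome,
    sample_compaction_regions,
    score_region_recovery,
    simulate_contact_map,
    simulate_study,
)

# study conditions for chromosome-level (entourage / cluster) benchmarks:
# 14 chromosomes of 4-16 Mb at 200 kb bins — the entourage statistics are
# chromosome-level, so coarse bins lose nothing while keeping runtime low
CE_LENGTHS = {
    f"chrT{i+1}": int(L * 1e6)
    for i, L in enumerate([16, 15, 14, 13, 12, 11, 10, 9, 8, 7, 6, 5, 4.5, 4])
}


def _random_map(rng: np.random.Generator, max_bins: int = 200) -> BinnedContactMap:
    n_chroms = int(rng.integers(2, 5))
    resolution = 50_000
    sizes = {}
    remaining = max_bins - 2 * n_chroms
    for k in range(n_chroms):
        nb = 2 + int(rng.integers(0, max(remaining // n_chroms, 1)))
        sizes[f"chr{k+1}"] = nb * resolution
    cs = ChromSizes.from_dict(sizes)
    n = sum(v // resolution for v in sizes.values())
    upper = rng.integers(0, 25, size=(n, n)).astype(float)
    counts = np.triu(upper) + np.triu(upper, 1).T
    return BinnedContactMap(cs, resolution, counts)


def oracle_equivalence(seed: int, n_maps: int = 20) -> dict:
    """Max |vectorized - naive| over random maps for the four core kernels."""
    rng = np.random.default_rng(seed)
    worst = {"local_ratio": 0.0, "expected_cis": 0.0, "trans_matrix": 0.0}
    intersections_exact = True
    window = 500_000
    for _ in range(n_maps):
        cmap = _random_map(rng)
        w = window // cmap.resolution

        track = local_ratio_track(cmap, window)
        k = 0
        for chrom, sl in cmap.chrom_slices().items():
            block = cmap.counts[sl, sl]
            nb = block.shape[0]
            for i in range(nb):
                total = sum(block[i, j] for j in range(nb))
                near = sum(block[i, j] for j in range(nb) if abs(i - j) <= w)
                ref = near / total if total > 0 else np.nan
                got = track.R[k]
                if np.isfinite(ref) or np.isfinite(got):
                    worst["local_ratio"] = max(worst["local_ratio"], abs(got - ref))
                k += 1

        curve = expected_cis(cmap)
        sums: dict[int, float] = {}
        counts: dict[int, int] = {}
        for chrom, sl in cmap.chrom_slices().items():
            block = cmap.counts[sl, sl]
            nb = block.shape[0]
            for i in range(nb):
                for j in range(i + 1, nb):
                    s = j - i
                    sums[s] = sums.get(s, 0.0) + block[i, j]
                    counts[s] = counts.get(s, 0) + 1
        got_map = dict(zip(curve.separations // cmap.resolution, curve.values))
        for s in sums:
            worst["expected_cis"] = max(
                worst["expected_cis"], abs(got_map[s] - sums[s] / counts[s])
            )

        tm = trans_frequency_matrix(cmap, weights_mode=None)
        slices = cmap.chrom_slices()
        for a, b in itertools.combinations(slices, 2):
            vals = [
                cmap.counts[i, j]
                for i in range(*slices[a].indices(cmap.n_bins))
                for j in range(*slices[b].indices(cmap.n_bins))
            ]
            worst["trans_matrix"] = max(worst["trans_matrix"], abs(tm[a, b] - np.mean(vals)))

        # interval intersections on random tracks over the same chromsizes
        cs = cmap.chromsizes
        regs, genes = [], []
        for _ in range(15):
            c = cs.names[rng.integers(len(cs))]
            s = int(rng.integers(0, max(cs[c] - 60_000, 1)))
            regs.append((c, s, s + int(rng.integers(10_000, 60_000)), "r"))
        for _ in range(40):
            c = cs.names[rng.integers(len(cs))]
            s = int(rng.integers(0, max(cs[c] - 30_000, 1)))
            genes.append((c, s, s + int(rng.integers(1_000, 30_000)), "g"))
        R = GenomicIntervalSet.from_records(regs, cs)
        G = GenomicIntervalSet.from_records(genes, cs)
        naive = sum(
            1
            for r in R.df.itertuples(index=False)
            for g in G.df.itertuples(index=False)
            if r.chrom == g.chrom and r.start < g.end and g.start < r.end
        )
        if count_intersections(R, G) != naive:
            intersections_exact = False
    worst["count_intersections_exact"] = intersections_exact
    worst["n_maps"] = n_maps
    return worst


def analytic_vicinity_ratio() -> dict:
    """Uniform 100-bin chromosome, +-20-bin window: interior and edge R."""
    cs = ChromSizes.from_dict({"chrU": 100 * 50_000})
    cmap = BinnedContactMap(cs, 50_000, np.ones((100, 100)))
    track = local_ratio_track(cmap, 1_000_000)
    return {"interior": float(track.R[50]), "edge": float(track.R[0])}


def region_worked_example() -> dict:
    """The seven-bin fold-change vector with default thresholds."""
    from .compaction import CompactionFoldChange

    vec = np.array([1.0, 1.3, 1.3, 1.0, 0.7, 1.0, 1.3])
    cs = ChromSizes.from_dict({"chrU": len(vec) * 50_000})
    bins = pd.DataFrame(
        {"chrom": "chrU", "start": np.arange(7) * 50_000, "end": (np.arange(7) + 1) * 50_000}
    )
    fc = CompactionFoldChange(bins, vec, 1_000_000, 50_000, cs)
    regions = call_altered_regions(fc)
    up = regions.direction("UP")
    return {
        "n_up": int(len(up)),
        "n_down": int(len(regions.direction("DOWN"))),
        "up_n_bins": int(up["n_bins"].iloc[0]) if len(up) else 0,
        "up_mean_fc": float(up["mean_fc"].iloc[0]) if len(up) else np.nan,
    }


def balance_convergence(seed: int, n_maps: int = 5, n_bins: int = 300) -> dict:
    """Marginal CV reached by cis-only / trans-only iterative correction on
    random positive matrices within 500 iterations."""
    rng = np.random.default_rng(seed)
    worst = {"cis": 0.0, "trans": 0.0}
    for _ in range(n_maps):
        n_chroms = int(rng.integers(3, 6))
        per = n_bins // n_chroms
        cs = ChromSizes.from_dict({f"chr{k+1}": per * 50_000 for k in range(n_chroms)})
        n = per * n_chroms
        upper = rng.uniform(0.5, 10.0, size=(n, n))
        counts = np.triu(upper) + np.triu(upper, 1).T
        cmap = BinnedContactMap(cs, 50_000, counts)
        for mode in ("cis", "trans"):
            out = balance(cmap, mode, tol=1e-5, max_iter=500)
            worst[mode] = max(worst[mode], out.balance_info[mode]["cv"])
    worst["n_maps"] = n_maps
    return worst


def ce_recovery(seed: int, n_seeds: int = 100) -> dict:
    """Sign accuracy and category recovery of entourage perturbations.

    Each simulated trisomy enforces the entourage on two chromosomes
    (target rho 0.8), reverses it on two (rho -0.8), and perturbs two
    stochastically (amplitude 0.5), on a 14-chromosome genome.
    """
    spec = SyntheticGenomeSpec(chrom_lengths=dict(CE_LENGTHS), resolution=200_000, n_small=5)
    genome = generate_genome(spec, seed=seed)
    params = ContactModelParams(depth=5_000_000)
    cls = genome.classification
    enforced = ["chrT2", "chrT5"]
    reversed_ = ["chrT3", "chrT8"]
    stochastic = ["chrT4", "chrT10"]
    plan = PerturbationPlan(
        trisomic_chrom="chrT13",
        ce_modes={
            **{c: CEPerturbation("enforced", rho=0.8, amplitude=0.3) for c in enforced},
            **{c: CEPerturbation("reversed", rho=0.8, amplitude=0.3) for c in reversed_},
            **{c: CEPerturbation("stochastic", amplitude=0.5) for c in stochastic},
        },
    )
    rs = {"enforced": [], "reversed": []}
    stochastic_calls = []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_seeds)]
    for s in child_seeds:
        study = simulate_study(genome, params, plan, seed=s, n_normal=2)
        tms = [trans_frequency_matrix(balance(m, "trans")) for m in study["normals"]]
        tmt = trans_frequency_matrix(balance(study["trisomy"], "trans"))
        base = dispersion_baseline(tms, cls)
        fc = pair_fold_change(tmt, tms[0], cls.excluded)
        for c in enforced:
            r, _ = ce_correlation(fccf_profile(tms[0], fc, c, cls))
            rs["enforced"].append(r)
        for c in reversed_:
            r, _ = ce_correlation(fccf_profile(tms[0], fc, c, cls))
            rs["reversed"].append(r)
        for c in stochastic:
            prof = fccf_profile(tms[0], fc, c, cls)
            r, p = ce_correlation(prof)
            stochastic_calls.append(
                ce_classify(r, p, fccf_dispersion(prof), base)
            )
    enf = np.array(rs["enforced"])
    rev = np.array(rs["reversed"])
    return {
        "enforced_sign_accuracy": float((enf > 0).mean()),
        "reversed_sign_accuracy": float((rev < 0).mean()),
        "stochastic_called": float(np.mean([c == "stochastic" for c in stochastic_calls])),
        "mean_r_enforced": float(enf.mean()),
        "mean_r_reversed": float(rev.mean()),
        "n_seeds": n_seeds,
    }


def compaction_recovery(seed: int, n_seeds: int = 20) -> dict:
    """Recall/precision of injected compaction regions (x1.4 UP / x0.7 DOWN,
    150-500 kb) on a two-chromosome genome at 50 kb bins, 5e6 contacts."""
    spec = SyntheticGenomeSpec(
        chrom_lengths={"chrC1": 60_000_000, "chrC2": 60_000_000},
        resolution=50_000,
        n_small=1,
    )
    genome = generate_genome(spec, seed=seed)
    params = ContactModelParams(cis_alpha=0.5, depth=5_000_000, trans_base=0.002)
    recalls, precisions = [], []
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_seeds)]
    for s in child_seeds:
        regions = sample_compaction_regions(genome, n=20, seed=s)
        plan = PerturbationPlan(compaction_regions=regions)
        normal, _ = simulate_contact_map(genome, params, None, seed=s)
        trisomy, truth = simulate_contact_map(genome, params, plan, seed=s + 1)
        fc = ratio_fold_change(
            local_ratio_track(trisomy), local_ratio_track(normal)
        )
        called = call_altered_regions(fc)
        sc = score_region_recovery(truth, called)
        recalls.append(sc["recall"])
        precisions.append(1.0 if np.isnan(sc["precision"]) else sc["precision"])
    return {
        "recall": float(np.mean(recalls)),
        "precision": float(np.mean(precisions)),
        "n_seeds": n_seeds,
    }


def shuffle_calibration(seed: int, n_replicates: int = 200, n_shuffles: int = 200) -> dict:
    """False-positive rate of the shuffle test when regions are independent
    of genes (observed regions drawn from the null placement)."""
    from .enrichment import _shuffle_once

    spec = SyntheticGenomeSpec()
    genome = generate_genome(spec, seed=seed)
    cs = genome.chromsizes
    rng = np.random.default_rng(seed)
    lengths = np.round(rng.uniform(100_000, 500_000, 30)).astype(np.int64)
    chrom_lengths = np.array(cs.lengths, dtype=np.int64)
    names = list(cs.names)
    hits = 0
    for _ in range(n_replicates):
        ci, ss = _shuffle_once(lengths, np.zeros(30, np.int64), chrom_lengths, rng, "genome")
        obs = pd.DataFrame(
            {"chrom": [names[i] for i in ci], "start": ss, "end": ss + lengths}
        )
        res = shuffle_enrichment(obs, genome.genes, cs, n=n_shuffles, seed=rng)
        hits += res.p_enrich < 0.05
    return {"fraction_p_below_0.05": hits / n_replicates, "n_replicates": n_replicates}


def cluster_contrast_power(seed: int, n_seeds: int = 50) -> dict:
    """Power to flag a 10% small-small trans affinity shift at p < 0.01."""
    spec = SyntheticGenomeSpec()
    genome = generate_genome(spec, seed=seed)
    params = ContactModelParams(depth=5_000_000)
    plan = PerturbationPlan(small_small_trans_multiplier=1.1)
    cls = genome.classification
    hits = 0
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_seeds)]
    for s in child_seeds:
        study = simulate_study(genome, params, plan, seed=s, n_normal=1)
        tn = trans_frequency_matrix(balance(study["normals"][0], "trans"))
        tt = trans_frequency_matrix(balance(study["trisomy"], "trans"))
        fc = pair_fold_change(tt, tn, cls.excluded)
        res = cluster_comparison(fc, cls)
        hits += res.p_value("small-small vs large-large") < 0.01
    return {"power": hits / n_seeds, "n_seeds": n_seeds}


def _write_study(tmpdir: Path, seed: int, depth: int = 800_000):
    spec = SyntheticGenomeSpec()
    genome = generate_genome(spec, seed)
    params = ContactModelParams(depth=depth)
    plan = PerturbationPlan(trisomic_chrom="chrS9")
    study = simulate_study(genome, params, plan, seed=seed)
    paths = {}
    for k, m in enumerate(study["normals"]):
        paths[f"normal_{k}"] = tmpdir / f"normal_{k}.tsv"
        write_contact_map(m, paths[f"normal_{k}"])
    paths["trisomy"] = tmpdir / "trisomy.tsv"
    write_contact_map(study["trisomy"], paths["trisomy"])
    return genome, paths


def identity_run(seed: int) -> dict:
    """Trisomy input == normal input: all fold changes must be exactly 1."""
    with tempfile.TemporaryDirectory() as td:
        tmpdir = Path(td)
        genome, paths = _write_study(tmpdir, seed)
        cfg = RunConfig(
            normal=[str(paths["normal_0"])],
            trisomy=[str(paths["normal_0"])],
            outdir=str(tmpdir / "out"),
            small=sorted(genome.classification.small),
            shuffles=5,
            seed=seed,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = run_comparison(cfg)
        fcv = rep.fold_change.values
        finite = fcv[np.isfinite(fcv)]
        return {
            "max_abs_fold_change_deviation": float(np.abs(finite - 1.0).max()),
            "n_regions": int(len(rep.regions)),
            "all_unchanged": bool(set(rep.entourage["category"]) <= {"unchanged"}),
        }


def determinism_check(seed: int) -> dict:
    """Two runs with identical config + seed produce byte-identical outputs."""
    with tempfile.TemporaryDirectory() as td:
        tmpdir = Path(td)
        genome, paths = _write_study(tmpdir, seed)
        outdir = tmpdir / "out"
        cfg = RunConfig(
            normal=[str(paths["normal_0"]), str(paths["normal_1"])],
            trisomy=[str(paths["trisomy"])],
            outdir=str(outdir),
            small=sorted(genome.classification.small),
            shuffles=10,
            seed=seed,
        )
        run_comparison(cfg)
        snapshot = {f: (outdir / f).read_bytes() for f in os.listdir(outdir)}
        run_comparison(cfg)
        identical = all((outdir / f).read_bytes() == b for f, b in snapshot.items())
        return {"byte_identical": bool(identical), "n_files": len(snapshot)}
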