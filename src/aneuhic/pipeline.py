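"""End-to-end normal-vs-trisomy comparison pipeline.

Order of operations: merge replicates (pixel sum) -> subsample both
karyotypes to the common depth -> balance -> expected cis curves -> trans
contact matrix + cluster comparison -> entourage (with a normal-vs-normal
dispersion baseline when at least two normal samples are given) ->
compaction ratio R + UP/DOWN regions -> annotation overlap and gene
enrichment. Identical config + seed reproduces byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .contacts import BinnedContactMap, balance, expected_cis, read_contact_map, subsample_to_depth
from .genome import ChromSizes, GenomicIntervalSet
from .interchrom import (
    ChromosomeClassification,
    cluster_comparison,
    pair_fold_change,
    trans_frequency_matrix,
)
from .entourage import analyze_entourage, dispersion_baseline
from .compaction import call_altered_regions, coverage_summary, local_ratio_track, ratio_fold_change
from .enrichment import chromosome_annotation_content, overlap_profile, shuffle_enrichment

logger = logging.getLogger("aneuhic")

__all__ = ["RunConfig", "RunReport", "run_comparison"]


@dataclass
class RunConfig:
    """Flat configuration for one normal-vs-trisomy comparison run."""

    normal: list[str]
    trisomy: list[str]
    outdir: str
    resolution: int | None = None
    small: list[str] | None = None  # None -> human default chr16-22
    excluded: list[str] = field(default_factory=list)
    low: float = 0.78
    high: float = 1.23
    min_dist: int = 50_000
    alpha: float = 0.05
    window: int = 1_000_000
    clads: str | None = None
    compartments: str | None = None
    genes: str | None = None
    housekeeping: str | None = None
    shuffles: int = 1000
    shuffle_mode: str = "genome"
    seed: int = 0
    merge_replicates: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if not self.normal or not self.trisomy:
            raise ValueError("need at least one normal and one trisomy map")
        if not (0 < self.low < 1 < self.high):
            raise ValueError(f"thresholds must satisfy 0 < low < 1 < high, got {self.low}, {self.high}")
        if self.min_dist < 0 or self.window <= 0 or not (0 < self.alpha < 1):
            raise ValueError("invalid min_dist/window/alpha")
        for p in [*self.normal, *self.trisomy, self.clads, self.compartments, self.genes, self.housekeeping]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class RunReport:
    """In-memory results of a pipeline run (files are also written to outdir)."""

    config: RunConfig
    classification: ChromosomeClassification
    trans_normal: object
    trans_trisomy: object
    fold_change: object
    cluster_tests: pd.DataFrame
    entourage: pd.DataFrame
    regions: object
    coverage: object
    enrichment: pd.DataFrame | None
    outdir: Path


def _merge_maps(maps: list[BinnedContactMap]) -> BinnedContactMap:
    counts = maps[0].counts.copy()
    for m in maps[1:]:
        if m.chromsizes != maps[0].chromsizes or m.resolution != maps[0].resolution:
            raise ValueError("replicate maps disagree on bins")
        counts += m.counts
    return BinnedContactMap(maps[0].chromsizes, maps[0].resolution, counts)


def _classification(cs: ChromSizes, config: RunConfig) -> ChromosomeClassification:
    excluded = set(config.excluded)
    if config.small is not None:
        small = set(config.small)
        large = set(cs.names) - small - excluded
        return ChromosomeClassification.make(small, large, excluded)
    cls = ChromosomeClassification.human_default(excluded)
    # keep only chromosomes present
    return ChromosomeClassification.make(
        cls.small & set(cs.names),
        cls.large & set(cs.names),
        (cls.excluded | excluded) & set(cs.names),
    )


def _header(config: RunConfig) -> str:
    return f"# aneuhic {__version__} config={config.hash()} seed={config.seed}\n"


def _write_tsv(df: pd.DataFrame, path: Path, config: RunConfig, index: bool = False) -> None:
    with open(path, "w") as fh:
        fh.write(_header(config))
        df.to_csv(fh, sep="\t", float_format="%.10g", index=index)


def run_comparison(config: RunConfig) -> RunReport:
    """Execute the full comparison and write report tables to ``config.outdir``."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    normals = [read_contact_map(p, config.resolution) for p in config.normal]
    trisomies = [read_contact_map(p, config.resolution) for p in config.trisomy]
    cs = normals[0].chromsizes
    cls = _classification(cs, config)
    cls.validate_cover(cs)

    # --- dispersion baseline from per-sample normal maps (equal depth) ---
    baseline = None
    if len(normals) >= 2:
        depth = int(min(m.total for m in normals))
        tms = []
        for m in normals:
            sub = subsample_to_depth(m, depth, rng)
            tms.append(trans_frequency_matrix(balance(sub, "trans")))
        baseline = dispersion_baseline(tms, cls)
    else:
        warnings.warn(
            "single normal sample: no dispersion baseline, entourage categories "
            "limited to enforced/reversed/unchanged",
            RuntimeWarning,
        )

    # --- merged maps at common depth ---
    norm = _merge_maps(normals) if config.merge_replicates else normals[0]
    tri = _merge_maps(trisomies) if config.merge_replicates else trisomies[0]
    depth = int(min(norm.total, tri.total))
    norm = subsample_to_depth(norm, depth, rng)
    tri = subsample_to_depth(tri, depth, rng)

    norm_t = balance(norm, "trans")
    tri_t = balance(tri, "trans")

    # --- expected cis ---
    for label, m in (("normal", norm), ("trisomy", tri)):
        curve = expected_cis(m)
        _write_tsv(curve.as_dataframe(), outdir / f"expected_cis_{label}.tsv", config)

    # --- trans matrices, fold change, cluster comparison ---
    tm_n = trans_frequency_matrix(norm_t)
    tm_t = trans_frequency_matrix(tri_t)
    fc = pair_fold_change(tm_t, tm_n, cls.excluded)
    comp = cluster_comparison(fc, cls)
    _write_tsv(tm_n.as_dataframe(), outdir / "trans_normal.tsv", config, index=True)
    _write_tsv(tm_t.as_dataframe(), outdir / "trans_trisomy.tsv", config, index=True)
    _write_tsv(fc.as_dataframe(), outdir / "fccf_matrix.tsv", config, index=True)
    _write_tsv(comp.tests, outdir / "cluster_comparison.tsv", config)

    # --- entourage ---
    ent = analyze_entourage(tm_n, fc, cls, baseline, config.alpha)
    _write_tsv(ent, outdir / "entourage.tsv", config)

    # --- compaction ---
    R_n = local_ratio_track(norm, config.window)
    R_t = local_ratio_track(tri, config.window)
    rfc = ratio_fold_change(R_t, R_n)
    regions = call_altered_regions(rfc, config.low, config.high, config.min_dist)
    R_n.to_bedgraph(outdir / "compaction_R_normal.bedgraph")
    R_t.to_bedgraph(outdir / "compaction_R_trisomy.bedgraph")
    rfc.to_bedgraph(outdir / "compaction_fc.bedgraph")
    regions.to_bed(outdir / "regions.bed")

    clads = GenomicIntervalSet.from_bed(config.clads, cs) if config.clads else None
    cov = coverage_summary(regions, cs, cls, clads)
    _write_tsv(cov.table, outdir / "coverage_summary.tsv", config)
    if len(cov.correlations):
        _write_tsv(cov.correlations, outdir / "coverage_clad_correlation.tsv", config)

    # --- annotation overlap + gene enrichment ---
    enrich_rows = []
    gene_sets = {}
    if config.genes:
        gene_sets["protein_coding"] = GenomicIntervalSet.from_bed(config.genes, cs)
    if config.housekeeping:
        gene_sets["housekeeping"] = GenomicIntervalSet.from_bed(config.housekeeping, cs)
    for gname, gset in gene_sets.items():
        for direction in ("UP", "DOWN"):
            sub = regions.as_interval_set(direction)
            if len(sub) == 0:
                enrich_rows.append((gname, direction, 0, np.nan, np.nan, np.nan, np.nan, 0))
                continue
            res = shuffle_enrichment(
                sub, gset, cs, n=config.shuffles, seed=rng, mode=config.shuffle_mode
            )
            enrich_rows.append(
                (gname, direction, res.observed, res.null_mean, res.null_std,
                 res.p_enrich, res.p_deplete, res.n_iterations)
            )
    enrichment = None
    if enrich_rows:
        enrichment = pd.DataFrame(
            enrich_rows,
            columns=["gene_set", "direction", "observed", "null_mean", "null_std",
                     "p_enrich", "p_deplete", "n_iterations"],
        )
        _write_tsv(enrichment, outdir / "enrichment.tsv", config)

    overlap_tracks = {}
    if clads is not None:
        overlap_tracks["cLAD"] = (clads, None)
    if config.compartments:
        comp_set = GenomicIntervalSet.from_bed(config.compartments, cs)
        overlap_tracks["compartment_A"] = (comp_set, "A")
        overlap_tracks["compartment_B"] = (comp_set, "B")
    ov_rows = []
    for tname, (track, label) in overlap_tracks.items():
        for direction in ("UP", "DOWN"):
            sub = regions.as_interval_set(direction)
            prof = overlap_profile(sub, track, label)
            ov_rows.append(
                (tname, direction, len(prof.fractions),
                 float(np.mean(prof.fractions)) if len(prof.fractions) else np.nan,
                 prof.percent_none, prof.percent_full)
            )
    if ov_rows:
        _write_tsv(
            pd.DataFrame(
                ov_rows,
                columns=["annotation", "direction", "n_regions", "mean_fraction",
                         "percent_no_overlap", "percent_full_overlap"],
            ),
            outdir / "region_overlap.tsv",
            config,
        )
    if clads is not None:
        _write_tsv(
            chromosome_annotation_content(clads, cs).to_frame(),
            outdir / "clad_content.tsv", config, index=True,
        )

    info = {
        "version": __version__,
        "config": asdict(config),
        "config_hash": config.hash(),
        "seed": config.seed,
        "common_depth": depth,
        "balance": {
            "normal_trans": norm_t.balance_info.get("trans"),
            "trisomy_trans": tri_t.balance_info.get("trans"),
        },
        "n_regions": len(regions),
        "baseline_threshold": baseline.threshold if baseline else None,
    }
    (outdir / "run_info.json").write_text(json.dumps(info, indent=2, sort_keys=True, default=str))
    logger.info("run complete: %s (%d regions)", outdir, len(regions))

    return RunReport(
        config, cls, tm_n, tm_t, fc, comp.tests, ent, regions, cov, enrichment, outdir
    )
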