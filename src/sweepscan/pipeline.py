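"""Stage orchestration: wire the scan stages together over a file bundle,
with a single run configuration holding every threshold.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import empirical as emp
from . import enrichment as enr
from . import fixed_sites as fx
from . import io as sio
from . import regions as rg
from . import scan as sc
from .nullsim import (NullDistribution, default_population_spec,
                      model_from_yaml, simulate_null)
from .popspec import PopulationSpec
from .synthetic import Bundle
from .windows import WindowSpec, compute_window_stats

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline thresholds in one place; every default is overridable
    via config file or CLI flag, none is hard-coded downstream."""

    window_size: int = 100_000
    window_step: int = 10_000
    min_callable: int = 30_000
    alpha: float = 0.01
    merge_gap: int = 200_000
    top_k: int = 100
    gene_flank: int = 25_000
    panel_flank: int = 500_000
    min_panel_freq: float = 0.75
    top_fraction: float = 0.01
    null_reps: int = 5_000
    null_window: int = 100_000
    seed: int = 1

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for name in ("window_size", "window_step", "min_callable",
                     "merge_gap", "top_k", "gene_flank", "panel_flank",
                     "null_reps", "null_window"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @property
    def window_spec(self) -> WindowSpec:
        return WindowSpec(self.window_size, self.window_step,
                          self.min_callable)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class ScanResult:
    """In-memory results of a full pipeline run."""

    wstats: pd.DataFrame
    null: NullDistribution
    scan: pd.DataFrame
    percentiles: pd.DataFrame
    fdr_regions: list          # every called region (union of significant windows)
    fdr_ranked: list           # the CMS-rankable subset, in rank order
    empirical_regions: list
    cms_threshold: float
    class_labels: pd.Series
    comparison: dict
    fixed: pd.DataFrame | None = None
    chi2: tuple | None = None
    genes_near: list | None = None
    enrichment: pd.DataFrame | None = None


def contig_lengths_from_manifest(bundle: Bundle) -> dict[str, int]:
    manifest = json.loads(bundle.manifest.read_text())
    return {k: int(v) for k, v in manifest["contig_lengths"].items()}


def run_scan(wstats: pd.DataFrame, null: NullDistribution,
             cfg: RunConfig
             ) -> tuple[pd.DataFrame, list, list, float, pd.Series]:
    """FDR stage: scan table, called regions, CMS-ranked regions, CMS
    threshold, window labels.

    Regions whose member windows all lack a defined CMS (no computable
    delta_td) remain called regions but are absent from the ranking.
    """
    scan = sc.build_scan_table(wstats, null)
    sig = rg.significant_windows(scan, cfg.alpha)
    regions = rg.call_regions(sig, cfg.merge_gap)
    ranked = rg.rank_regions(list(regions), scan, "cms")
    if ranked:
        thr = rg.cms_threshold_top_k(ranked, cfg.top_k)
    else:
        thr = 1.0
    labels = sc.classify_windows(scan, thr, cfg.alpha)
    return scan, regions, ranked, thr, labels


def run_empirical(wstats: pd.DataFrame,
                  cfg: RunConfig) -> tuple[pd.DataFrame, list]:
    """Empirical-outlier stage: percentile table and ranked regions."""
    pct = emp.joint_percentile(wstats)
    outlier = emp.top_fraction(pct["pct_joint"].to_numpy(),
                               cfg.top_fraction)
    sig = pct.loc[outlier, ["contig", "start", "end"]].copy()
    sig["stat"] = "joint"
    regions = rg.call_regions(sig, cfg.merge_gap)
    scan_like = pct.rename(columns={"pct_joint": "score"})
    ranked = rg.rank_regions(regions, scan_like, "score")
    return pct, ranked


def run_all(bundle: Bundle, cfg: RunConfig, outdir,
            spec: PopulationSpec | None = None,
            null: NullDistribution | None = None) -> ScanResult:
    """Run every stage on a file bundle and write stage outputs to
    *outdir*: window stats, null, scan table, percentile table, region
    TSV/BED for both methods, fixed-site table and test, enrichment table,
    and a run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    spec = spec or default_population_spec(outgroup=True)
    lengths = contig_lengths_from_manifest(bundle)

    sites = sio.read_genotypes(bundle.vcf, spec)
    mask = sio.read_mask(bundle.mask)
    wstats = compute_window_stats(sites, mask, cfg.window_spec, spec,
                                  lengths)
    sio.write_table(wstats, outdir / "window_stats.tsv")

    if null is None:
        model = model_from_yaml(bundle.model)
        null = simulate_null(model, cfg.null_reps, cfg.null_window,
                             seed=cfg.seed)
    null.save(outdir / "null.tsv")

    scan, fdr_regions, fdr_ranked, thr, labels = run_scan(wstats, null, cfg)
    scan_out = scan.copy()
    scan_out["class_label"] = labels
    sio.write_table(scan_out, outdir / "scan.tsv")

    pct, emp_regions = run_empirical(wstats, cfg)
    sio.write_table(pct, outdir / "empirical.tsv")

    panel = sio.read_table(bundle.panel_pi)
    fdr_regions = rg.validate_with_panel(fdr_regions, panel,
                                         cfg.panel_flank)
    comparison = rg.compare_region_sets(fdr_regions, emp_regions)

    sio.write_table(rg.regions_to_frame(fdr_regions),
                    outdir / "regions_fdr.tsv")
    sio.write_table(rg.regions_to_frame(emp_regions),
                    outdir / "regions_empirical.tsv")
    sio.write_bed(outdir / "regions_fdr.bed",
                  [(r.contig, r.start, r.end) for r in fdr_regions],
                  scores=[0.0 if np.isnan(r.score) else r.score
                          for r in fdr_regions])

    # fixed-derived sites
    polarized = sio.polarize(sites, spec)
    candidates = fx.find_fixed_derived(polarized, spec)
    panel_freqs = sio.read_table(bundle.panel_freqs)
    fixed = fx.filter_by_panel(candidates, panel_freqs, cfg.min_panel_freq)
    classes = sio.read_table(bundle.site_classes)
    fixed = fx.annotate_fixed_sites(fixed, classes, fdr_regions)
    sio.write_table(fixed, outdir / "fixed_sites.tsv")
    chi2 = None
    if (len(fixed) and fixed["class"].nunique() >= 2
            and fixed["in_outlier"].nunique() == 2):
        chi2 = fx.functional_class_chi2(fixed)

    # enrichment around peaks
    genes = sio.read_genes(bundle.genes)
    term_map = sio.read_term_map(bundle.term_map)
    genes_near = enr.genes_near_peaks(fdr_ranked, genes, cfg.gene_flank,
                                      cfg.top_k, validated_only=True)
    enrich = enr.enrichment_test(genes_near, term_map)
    sio.write_table(enrich, outdir / "enrichment.tsv")

    manifest = {
        "config": cfg.to_dict(),
        "inputs": {name: _digest(getattr(bundle, name))
                   for name in ("vcf", "mask", "genes", "term_map",
                                "panel_pi", "panel_freqs", "site_classes",
                                "model")},
        "n_windows": int(len(wstats)),
        "n_fdr_regions": len(fdr_regions),
        "n_empirical_regions": len(emp_regions),
        "cms_threshold": thr,
        "chi2": list(chi2) if chi2 else None,
    }
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n")

    return ScanResult(wstats=wstats, null=null, scan=scan,
                      percentiles=pct, fdr_regions=fdr_regions,
                      fdr_ranked=fdr_ranked,
                      empirical_regions=emp_regions, cms_threshold=thr,
                      class_labels=labels, comparison=comparison,
                      fixed=fixed, chi2=chi2, genes_near=genes_near,
                      enrichment=enrich)


def _digest(path: Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
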