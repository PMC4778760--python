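"""Self-contained synthetic datasets with the statistical structure the
scan assumes: a neutral two-population genome under divergence-with-
bottleneck demography, injected sweep loci, a callable mask, gene models,
a gene->term map, panel window diversity, and planted fixed-derived sites
with functional classes and panel frequencies.

Sweeps are emulated demographically: within a sweep locus the sweep
population's recent effective size is divided by ``intensity`` during a
crash epoch that ends shortly before the present (default: from 2,500 to
250 generations ago).  The post-crash recovery phase repopulates the locus
with rare, young variants, yielding the classic hitchhiking footprint the
scan statistics target — collapsed diversity, elevated differentiation and
a negative Tajima's D in the sweep population — without forward-time
selection simulation.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import msprime
import numpy as np
import pandas as pd

from . import io as sio
from .nullsim import (DemographicModel, default_model,
                      default_population_spec, model_to_yaml,
                      site_table_from_ts)
from .popspec import IntervalSet, PopulationSpec, SiteTable
from .windows import WindowSpec, sliding_windows

logger = logging.getLogger(__name__)

#: ten-class functional vocabulary for planted fixed sites
FUNCTIONAL_CLASSES = ("intergenic", "intron", "upstream_1kb",
                      "downstream_1kb", "utr5", "utr3", "synonymous",
                      "non_synonymous", "splice_region", "ncRNA")
# class frequencies outside / inside sweep loci (inside skewed toward
# regulatory and coding classes so the functional-class test has signal)
_CLASS_P_NEUTRAL = (0.60, 0.29, 0.005, 0.01, 0.01, 0.015, 0.04, 0.02,
                    0.005, 0.005)
_CLASS_P_SWEEP = (0.45, 0.25, 0.03, 0.02, 0.02, 0.03, 0.08, 0.10,
                  0.01, 0.01)


@dataclass(frozen=True)
class SweepLocus:
    contig: str
    center: int
    width: int = 100_000
    intensity: float = 100.0

    @property
    def start(self) -> int:
        return self.center - self.width // 2

    @property
    def end(self) -> int:
        return self.center + self.width // 2


@dataclass
class SyntheticConfig:
    """Desk-scale defaults: 2 x 10 Mb contigs, 5 dog + 6 wolf + 2 outgroup
    chromosomes, 10 injected sweeps (one every 2 Mb) of width 100 kb and
    intensity 100, 10% callable dropout."""

    contig_lengths: dict = field(
        default_factory=lambda: {"chr1": 10_000_000, "chr2": 10_000_000})
    model: DemographicModel = field(
        default_factory=lambda: default_model(with_outgroup=True))
    sweeps: tuple = field(default_factory=lambda: tuple(
        SweepLocus(contig, center)
        for contig in ("chr1", "chr2")
        for center in (1_000_000, 3_000_000, 5_000_000, 7_000_000,
                       9_000_000)))
    sweep_pop: str = "dog"
    sweep_end_time: float = 250.0
    sweep_duration: float = 2_250.0
    mask_dropout: float = 0.10
    mask_tile: int = 1_000
    genes_per_mb: float = 8.0
    n_terms: int = 25
    term_size_range: tuple = (5, 40)
    panel_n_diploid: int = 12
    n_planted_fixed: int = 300
    min_separation: int = 300_000
    panel_window: WindowSpec = field(default_factory=WindowSpec)
    seed: int = 1

    def __post_init__(self):
        for locus in self.sweeps:
            if locus.intensity < 1:
                raise ValueError("sweep intensity must be >= 1")
            if locus.start < 0 or locus.end > self.contig_lengths[locus.contig]:
                raise ValueError(f"sweep locus outside contig: {locus}")
        by_contig: dict[str, list[SweepLocus]] = {}
        for locus in self.sweeps:
            by_contig.setdefault(locus.contig, []).append(locus)
        for loci in by_contig.values():
            loci.sort(key=lambda s: s.center)
            for a, b in zip(loci, loci[1:]):
                if b.start - a.end <= 0:
                    raise ValueError(f"overlapping sweep loci: {a}, {b}")
                if b.start - a.end <= self.min_separation:
                    raise ValueError(
                        f"sweep loci closer than min_separation "
                        f"({self.min_separation} bp): {a}, {b}")


def with_local_sweep(model: DemographicModel, pop: str, intensity: float,
                     t_end: float = 250.0,
                     duration: float = 2_250.0) -> DemographicModel:
    """Model variant emulating a completed sweep in *pop*.

    The population's recent size is divided by *intensity* between
    ``t_end`` and ``t_end + duration`` generations ago; the original epochs
    resume beyond the crash.  The default recovery time ``t_end`` makes the
    locus diversity floor (~2 * mu * t_end) equal the neutral level divided
    by the default intensity, so "intensity" reads as the realized fold
    reduction in diversity, while leaving about one expected segregating
    site per 100 kb so the frequency-spectrum statistics stay computable.
    With intensity 1 the model is returned unchanged.
    """
    if intensity == 1:
        return model
    epochs = list(model.populations[pop])
    recent_size = epochs[0][1]
    t_resume = t_end + duration
    new_epochs = [(0.0, recent_size), (t_end, recent_size / intensity)]
    resume_size = [s for t, s in epochs if t <= t_resume][-1]
    if not any(t == t_resume for t, _ in epochs):
        new_epochs.append((t_resume, resume_size))
    new_epochs.extend((t, s) for t, s in epochs if t > t_resume)
    populations = dict(model.populations)
    populations[pop] = tuple(new_epochs)
    return DemographicModel(
        populations=populations, splits=model.splits, samples=model.samples,
        mutation_rate=model.mutation_rate,
        recombination_rate=model.recombination_rate,
        migration=model.migration, pulses=model.pulses)


# ---------------------------------------------------------------------------
# genome simulation
# ---------------------------------------------------------------------------

def _simulate_segment(model: DemographicModel, length: int, contig: str,
                      seed: int, offset: int = 0) -> SiteTable:
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = (int(s) for s in rng.integers(1, 2**31 - 1, size=2))
    ts = msprime.sim_ancestry(
        samples=model.sample_sets(), demography=model.to_demography(),
        sequence_length=length,
        recombination_rate=model.recombination_rate, random_seed=anc_seed)
    mts = msprime.sim_mutations(ts, rate=model.mutation_rate,
                                random_seed=mut_seed)
    table = site_table_from_ts(mts, model, contig=contig)
    if offset:
        table = SiteTable(table.contig, table.pos + offset, table.alt,
                          table.n)
    return table


def simulate_genome(cfg: SyntheticConfig, seed: int | None = None
                    ) -> SiteTable:
    """Simulate the multi-contig genome of *cfg* (neutral background plus
    spliced-in sweep loci) as an allele-count table.

    Each sweep locus is simulated independently under the crash-epoch model
    and replaces the neutral variants in its span; the independence across
    the splice boundary is a documented approximation.
    """
    seed = cfg.seed if seed is None else seed
    rng = np.random.default_rng([seed, 11])
    pieces = []
    for contig, length in cfg.contig_lengths.items():
        neutral = _simulate_segment(cfg.model, int(length), contig,
                                    int(rng.integers(1, 2**31 - 1)))
        loci = [s for s in cfg.sweeps if s.contig == contig]
        if loci:
            drop = IntervalSet([(contig, s.start, s.end) for s in loci])
            neutral = neutral.take(~drop.contains(neutral.contig,
                                                  neutral.pos))
        pieces.append(neutral)
        for locus in loci:
            sweep_model = with_local_sweep(
                cfg.model, cfg.sweep_pop, locus.intensity,
                cfg.sweep_end_time, cfg.sweep_duration)
            pieces.append(_simulate_segment(
                sweep_model, locus.width, contig,
                int(rng.integers(1, 2**31 - 1)), offset=locus.start))
    return SiteTable.concat(pieces)


def generate_mask(cfg: SyntheticConfig) -> IntervalSet:
    """Callable mask: random dropout of mask_tile-sized tiles."""
    rng = np.random.default_rng([cfg.seed, 23])
    records = []
    for contig, length in cfg.contig_lengths.items():
        n_tiles = int(np.ceil(length / cfg.mask_tile))
        keep = rng.random(n_tiles) >= cfg.mask_dropout
        for i in np.flatnonzero(keep):
            records.append((contig, i * cfg.mask_tile,
                            min((i + 1) * cfg.mask_tile, int(length))))
    return IntervalSet(records)


def generate_genes(cfg: SyntheticConfig) -> pd.DataFrame:
    """Gene models: random spans plus one gene anchored at each sweep
    center (so peak regions always have nearby genes)."""
    rng = np.random.default_rng([cfg.seed, 37])
    rows = []
    for locus in cfg.sweeps:
        rows.append((locus.contig, locus.center - 10_000,
                     locus.center + 10_000))
    for contig, length in cfg.contig_lengths.items():
        n = int(round(cfg.genes_per_mb * length / 1e6))
        starts = rng.integers(0, length - 50_000, size=n)
        sizes = rng.integers(2_000, 50_000, size=n)
        for s, w in zip(starts, sizes):
            rows.append((contig, int(s), int(s + w)))
    df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    df = df.sort_values(["contig", "start"]).reset_index(drop=True)
    df["gene_id"] = [f"gene{i + 1:04d}" for i in range(len(df))]
    return df


def generate_term_map(cfg: SyntheticConfig,
                      genes: pd.DataFrame) -> pd.DataFrame:
    """Flat gene->term map; the first term collects the sweep-anchored
    genes (an enriched set the enrichment test should flag)."""
    rng = np.random.default_rng([cfg.seed, 53])
    gene_ids = genes["gene_id"].tolist()
    sweep_genes = []
    for locus in cfg.sweeps:
        hit = genes[(genes["contig"] == locus.contig)
                    & (genes["end"] > locus.center)
                    & (genes["start"] <= locus.center)]
        sweep_genes.extend(hit["gene_id"])
    rows = []
    lo, hi = cfg.term_size_range
    extra = rng.choice(gene_ids, size=min(5, len(gene_ids)), replace=False)
    for g in dict.fromkeys(list(sweep_genes) + list(extra)):
        rows.append((g, "term0001", "sweep-associated process"))
    for t in range(2, cfg.n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(gene_ids, size=min(size, len(gene_ids)),
                             replace=False)
        for g in members:
            rows.append((g, f"term{t:04d}", f"process {t}"))
    return pd.DataFrame(rows, columns=["gene_id", "term_id", "term_name"])


def generate_panel_pi(cfg: SyntheticConfig,
                      wspec: WindowSpec | None = None) -> pd.DataFrame:
    """Panel window diversity on the scan grid: lognormal noise around a
    genome-wide level, reduced 12.5-fold inside sweep loci (the panel is a
    wider sample of the sweep population, so true sweeps replicate)."""
    wspec = wspec or cfg.panel_window
    rng = np.random.default_rng([cfg.seed, 71])
    grid = sliding_windows(cfg.contig_lengths, wspec)
    base = 3e-4
    pi = base * rng.lognormal(mean=0.0, sigma=0.25, size=len(grid))
    in_sweep = np.zeros(len(grid), dtype=bool)
    for locus in cfg.sweeps:
        in_sweep |= ((grid["contig"] == locus.contig)
                     & (grid["end"] > locus.start)
                     & (grid["start"] < locus.end)).to_numpy()
    pi[in_sweep] *= 0.08
    out = grid.copy()
    out["pi"] = pi
    return out


def planted_fixed_sites(cfg: SyntheticConfig) -> pd.DataFrame:
    """Sites planted as fixed-derived in the sweep population.

    Positions, functional classes and panel frequencies are drawn from a
    dedicated random stream, independent of the coalescent simulation, so
    the truth table is reproducible from the config alone.  Panel
    frequencies straddle the 0.75 retention threshold (≈70% above).  About
    30% of sites land inside sweep loci, where the class distribution is
    skewed, giving the functional-class contrast its signal.
    """
    rng = np.random.default_rng([cfg.seed, 104729])
    n = cfg.n_planted_fixed
    panel_chroms = 2 * cfg.panel_n_diploid
    rows = []
    positions_used: set[tuple[str, int]] = set()
    contigs = list(cfg.contig_lengths)
    loci = list(cfg.sweeps)
    for _ in range(n):
        in_sweep = bool(loci) and rng.random() < 0.30
        while True:
            if in_sweep:
                locus = loci[int(rng.integers(len(loci)))]
                contig = locus.contig
                pos = int(rng.integers(locus.start, locus.end))
            else:
                contig = contigs[int(rng.integers(len(contigs)))]
                pos = int(rng.integers(0, cfg.contig_lengths[contig]))
                if any(s.contig == contig and s.start <= pos < s.end
                       for s in loci):
                    continue
            if (contig, pos) not in positions_used:
                positions_used.add((contig, pos))
                break
        probs = _CLASS_P_SWEEP if in_sweep else _CLASS_P_NEUTRAL
        cls = FUNCTIONAL_CLASSES[int(rng.choice(len(FUNCTIONAL_CLASSES),
                                                p=probs))]
        if rng.random() < 0.70:
            k = int(rng.integers(int(np.ceil(0.75 * panel_chroms)),
                                 panel_chroms + 1))
        else:
            k = int(rng.integers(int(0.25 * panel_chroms),
                                 int(np.ceil(0.75 * panel_chroms))))
        rows.append((contig, pos, cls, k / panel_chroms, in_sweep))
    df = pd.DataFrame(rows, columns=["contig", "pos", "class", "freq",
                                     "in_sweep"])
    return df.sort_values(["contig", "pos"]).reset_index(drop=True)


def generate_fixed_site_truth(cfg: SyntheticConfig) -> pd.DataFrame:
    """Planted sites that the fixed-site pipeline must recover: those whose
    panel frequency clears the 0.75 threshold."""
    planted = planted_fixed_sites(cfg)
    return planted[planted["freq"] >= 0.75].reset_index(drop=True)


def _inject_planted(sites: SiteTable, planted: pd.DataFrame,
                    spec: PopulationSpec) -> SiteTable:
    """Overwrite/add planted positions: sweep population fixed for the
    alternate allele, everything else fixed reference (= ancestral)."""
    sweep = spec.sweep_pop
    n = dict(sites.n)
    alt = {}
    for pop in n:
        alt[pop] = np.full(len(planted), n[pop] if pop == sweep else 0,
                           dtype=np.int64)
    extra = SiteTable(planted["contig"].to_numpy(),
                      planted["pos"].to_numpy(), alt, n)
    return SiteTable.concat([sites, extra])


@dataclass
class Bundle:
    """Paths of one generated dataset."""

    directory: Path
    vcf: Path
    mask: Path
    genes: Path
    term_map: Path
    panel_pi: Path
    panel_freqs: Path
    site_classes: Path
    model: Path
    manifest: Path

    @classmethod
    def in_dir(cls, directory) -> "Bundle":
        d = Path(directory)
        return cls(directory=d, vcf=d / "genotypes.vcf",
                   mask=d / "callable.bed", genes=d / "genes.gff3",
                   term_map=d / "terms.tsv", panel_pi=d / "panel_pi.tsv",
                   panel_freqs=d / "panel_freqs.tsv",
                   site_classes=d / "site_classes.tsv",
                   model=d / "model.yaml", manifest=d / "manifest.json")


def _config_digest(cfg: SyntheticConfig) -> str:
    payload = json.dumps(_config_dict(cfg), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _config_dict(cfg: SyntheticConfig) -> dict:
    d = asdict(cfg)
    d["model"] = cfg.model.to_dict()
    d["sweeps"] = [asdict(s) for s in cfg.sweeps]
    return d


def generate_dataset(cfg: SyntheticConfig, outdir) -> Bundle:
    """Write the complete file bundle for *cfg* (deterministic per seed).

    Emits VCF (mixed-ploidy genotypes realizing the simulated counts),
    callable-mask BED, GFF3 genes, gene->term TSV, panel window-diversity
    TSV, planted-site panel frequencies and functional classes, the
    demographic model YAML, and a manifest with the seed and a config hash.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = Bundle.in_dir(outdir)
    spec = default_population_spec(outgroup=True)

    sites = simulate_genome(cfg)
    planted = planted_fixed_sites(cfg)
    sites = _inject_planted(sites, planted, spec)
    sio.write_vcf(bundle.vcf, sites, spec, cfg.contig_lengths)

    mask = generate_mask(cfg)
    with open(bundle.mask, "w") as fh:
        for contig, s, e in mask:
            fh.write(f"{contig}\t{s}\t{e}\n")

    genes = generate_genes(cfg)
    with open(bundle.genes, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in genes.itertuples(index=False):
            fh.write(f"{row.contig}\tsweepscan\tgene\t{row.start + 1}\t"
                     f"{row.end}\t.\t+\t.\tID={row.gene_id}\n")

    terms = generate_term_map(cfg, genes)
    terms.to_csv(bundle.term_map, sep="\t", index=False, header=False)

    sio.write_table(generate_panel_pi(cfg), bundle.panel_pi)
    sio.write_table(planted[["contig", "pos", "freq"]], bundle.panel_freqs)
    sio.write_table(planted[["contig", "pos", "class"]],
                    bundle.site_classes)
    model_to_yaml(cfg.model, bundle.model)

    manifest = {
        "seed": cfg.seed,
        "config_sha256": _config_digest(cfg),
        "contig_lengths": {k: int(v) for k, v in cfg.contig_lengths.items()},
        "sweeps": [asdict(s) for s in cfg.sweeps],
        "files": {k: str(getattr(bundle, k).name)
                  for k in ("vcf", "mask", "genes", "term_map", "panel_pi",
                            "panel_freqs", "site_classes", "model")},
    }
    bundle.manifest.write_text(json.dumps(manifest, indent=1) + "\n")
    return bundle
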