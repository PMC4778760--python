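"""Neutral null distributions of the scan statistics by coalescent
simulation of independent windows under a configurable demographic model.

The model is a population tree with piecewise-constant sizes (epochs stated
backward in time), optional continuous migration and mass-migration pulses,
and per-generation per-bp mutation and recombination rates.  Each replicate
is one fully callable window; its statistics are computed by the same
``window_stats`` operations applied to observed data, so observed and null
values share every convention (estimators, undefined-value rules, epsilon
for zero diversity).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import msprime
import numpy as np
import pandas as pd
import yaml

from .popspec import IntervalSet, PopulationSpec, SiteTable
from .windows import STATS, WindowSpec, compute_window_stats

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DemographicModel:
    """Population tree with epoch-wise sizes and sampling configuration.

    Parameters
    ----------
    populations
        Mapping population -> tuple of ``(time_ago, size)`` epochs; the
        first epoch must start at time 0 and epochs are ordered backward in
        time.  Each epoch's size applies from its start time back to the
        next epoch (or a split).
    splits
        ``(time_ago, (child_a, child_b), parent)`` events, oldest split
        listed last.  Parents are populations too (with their own epochs,
        whose pre-split entries are ignored by msprime).
    samples
        Chromosomes sampled at time 0 per (leaf) population.
    migration
        Optional symmetric continuous migration rates
        ``((pop_a, pop_b), rate)`` (per generation, backward in time).
    pulses
        Optional mass-migration pulses ``(time_ago, source, dest, fraction)``
        in forward-time parlance: a *fraction* of ``dest`` lineages trace
        back into ``source`` at ``time_ago``.
    mutation_rate, recombination_rate
        Per bp per generation.
    """

    populations: Mapping[str, tuple[tuple[float, float], ...]]
    splits: tuple[tuple[float, tuple[str, str], str], ...]
    samples: Mapping[str, int]
    mutation_rate: float
    recombination_rate: float
    migration: tuple[tuple[tuple[str, str], float], ...] = ()
    pulses: tuple[tuple[float, str, str, float], ...] = ()

    def __post_init__(self):
        if self.mutation_rate < 0 or self.recombination_rate < 0:
            raise ValueError("rates must be non-negative")
        for pop, epochs in self.populations.items():
            if not epochs or epochs[0][0] != 0:
                raise ValueError(f"population {pop!r}: first epoch must "
                                 "start at time 0")
            times = [t for t, _ in epochs]
            if any(t2 <= t1 for t1, t2 in zip(times, times[1:])):
                raise ValueError(f"population {pop!r}: epochs must be "
                                 "ordered backward in time")
            if any(s <= 0 for _, s in epochs):
                raise ValueError(f"population {pop!r}: sizes must be > 0")
        for pop in self.samples:
            if pop not in self.populations:
                raise ValueError(f"sampled population {pop!r} undefined")

    def to_demography(self) -> msprime.Demography:
        dem = msprime.Demography()
        for pop, epochs in self.populations.items():
            dem.add_population(name=pop, initial_size=epochs[0][1])
        for pop, epochs in self.populations.items():
            for t, size in epochs[1:]:
                dem.add_population_parameters_change(
                    time=t, population=pop, initial_size=size)
        for (a, b), rate in self.migration:
            dem.set_symmetric_migration_rate([a, b], rate)
        for t, source, dest, frac in self.pulses:
            # msprime's mass migration is stated backward in time
            dem.add_mass_migration(time=t, source=dest, dest=source,
                                   proportion=frac)
        for t, children, parent in self.splits:
            dem.add_population_split(time=t, derived=list(children),
                                     ancestral=parent)
        dem.sort_events()
        return dem

    def sample_sets(self) -> list[msprime.SampleSet]:
        return [msprime.SampleSet(n, population=pop, ploidy=1)
                for pop, n in self.samples.items()]

    def to_dict(self) -> dict:
        return {
            "populations": {p: [list(e) for e in eps]
                            for p, eps in self.populations.items()},
            "splits": [[t, list(ch), par] for t, ch, par in self.splits],
            "samples": dict(self.samples),
            "mutation_rate": self.mutation_rate,
            "recombination_rate": self.recombination_rate,
            "migration": [[list(k), r] for k, r in self.migration],
            "pulses": [list(p) for p in self.pulses],
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DemographicModel":
        return cls(
            populations={p: tuple((float(t), float(s)) for t, s in eps)
                         for p, eps in d["populations"].items()},
            splits=tuple((float(t), tuple(ch), par)
                         for t, ch, par in d.get("splits", [])),
            samples={p: int(n) for p, n in d["samples"].items()},
            mutation_rate=float(d["mutation_rate"]),
            recombination_rate=float(d["recombination_rate"]),
            migration=tuple((tuple(k), float(r))
                            for k, r in d.get("migration", [])),
            pulses=tuple((float(t), a, b, float(f))
                         for t, a, b, f in d.get("pulses", [])),
        )


def model_to_yaml(model: DemographicModel, path) -> None:
    Path(path).write_text(yaml.safe_dump(model.to_dict(), sort_keys=False))


def model_from_yaml(path) -> DemographicModel:
    return DemographicModel.from_dict(yaml.safe_load(Path(path).read_text()))


def default_model(with_outgroup: bool = False) -> DemographicModel:
    """Bundled two-population divergence-with-bottleneck model.

    A domestication-style history: an ancestral population of 15,000 splits
    10,000 generations ago into a "dog" lineage — which passes through a
    bottleneck of 2,000 between 3,000 and 2,500 generations ago before
    recovering to 5,000 — and a "wolf" lineage of constant size 15,000.
    The bottleneck is strong enough to distort the site-frequency spectrum
    genome-wide but brief enough that neutral windows only rarely lose most
    of their diversity (a history in which no demography-aware scan could
    separate sweeps from drift would defeat the design's purpose).
    Mutation and recombination are both 1e-8 per bp per generation.  With
    ``with_outgroup`` a third lineage (size 10,000) diverges 40,000
    generations ago from a root of the same size as the dog-wolf ancestor,
    so the focal pair's marginal history is unchanged; the outgroup is used
    only to polarize alleles.  Sample sizes follow the scanned design: 5 dog chromosomes
    (2 diploids + 1 haploid reference), 6 wolf chromosomes, 2 outgroup
    chromosomes.
    """
    populations = {
        "dog": ((0.0, 5_000.0), (2_500.0, 2_000.0), (3_000.0, 15_000.0)),
        "wolf": ((0.0, 15_000.0),),
        "anc_dw": ((0.0, 15_000.0),),
    }
    splits = [(10_000.0, ("dog", "wolf"), "anc_dw")]
    samples = {"dog": 5, "wolf": 6}
    if with_outgroup:
        populations["outgroup"] = ((0.0, 10_000.0),)
        # root size equals the dog-wolf ancestor so adding the outgroup
        # leaves the focal pair's marginal history unchanged
        populations["root"] = ((0.0, 15_000.0),)
        splits.append((40_000.0, ("anc_dw", "outgroup"), "root"))
        samples["outgroup"] = 2
    return DemographicModel(
        populations={p: tuple(e) for p, e in populations.items()},
        splits=tuple(splits), samples=samples,
        mutation_rate=1e-8, recombination_rate=1e-8)


def default_population_spec(outgroup: bool = True) -> PopulationSpec:
    """Sample/population layout matching :func:`default_model`."""
    pops = {
        "dog": (("boxer", 1), ("basenji", 2), ("dingo", 2)),
        "wolf": (("wolf1", 2), ("wolf2", 2), ("wolf3", 2)),
    }
    if outgroup:
        pops["outgroup"] = (("jackal", 2),)
    return PopulationSpec(populations=pops, focal_pair=("dog", "wolf"),
                          outgroup="outgroup" if outgroup else None)


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def site_table_from_ts(ts, model: DemographicModel,
                       contig: str = "sim") -> SiteTable:
    """Allele-count SiteTable from a mutated tree sequence.

    Counts are of non-ancestral alleles; sites with more than one derived
    state (possible under a finite-sites mutation model) are binarized as
    ancestral vs. not, which the frequency-spectrum statistics treat
    correctly as a biallelic approximation.
    """
    pops = list(model.samples)
    bounds = np.cumsum([0] + [model.samples[p] for p in pops])
    if ts.num_sites == 0:
        return SiteTable([], [], {p: [] for p in pops},
                         {p: model.samples[p] for p in pops})
    G = ts.genotype_matrix()  # sites x chromosomes
    pos = ts.sites_position.astype(np.int64)
    alt = {}
    for i, p in enumerate(pops):
        alt[p] = (G[:, bounds[i]:bounds[i + 1]] != 0).sum(axis=1)
    return SiteTable([contig] * len(pos), pos, alt,
                     {p: model.samples[p] for p in pops})


def _window_spec_full(window_bp: int) -> WindowSpec:
    return WindowSpec(size=window_bp, step=window_bp, min_callable=1)


def _sim_spec(model: DemographicModel) -> PopulationSpec:
    """Minimal PopulationSpec whose counts line up with simulated samples."""
    pops = {p: tuple((f"{p}_{i}", 1) for i in range(n))
            for p, n in model.samples.items()}
    focal = [p for p in model.samples if p in ("dog", "wolf")]
    if len(focal) != 2:
        focal = list(model.samples)[:2]
    outgroup = next((p for p in model.samples
                     if p not in focal and p == "outgroup"), None)
    return PopulationSpec(populations=pops, focal_pair=tuple(focal),
                          outgroup=outgroup)


def simulate_window_table(model: DemographicModel, n_reps: int,
                          window_bp: int, seed: int) -> pd.DataFrame:
    """Full per-replicate window statistics for *n_reps* neutral windows.

    Each replicate is an independent window of ``window_bp`` with
    recombination, treated as fully callable, run through
    :func:`sweepscan.windows.compute_window_stats`.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if model.mutation_rate == 0:
        raise ValueError("mutation rate is zero: statistics degenerate")
    rng = np.random.default_rng(seed)
    anc_seed, mut_seed = rng.integers(1, 2**31 - 1, size=2)
    spec = _sim_spec(model)
    wspec = _window_spec_full(window_bp)
    mask = IntervalSet([("sim", 0, window_bp)])
    lengths = {"sim": window_bp}
    reps = msprime.sim_ancestry(
        samples=model.sample_sets(), demography=model.to_demography(),
        sequence_length=window_bp,
        recombination_rate=model.recombination_rate,
        num_replicates=n_reps, random_seed=int(anc_seed))
    mut_rng = np.random.default_rng(mut_seed)
    rows = []
    for ts in reps:
        mts = msprime.sim_mutations(
            ts, rate=model.mutation_rate,
            random_seed=int(mut_rng.integers(1, 2**31 - 1)))
        sites = site_table_from_ts(mts, model)
        row = compute_window_stats(sites, mask, wspec, spec, lengths)
        rows.append(row.iloc[0])
    return pd.DataFrame(rows).reset_index(drop=True)


@dataclass
class NullDistribution:
    """Sorted null values per statistic, with simulation provenance."""

    values: dict[str, np.ndarray]
    n_sims: int
    mode: str  # "fixed" or "posterior"
    seed: int
    n_excluded: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.values = {k: np.sort(np.asarray(v, dtype=float))
                       for k, v in self.values.items()}

    def save(self, tsv_path, json_path=None) -> None:
        """Write values as TSV (one column per statistic, NA-padded) plus a
        JSON provenance sidecar."""
        cols = {k: pd.Series(v) for k, v in self.values.items()}
        pd.DataFrame(cols).to_csv(tsv_path, sep="\t", index=False,
                                  na_rep="NA")
        meta = {"n_sims": self.n_sims, "mode": self.mode, "seed": self.seed,
                "n_excluded": self.n_excluded}
        json_path = json_path or str(tsv_path) + ".json"
        Path(json_path).write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, tsv_path, json_path=None) -> "NullDistribution":
        df = pd.read_csv(tsv_path, sep="\t", na_values=["NA"])
        meta = json.loads(Path(json_path or str(tsv_path) + ".json")
                          .read_text())
        values = {c: df[c].dropna().to_numpy() for c in df.columns}
        return cls(values=values, n_sims=meta["n_sims"], mode=meta["mode"],
                   seed=meta["seed"],
                   n_excluded={k: int(v)
                               for k, v in meta["n_excluded"].items()})


def _collect(table: pd.DataFrame, n_sims: int, mode: str,
             seed: int) -> NullDistribution:
    values, excluded = {}, {}
    for stat in STATS:
        v = table[stat].to_numpy(dtype=float)
        defined = ~np.isnan(v)
        values[stat] = np.sort(v[defined])
        excluded[stat] = int(np.sum(~defined))
    for stat, n_ex in excluded.items():
        if n_ex:
            logger.info("null: excluded %d/%d replicates with undefined %s",
                        n_ex, n_sims, stat)
    return NullDistribution(values=values, n_sims=n_sims, mode=mode,
                            seed=seed, n_excluded=excluded)


def simulate_null(model: DemographicModel, n_reps: int, window_bp: int,
                  seed: int) -> NullDistribution:
    """Fixed-parameter null: *n_reps* neutral windows under *model*."""
    table = simulate_window_table(model, n_reps, window_bp, seed)
    return _collect(table, n_reps, "fixed", seed)


# -- posterior-draw variant -------------------------------------------------

_DRAW_PREFIXES = ("size:", "time:", "split:", "mutation_rate",
                  "recombination_rate")


def apply_draw(model: DemographicModel,
               params: Mapping[str, float]) -> DemographicModel:
    """Return *model* with parameters replaced by one posterior draw.

    Recognized keys: ``size:<pop>:<epoch>``, ``time:<pop>:<epoch>``,
    ``split:<parent>``, ``mutation_rate``, ``recombination_rate``.
    """
    populations = {p: [list(e) for e in eps]
                   for p, eps in model.populations.items()}
    splits = [[t, ch, par] for t, ch, par in model.splits]
    mu, rec = model.mutation_rate, model.recombination_rate
    for key, value in params.items():
        value = float(value)
        if key == "mutation_rate":
            mu = value
        elif key == "recombination_rate":
            rec = value
        elif key.startswith("size:"):
            _, pop, idx = key.split(":")
            populations[pop][int(idx)][1] = value
        elif key.startswith("time:"):
            _, pop, idx = key.split(":")
            populations[pop][int(idx)][0] = value
        elif key.startswith("split:"):
            parent = key.split(":", 1)[1]
            hit = [s for s in splits if s[2] == parent]
            if not hit:
                raise KeyError(f"no split with parent {parent!r}")
            hit[0][0] = value
        else:
            raise KeyError(f"unrecognized draw parameter {key!r}")
    return DemographicModel(
        populations={p: tuple(tuple(e) for e in eps)
                     for p, eps in populations.items()},
        splits=tuple((t, tuple(ch), par) for t, ch, par in splits),
        samples=model.samples, mutation_rate=mu, recombination_rate=rec,
        migration=model.migration, pulses=model.pulses)


def simulate_null_posterior(model_template: DemographicModel,
                            draws: pd.DataFrame, reps_per_draw: int,
                            window_bp: int, seed: int) -> NullDistribution:
    """Posterior-draw null: each draw row re-parameterizes the template and
    contributes *reps_per_draw* windows; statistics are concatenated."""
    if len(draws) == 0:
        raise ValueError("posterior draw table is empty")
    rng = np.random.default_rng(seed)
    tables = []
    for i, (_, row) in enumerate(draws.iterrows()):
        try:
            model = apply_draw(model_template, row.to_dict())
        except (ValueError, KeyError) as exc:
            raise ValueError(f"posterior draw row {i}: {exc}") from exc
        tables.append(simulate_window_table(
            model, reps_per_draw, window_bp,
            seed=int(rng.integers(1, 2**31 - 1))))
    table = pd.concat(tables, ignore_index=True)
    return _collect(table, len(table), "posterior", seed)
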