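"""Lineage-specific fixed derived alleles and their functional-class
enrichment in outlier vs. non-outlier regions.

A candidate fixed site is one where every sweep-population chromosome
carries the derived allele while the reference population and the outgroup
are entirely ancestral.  Candidates are then filtered on the derived-allele
frequency observed in a broader diversity panel, and the retained sites'
functional-class composition is contrasted between outlier regions and the
rest of the genome with a Pearson chi-squared test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .popspec import PopulationSpec, SiteTable
from .regions import Region

logger = logging.getLogger(__name__)


def find_fixed_derived(sites: SiteTable,
                       spec: PopulationSpec) -> pd.DataFrame:
    """Sites fixed derived in the sweep population, ancestral elsewhere.

    Requires a polarized table (outgroup-oriented alleles); sites with
    unknown ancestral state are skipped.  Returns (contig, pos,
    derived_is_alt).
    """
    if not sites.is_polarized:
        raise ValueError("SiteTable must be polarized (run polarize first)")
    sweep, ref = spec.focal_pair
    d_sweep = sites.derived(sweep)
    d_ref = sites.derived(ref)
    sel = (sites.ancestral_known
           & (d_sweep == sites.n[sweep])
           & (d_ref == 0))
    return pd.DataFrame({
        "contig": sites.contig[sel],
        "pos": sites.pos[sel],
        "derived_is_alt": sites.derived_is_alt[sel],
    })


def filter_by_panel(candidates: pd.DataFrame, panel_freqs: pd.DataFrame,
                    min_freq: float = 0.75) -> pd.DataFrame:
    """Keep candidates whose panel derived-allele frequency is >= min_freq.

    *panel_freqs* has columns (contig, pos, freq), frequencies over called
    panel chromosomes.  Candidates absent from the panel are dropped with a
    logged count.
    """
    if len(panel_freqs) and not panel_freqs["freq"].between(0, 1).all():
        raise ValueError("panel frequencies must lie in [0, 1]")
    merged = candidates.merge(panel_freqs[["contig", "pos", "freq"]],
                              on=["contig", "pos"], how="left")
    missing = merged["freq"].isna()
    if missing.any():
        logger.info("dropped %d candidate sites absent from the panel",
                    int(missing.sum()))
    out = merged[~missing & (merged["freq"] >= min_freq)]
    return out.reset_index(drop=True)


def annotate_fixed_sites(fixed: pd.DataFrame, classes: pd.DataFrame,
                         regions: list[Region]) -> pd.DataFrame:
    """Attach functional class and outlier-region membership to each site.

    *classes* has columns (contig, pos, class); sites without a class
    annotation are dropped with a logged count.
    """
    merged = fixed.merge(classes[["contig", "pos", "class"]],
                         on=["contig", "pos"], how="left")
    missing = merged["class"].isna()
    if missing.any():
        logger.info("dropped %d fixed sites without class annotation",
                    int(missing.sum()))
        merged = merged[~missing]
    in_outlier = np.zeros(len(merged), dtype=bool)
    pos = merged["pos"].to_numpy()
    contig = merged["contig"].to_numpy()
    for r in regions:
        in_outlier |= (contig == r.contig) & (pos >= r.start) & (pos < r.end)
    merged = merged.reset_index(drop=True)
    merged["in_outlier"] = in_outlier
    return merged


def functional_class_chi2(fixed: pd.DataFrame) -> tuple[float, int, float]:
    """Pearson chi-squared test of functional class x outlier status.

    Input needs columns ``class`` and ``in_outlier``.  Classes with zero
    total are dropped (warned); fewer than two remaining classes is an
    error.  Returns (statistic, df, p).
    """
    status = np.where(fixed["in_outlier"], "outlier", "background")
    table = pd.crosstab(fixed["class"], pd.Series(status, name="status"))
    for col in ("background", "outlier"):
        if col not in table.columns:
            table[col] = 0
    table = table[["background", "outlier"]]
    empty = table.sum(axis=1) == 0
    if empty.any():
        logger.warning("dropping %d empty functional classes",
                       int(empty.sum()))
        table = table[~empty]
    if len(table) < 2:
        raise ValueError("need at least two functional classes")
    if (table.sum(axis=0) == 0).any():
        raise ValueError("need fixed sites in both outlier and "
                         "non-outlier strata")
    stat, p, df, _ = chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), int(df), float(p)
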