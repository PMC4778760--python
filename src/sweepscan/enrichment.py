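"""Gene-set enrichment around region peaks: fold enrichment, hypergeometric
upper-tail p-values, and Benjamini-Hochberg correction on a percentage
scale.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .regions import Region
from .scan import bh_qvalues

logger = logging.getLogger(__name__)


def genes_near_peaks(regions: list[Region], genes: pd.DataFrame,
                     flank: int = 25_000, top_k: int = 100,
                     validated_only: bool = True) -> list[str]:
    """Genes within *flank* bp of the peak window of top-ranked regions.

    *genes* has columns (contig, start, end, gene_id).  Regions must be
    ranked; with ``validated_only`` regions whose panel validation failed
    are skipped.  A gene is included when its span intersects
    [peak_start - flank, peak_end + flank); the result is deduplicated in
    rank order.
    """
    if genes is None or genes.empty:
        raise ValueError("no gene annotation supplied")
    out: list[str] = []
    seen: set[str] = set()
    for r in sorted(regions, key=lambda r: r.rank or 0)[:top_k]:
        if validated_only and r.validation == "fail":
            continue
        if r.peak is None:
            continue
        lo, hi = r.peak[0] - flank, r.peak[1] + flank
        hit = genes[(genes["contig"] == r.contig)
                    & (genes["end"] > lo) & (genes["start"] < hi)]
        for g in hit["gene_id"]:
            if g not in seen:
                seen.add(g)
                out.append(g)
    return out


def fold_enrichment(k: int, n: int, K: int, N: int) -> float:
    """(k/n) / (K/N): input-set rate over background rate for one term."""
    if n <= 0 or K <= 0 or N <= 0:
        raise ValueError("n, K and N must be positive")
    return (k / n) / (K / N)


def enrichment_test(gene_set, term_map: pd.DataFrame,
                    background_n: int | None = None,
                    fdr_pct_max: float = 10.0) -> pd.DataFrame:
    """Hypergeometric term enrichment for an input gene set.

    For each term with background count K > 0: P(X >= k) for X
    hypergeometric(N, K, n), where N is the background gene total (all
    genes in the term map, overridable via ``background_n``), n the input
    genes present in the background, and k the input genes in the term.
    P-values are Benjamini-Hochberg corrected across tested terms
    (``p_corrected``; ``fdr_pct`` is the same quantity on a percentage
    scale) and results with at least one hit are reported at
    fdr_pct <= ``fdr_pct_max``, sorted by p.
    """
    background = set(term_map["gene_id"])
    N = int(background_n) if background_n is not None else len(background)
    genes = [g for g in dict.fromkeys(gene_set) if g in background]
    n = len(genes)
    if n == 0:
        return pd.DataFrame(columns=["term_id", "term_name", "k", "n", "K",
                                     "N", "fold", "p", "p_corrected",
                                     "fdr_pct", "genes"])
    gene_set_ = set(genes)
    rows = []
    for (term_id, term_name), sub in term_map.groupby(
            ["term_id", "term_name"], sort=True):
        members = set(sub["gene_id"])
        K = len(members)
        if K == 0:
            continue
        hits = sorted(gene_set_ & members)
        k = len(hits)
        p = float(hypergeom.sf(k - 1, N, K, n))
        rows.append({"term_id": term_id, "term_name": term_name,
                     "k": k, "n": n, "K": K, "N": N,
                     "fold": fold_enrichment(k, n, K, N),
                     "p": p, "genes": ",".join(hits)})
    res = pd.DataFrame(rows)
    if res.empty:
        return res
    res["p_corrected"] = bh_qvalues(res["p"].to_numpy())
    res["fdr_pct"] = 100.0 * res["p_corrected"]
    res = res[(res["k"] > 0) & (res["fdr_pct"] <= fdr_pct_max)]
    res = res.sort_values("p").reset_index(drop=True)
    return res[["term_id", "term_name", "k", "n", "K", "N", "fold", "p",
                "p_corrected", "fdr_pct", "genes"]]
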