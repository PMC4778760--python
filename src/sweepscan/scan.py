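"""FDR-calibrated scan: empirical p-values against a simulated neutral
null, Benjamini-Hochberg q-values, the CMS(1-FDR) composite, and the
four-way window classification.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .nullsim import NullDistribution
from .windows import STATS

logger = logging.getLogger(__name__)

CLASS_LABELS = ("low-CMS/high-FDR", "high-CMS/high-FDR",
                "low-CMS/low-FDR", "high-CMS/low-FDR")


def empirical_pvalue(obs, null_sorted: np.ndarray):
    """Upper-tail empirical p-value: (# null >= obs) / N, by binary search.

    *obs* may be a scalar or array; NaN observations give NaN p-values.
    p may be exactly 0 when the observation exceeds every null value (no
    continuity correction; this mirrors ranking by k/N).
    """
    null_sorted = np.asarray(null_sorted, dtype=float)
    N = len(null_sorted)
    if N == 0:
        raise ValueError("null distribution is empty")
    obs = np.asarray(obs, dtype=float)
    scalar = obs.ndim == 0
    obs = np.atleast_1d(obs)
    p = (N - np.searchsorted(null_sorted, obs, side="left")) / N
    p = np.where(np.isnan(obs), np.nan, p)
    return float(p[0]) if scalar else p


def bh_qvalues(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values.

    Standard step-up: for the sorted p-values p_(1) <= ... <= p_(m),
    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1, mapped back to input
    order.  NaN entries stay NaN and do not count toward m.
    """
    p = np.asarray(pvals, dtype=float)
    q = np.full(p.shape, np.nan)
    defined = ~np.isnan(p)
    pd_ = p[defined]
    if pd_.size == 0:
        return q
    if pd_.min() < 0 or pd_.max() > 1:
        raise ValueError("p-values must lie in [0, 1]")
    m = pd_.size
    order = np.argsort(pd_, kind="stable")
    ranked = pd_[order] * m / np.arange(1, m + 1)
    qs = np.minimum.accumulate(ranked[::-1])[::-1]
    qs = np.minimum(qs, 1.0)
    out = np.empty(m)
    out[order] = qs
    q[defined] = out
    return q


def cms_1_fdr(q_dpi, q_fst, q_dtd):
    """CMS(1-FDR) = (1 - q_dpi) * (1 - q_fst) * (1 - q_dtd).

    Undefined (NaN) if any constituent q is undefined; lies in [0, 1] and is
    monotone non-increasing in each q.
    """
    q_dpi, q_fst, q_dtd = (np.asarray(q, dtype=float)
                           for q in (q_dpi, q_fst, q_dtd))
    for q in (q_dpi, q_fst, q_dtd):
        with np.errstate(invalid="ignore"):
            if np.any((q < 0) | (q > 1)):
                raise ValueError("q-values must lie in [0, 1]")
    return (1 - q_dpi) * (1 - q_fst) * (1 - q_dtd)


def build_scan_table(wstats: pd.DataFrame,
                     null: NullDistribution) -> pd.DataFrame:
    """Attach per-statistic p, q and the CMS composite to a window table.

    BH is applied once per statistic across all retained windows genome-wide.
    Windows with undefined delta_td keep their fst/delta_pi q-values but get
    undefined CMS (and are excluded from CMS-based ranking downstream).
    """
    scan = wstats[["contig", "start", "end"]].copy()
    for stat in STATS:
        p = empirical_pvalue(wstats[stat].to_numpy(), null.values[stat])
        scan[f"p_{stat}"] = p
        scan[f"q_{stat}"] = bh_qvalues(p)
    scan["cms"] = cms_1_fdr(scan["q_delta_pi"], scan["q_fst"],
                            scan["q_delta_td"])
    return scan


def classify_windows(scan: pd.DataFrame, cms_threshold: float,
                     alpha: float = 0.01) -> pd.Series:
    """Four-way classification of windows by FDR and CMS level.

    low-FDR <=> min per-statistic q <= alpha; high-CMS <=> cms >=
    cms_threshold (the minimum over the top-ranked regions of each region's
    maximum CMS).  Windows with undefined CMS are excluded (NA label, count
    logged).
    """
    if not 0 <= cms_threshold <= 1:
        raise ValueError("cms_threshold must lie in [0, 1]")
    min_q = scan[[f"q_{s}" for s in STATS]].min(axis=1, skipna=True)
    low_fdr = min_q <= alpha
    high_cms = scan["cms"] >= cms_threshold
    labels = np.where(high_cms,
                      np.where(low_fdr, "high-CMS/low-FDR", "high-CMS/high-FDR"),
                      np.where(low_fdr, "low-CMS/low-FDR", "low-CMS/high-FDR"))
    out = pd.Series(labels, index=scan.index, dtype="object")
    undef = scan["cms"].isna()
    if undef.any():
        logger.info("excluded %d windows with undefined CMS from "
                    "classification", int(undef.sum()))
        out[undef] = pd.NA
    return out
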