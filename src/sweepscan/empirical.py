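"""Demography-free comparator: per-statistic empirical percentile ranks,
the joint percentile product, and top-fraction outlier flagging.

Windows are ranked by each raw statistic and ranks transformed to
percentiles in (0, 1]; the per-window product of the three percentiles is
itself percentile-ranked ("joint percentile").  No neutral model enters
anywhere, which is exactly why this comparator and the FDR-calibrated scan
can disagree.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .windows import STATS

logger = logging.getLogger(__name__)


def percentile_rank(values) -> np.ndarray:
    """Percentile of each value: (# values <= v_i) / N.

    Ties share the maximum rank, so the largest value always has percentile
    exactly 1.  NaN inputs stay NaN and do not count toward N.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    defined = ~np.isnan(v)
    if not defined.any():
        raise ValueError("no defined values to rank")
    ranks = rankdata(v[defined], method="max")
    out[defined] = ranks / defined.sum()
    return out


def joint_percentile(scan: pd.DataFrame) -> pd.DataFrame:
    """Percentile table: per-statistic percentiles, product, joint
    percentile and joint empirical p-value.

    Windows where any constituent statistic is undefined are excluded from
    the product and from the joint ranking (their joint columns are NA).
    The joint empirical p-value of a window is the probability of a joint
    percentile greater than or equal to the one observed.
    """
    out = scan[["contig", "start", "end"]].copy()
    pct = {}
    for stat in STATS:
        pct[stat] = percentile_rank(scan[stat].to_numpy())
        out[f"pct_{stat}"] = pct[stat]
    product = pct["fst"] * pct["delta_pi"] * pct["delta_td"]
    defined = ~np.isnan(product)
    if defined.sum() == 0:
        raise ValueError("no window has all three statistics defined")
    out["product"] = product
    pj = np.full(len(product), np.nan)
    pj[defined] = rankdata(product[defined], method="max") / defined.sum()
    out["pct_joint"] = pj
    # p_joint = (# pct_joint >= obs) / N  (max-tie ranks from the top)
    p = np.full(len(product), np.nan)
    p[defined] = rankdata(-pj[defined], method="max") / defined.sum()
    out["p_joint"] = p
    return out


def top_fraction(pct_joint, frac: float = 0.01) -> np.ndarray:
    """Boolean outlier mask: joint percentile strictly above 1 - frac."""
    if not 0 < frac < 1:
        raise ValueError("frac must be in (0, 1)")
    pj = np.asarray(pct_joint, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = pj > 1 - frac
    n_tied_top = int(np.sum(pj == np.nanmax(pj))) if np.isfinite(pj).any() else 0
    if n_tied_top > 1 and mask.sum() in (0, np.isfinite(pj).sum()):
        logger.info("degenerate tie structure: %d windows share the top "
                    "joint percentile", n_tied_top)
    return mask
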