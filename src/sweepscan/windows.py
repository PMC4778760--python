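"""Sliding-window summary statistics: pi, pi_between, F_ST, Tajima's D,
and the two-population contrasts delta_pi and delta_td.

All diversities are per-site averages over the callable base pairs of a
window.  F_ST follows the Hudson/Slatkin diversity form
``(pi_between - pi_within) / pi_between`` with pi_within the arithmetic mean
of the two populations' diversities.  delta_pi is
``ln(pi_reference / pi_sweep)`` and delta_td is ``TD_reference - TD_sweep``,
so a sweep in the sweep population (diversity loss, excess rare variants)
pushes all three statistics into the right tail.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .popspec import IntervalSet, PopulationSpec, SiteTable

logger = logging.getLogger(__name__)

#: the three scan statistics, as they appear in scan tables
STATS = ("fst", "delta_pi", "delta_td")


@dataclass(frozen=True)
class WindowSpec:
    """Sliding-window geometry and the callable-length retention filter."""

    size: int = 100_000
    step: int = 10_000
    min_callable: int = 30_000

    def __post_init__(self):
        if self.step <= 0 or self.size <= 0:
            raise ValueError("size and step must be positive")
        if self.step > self.size:
            raise ValueError(f"step ({self.step}) > size ({self.size})")
        if not 0 < self.min_callable <= self.size:
            raise ValueError("min_callable must be in (0, size]")


def sliding_windows(contig_lengths: Mapping[str, int],
                    spec: WindowSpec) -> pd.DataFrame:
    """Window grid [k*step, k*step+size) per contig while start < length.

    Windows overhanging the contig end are truncated (partial windows); the
    callable-length filter decides their fate downstream.
    """
    rows = []
    for contig, length in contig_lengths.items():
        length = int(length)
        if length <= 0:
            raise ValueError(f"contig {contig!r} has non-positive length")
        start = 0
        while start < length:
            rows.append((contig, start, min(start + spec.size, length)))
            start += spec.step
    return pd.DataFrame(rows, columns=["contig", "start", "end"])


# ---------------------------------------------------------------------------
# scalar statistic definitions
# ---------------------------------------------------------------------------

def _pairs(n: int) -> int:
    return n * (n - 1) // 2


def pi_within(sites: SiteTable, pop: str, window: tuple[int, int],
              callable_bp: int) -> float:
    """Per-site nucleotide diversity of *pop* in *window*.

    pi = [sum_sites c(n-c) / C(n,2)] / callable_bp, the average pairwise
    difference per callable base pair.
    """
    if callable_bp <= 0:
        return float("nan")
    n = sites.n[pop]
    sel = (sites.pos >= window[0]) & (sites.pos < window[1])
    c = sites.alt[pop][sel]
    return float(np.sum(c * (n - c)) / _pairs(n) / callable_bp)


def pi_between(sites: SiteTable, pop_a: str, pop_b: str,
               window: tuple[int, int], callable_bp: int) -> float:
    """Per-site divergence: average cross-population pairwise difference."""
    if callable_bp <= 0:
        return float("nan")
    na, nb = sites.n[pop_a], sites.n[pop_b]
    sel = (sites.pos >= window[0]) & (sites.pos < window[1])
    ca, cb = sites.alt[pop_a][sel], sites.alt[pop_b][sel]
    return float(np.sum(ca * (nb - cb) + (na - ca) * cb) / (na * nb)
                 / callable_bp)


def fst(pi_b: float, pi_1: float, pi_2: float) -> float:
    """Hudson/Slatkin F_ST = (pi_between - pi_within) / pi_between.

    pi_within is the mean of the two within-population diversities.
    Undefined (NaN) when pi_between is zero; negative values are retained.
    """
    if pi_b < 0 or pi_1 < 0 or pi_2 < 0:
        raise ValueError("diversities must be non-negative")
    if pi_b == 0:
        return float("nan")
    return (pi_b - 0.5 * (pi_1 + pi_2)) / pi_b


def _tajima_constants(n: int):
    if n < 2:
        raise ValueError("Tajima's D requires n >= 2 chromosomes")
    i = np.arange(1, n)
    a1 = np.sum(1.0 / i)
    a2 = np.sum(1.0 / i**2)
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return a1, e1, e2


def tajimas_d(S: int, pi_sum: float, n: int) -> float:
    """Tajima's (1989) D from segregating sites and total pairwise diversity.

    *pi_sum* is the mean number of pairwise differences summed over the
    window (not per site).  Returns NaN when S == 0.
    """
    a1, e1, e2 = _tajima_constants(n)
    if S == 0:
        return float("nan")
    var = e1 * S + e2 * S * (S - 1)
    return float((pi_sum - S / a1) / np.sqrt(var))


def delta_pi(pi_reference: float, pi_sweep: float, callable_bp: int,
             n_sweep: int) -> float:
    """ln(pi_reference / pi_sweep), the log diversity ratio.

    When the sweep population's diversity is exactly zero it is replaced by
    half the smallest attainable nonzero value for the window,
    0.5 / (callable_bp * C(n_sweep, 2)).  NaN when pi_reference is zero.
    """
    if callable_bp <= 0:
        raise ValueError("callable_bp must be positive")
    if pi_reference < 0 or pi_sweep < 0:
        raise ValueError("diversities must be non-negative")
    if pi_reference == 0:
        return float("nan")
    if pi_sweep == 0:
        pi_sweep = 0.5 / (callable_bp * _pairs(n_sweep))
    return float(np.log(pi_reference / pi_sweep))


# ---------------------------------------------------------------------------
# vectorized window scan
# ---------------------------------------------------------------------------

def compute_window_stats(sites: SiteTable, mask: IntervalSet,
                         spec: WindowSpec, pops: PopulationSpec,
                         contig_lengths: Mapping[str, int]) -> pd.DataFrame:
    """Per-window statistics over the sliding grid, with retention filter.

    Sites outside the callable mask are ignored; windows with fewer than
    ``spec.min_callable`` callable bp are dropped.  Column names carry the
    focal population names (e.g. ``pi_dog``); the contrast columns are
    always ``fst``, ``delta_pi``, ``delta_td``.
    """
    p1, p2 = pops.focal_pair  # sweep, reference
    n1, n2 = pops.n_chrom(p1), pops.n_chrom(p2)
    k1, k2 = _pairs(n1), _pairs(n2)
    a1_1, e1_1, e2_1 = _tajima_constants(n1)
    a1_2, e1_2, e2_2 = _tajima_constants(n2)

    grid = sliding_windows(contig_lengths, spec)
    masked = sites.restrict_to(mask)

    frames = []
    for contig in grid["contig"].unique():
        g = grid[grid["contig"] == contig]
        st = masked.contig_slice(contig)
        pos = st.pos
        c1, c2 = st.alt[p1], st.alt[p2]
        pd_site = (c1 * (n1 - c1)).astype(float)
        pw_site = (c2 * (n2 - c2)).astype(float)
        pb_site = (c1 * (n2 - c2) + (n1 - c1) * c2).astype(float)
        seg1 = ((c1 > 0) & (c1 < n1)).astype(float)
        seg2 = ((c2 > 0) & (c2 < n2)).astype(float)
        cums = [np.concatenate(([0.0], np.cumsum(v)))
                for v in (pd_site, pw_site, pb_site, seg1, seg2)]

        starts = g["start"].to_numpy()
        ends = g["end"].to_numpy()
        i0 = np.searchsorted(pos, starts, side="left")
        i1 = np.searchsorted(pos, ends, side="left")
        sum_pd, sum_pw, sum_pb, S1, S2 = (c[i1] - c[i0] for c in cums)
        callable_bp = np.array(
            [mask.length_in(contig, s, e) for s, e in zip(starts, ends)],
            dtype=np.int64)

        keep = callable_bp >= spec.min_callable
        if not keep.any():
            continue
        cb = callable_bp[keep].astype(float)
        sum_pd, sum_pw, sum_pb = sum_pd[keep], sum_pw[keep], sum_pb[keep]
        S1, S2 = S1[keep].astype(int), S2[keep].astype(int)

        pi1 = sum_pd / k1 / cb
        pi2 = sum_pw / k2 / cb
        pib = sum_pb / (n1 * n2) / cb
        pibar = 0.5 * (pi1 + pi2)
        with np.errstate(divide="ignore", invalid="ignore"):
            fst_v = np.where(pib > 0, (pib - pibar) / pib, np.nan)

            # Tajima's D per population; NaN when S == 0
            def _td(S, pi_sum, a1, e1, e2):
                var = e1 * S + e2 * S * (S - 1)
                d = (pi_sum - S / a1) / np.sqrt(var)
                return np.where(S > 0, d, np.nan)

            td1 = _td(S1, sum_pd / k1, a1_1, e1_1, e2_1)
            td2 = _td(S2, sum_pw / k2, a1_2, e1_2, e2_2)

            eps = 0.5 / (cb * k1)
            pi1_adj = np.where(pi1 > 0, pi1, eps)
            dpi = np.where(pi2 > 0, np.log(pi2 / pi1_adj), np.nan)
        dtd = td2 - td1  # NaN propagates from either side

        frames.append(pd.DataFrame({
            "contig": contig,
            "start": starts[keep], "end": ends[keep],
            "callable_bp": callable_bp[keep],
            f"S_{p1}": S1, f"S_{p2}": S2,
            f"pi_{p1}": pi1, f"pi_{p2}": pi2, "pi_between": pib,
            "fst": fst_v,
            f"td_{p1}": td1, f"td_{p2}": td2,
            "delta_pi": dpi, "delta_td": dtd,
        }))
    if not frames:
        logger.warning("no windows passed the callable-length filter")
        cols = (["contig", "start", "end", "callable_bp",
                 f"S_{p1}", f"S_{p2}", f"pi_{p1}", f"pi_{p2}", "pi_between",
                 "fst", f"td_{p1}", f"td_{p2}", "delta_pi", "delta_td"])
        out = pd.DataFrame(columns=cols)
    else:
        out = pd.concat(frames, ignore_index=True)
    out.attrs["focal_pair"] = (p1, p2)
    return out
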