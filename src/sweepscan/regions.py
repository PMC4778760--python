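"""Region calling: merge significant windows into candidate regions, rank
them by their best composite score, compare region sets between methods,
and apply the diversity-panel validation filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .windows import STATS

logger = logging.getLogger(__name__)


@dataclass
class Region:
    """A merged run of significant windows on one contig.

    ``members`` are the (start, end) member windows; ``stats`` records which
    statistics were significant in at least one member.  ``score`` is the
    maximum composite score (CMS or joint percentile) over members, ``peak``
    the member window attaining it.  ``validation`` is one of
    {"untested", "pass", "fail"}.
    """

    contig: str
    start: int
    end: int
    members: list[tuple[int, int]] = field(default_factory=list)
    stats: set = field(default_factory=set)
    score: float = float("nan")
    peak: tuple[int, int] | None = None
    rank: int | None = None
    display_rank: float | None = None
    validation: str = "untested"

    @property
    def length(self) -> int:
        return self.end - self.start


def significant_windows(scan: pd.DataFrame, alpha: float = 0.01,
                        stats=STATS) -> pd.DataFrame:
    """Windows with q <= alpha for at least one statistic, tagged by which."""
    frames = []
    for stat in stats:
        sel = scan[f"q_{stat}"] <= alpha
        sub = scan.loc[sel, ["contig", "start", "end"]].copy()
        sub["stat"] = stat
        frames.append(sub)
    if not frames:
        return pd.DataFrame(columns=["contig", "start", "end", "stat"])
    return pd.concat(frames, ignore_index=True)


def call_regions(sig: pd.DataFrame, max_gap: int = 200_000) -> list[Region]:
    """Merge tagged significant windows into regions.

    Windows (across statistics) join transitively whenever the gap between
    the growing region envelope's end and the next window's start is at
    most ``max_gap``; the region span is the union envelope of its members.
    Output is sorted by (contig, start) and independent of input order.
    """
    regions: list[Region] = []
    if sig.empty:
        return regions
    for contig, group in sig.groupby("contig", sort=True):
        group = group.sort_values(["start", "end"])
        cur: Region | None = None
        for row in group.itertuples(index=False):
            w = (int(row.start), int(row.end))
            if cur is not None and w[0] - cur.end <= max_gap:
                cur.end = max(cur.end, w[1])
                if w not in cur.members:
                    cur.members.append(w)
                cur.stats.add(row.stat)
            else:
                if cur is not None:
                    regions.append(cur)
                cur = Region(contig=str(contig), start=w[0], end=w[1],
                             members=[w], stats={row.stat})
        if cur is not None:
            regions.append(cur)
    return regions


def rank_regions(regions: list[Region], scan: pd.DataFrame,
                 score_col: str = "cms") -> list[Region]:
    """Score regions by the maximum *score_col* over member windows and
    rank them.

    Descending by score; ties broken by longer region, then (contig,
    start).  Tied scores additionally get an average display rank (so two
    regions tied across display positions 2 and 3 both show 2.5).  Regions
    whose members all have undefined scores are excluded with a warning.
    """
    score_map = {(c, int(s), int(e)): v for c, s, e, v in zip(
        scan["contig"], scan["start"], scan["end"], scan[score_col])}
    kept = []
    for r in regions:
        vals = [score_map.get((r.contig, s, e), np.nan) for s, e in r.members]
        vals = np.asarray(vals, dtype=float)
        if np.all(np.isnan(vals)):
            logger.warning("region %s:%d-%d has no defined %s score; "
                           "excluded from ranking", r.contig, r.start, r.end,
                           score_col)
            continue
        i = int(np.nanargmax(vals))
        r.score = float(vals[i])
        r.peak = r.members[i]
        kept.append(r)
    kept.sort(key=lambda r: (-r.score, -r.length, r.contig, r.start))
    for i, r in enumerate(kept, start=1):
        r.rank = i
    scores = np.array([r.score for r in kept])
    for r in kept:
        tied = np.flatnonzero(scores == r.score)
        r.display_rank = float(tied.mean() + 1)
    return kept


def cms_threshold_top_k(ranked: list[Region], k: int = 100) -> float:
    """Minimum over the top-k regions of each region's maximum score.

    Feeds the high-CMS classification threshold.  With fewer than *k*
    regions, all are used (with a warning).
    """
    if not ranked:
        raise ValueError("no ranked regions")
    if len(ranked) < k:
        logger.warning("only %d regions available for top-%d threshold",
                       len(ranked), k)
    top = ranked[:k]
    return float(min(r.score for r in top))


def compare_region_sets(a: list[Region], b: list[Region]) -> dict:
    """Overlap bookkeeping between two region sets.

    For each region in *a*, the total bp shared with any region of *b* (and
    vice versa), plus the fraction of each set with no overlap at all.
    """
    def overlaps(x: Region, ys: list[Region]) -> int:
        total = 0
        for y in ys:
            if y.contig != x.contig:
                continue
            total += max(0, min(x.end, y.end) - max(x.start, y.start))
        return total

    ov_a = [overlaps(r, b) for r in a]
    ov_b = [overlaps(r, a) for r in b]
    return {
        "overlap_bp_a": ov_a,
        "overlap_bp_b": ov_b,
        "frac_a_without_overlap": (float(np.mean([v == 0 for v in ov_a]))
                                   if a else float("nan")),
        "frac_b_without_overlap": (float(np.mean([v == 0 for v in ov_b]))
                                   if b else float("nan")),
    }


def validate_with_panel(regions: list[Region], panel: pd.DataFrame,
                        flank_bp: int = 500_000) -> list[Region]:
    """Diversity-panel validation of candidate regions.

    *panel* must carry per-window diversity (columns contig, start, end,
    pi) on the same window grid as the scan.  A region FAILS when mean
    panel diversity over its member windows is greater than or equal to the
    mean over non-member windows within ``flank_bp`` on either side; it
    PASSES otherwise and stays "untested" when the flank holds no windows.
    """
    grid = {(c, int(s), int(e)): float(p) for c, s, e, p in zip(
        panel["contig"], panel["start"], panel["end"], panel["pi"])}
    for r in regions:
        try:
            member_pi = [grid[(r.contig, s, e)] for s, e in r.members]
        except KeyError as exc:
            raise ValueError(
                f"panel window grid does not cover member window {exc} of "
                f"region {r.contig}:{r.start}-{r.end}") from exc
        member_set = set(r.members)
        flank_pi = [
            p for (c, s, e), p in grid.items()
            if c == r.contig and (s, e) not in member_set
            and s >= r.start - flank_bp and e <= r.end + flank_bp
            and (e <= r.start or s >= r.end)]
        if not flank_pi:
            r.validation = "untested"
        elif float(np.mean(member_pi)) >= float(np.mean(flank_pi)):
            r.validation = "fail"
        else:
            r.validation = "pass"
    return regions


def regions_to_frame(regions: list[Region]) -> pd.DataFrame:
    """Flatten Region objects for TSV output."""
    rows = []
    for r in regions:
        rows.append({
            "contig": r.contig, "start": r.start, "end": r.end,
            "n_windows": len(r.members),
            "stats": ",".join(sorted(r.stats)),
            "score": r.score,
            "peak_start": r.peak[0] if r.peak else np.nan,
            "peak_end": r.peak[1] if r.peak else np.nan,
            "rank": r.rank, "display_rank": r.display_rank,
            "validation": r.validation,
        })
    return pd.DataFrame(rows)
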