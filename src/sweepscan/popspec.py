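"""Population/ploidy specification and the per-site allele-count table.

The scan contrasts two focal populations (a putative sweep population and a
reference population, e.g. dog vs. wolf) with an optional outgroup used only
to orient alleles as derived vs. ancestral.  Samples may be haploid or
diploid; all per-site bookkeeping is in units of chromosomes, so a mixture
(e.g. a haploid reference genome alongside diploid individuals) is handled
uniformly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np


@dataclass(frozen=True)
class PopulationSpec:
    """Assignment of samples to populations, with per-sample ploidy.

    Parameters
    ----------
    populations
        Mapping population name -> sequence of ``(sample_name, ploidy)``
        pairs, ploidy in {1, 2}.
    focal_pair
        ``(sweep_pop, reference_pop)`` — the pair of populations scanned.
        Contrast statistics (delta_pi, delta_td) are oriented so that reduced
        diversity / skewed frequency spectra in the sweep population fall in
        the right tail.
    outgroup
        Name of the outgroup population, or ``None``.  Used only to polarize
        alleles; never one of the focal populations.
    """

    populations: Mapping[str, tuple[tuple[str, int], ...]]
    focal_pair: tuple[str, str]
    outgroup: str | None = None

    def __post_init__(self):
        pops = {name: tuple((str(s), int(p)) for s, p in members)
                for name, members in self.populations.items()}
        object.__setattr__(self, "populations", pops)
        seen: dict[str, str] = {}
        for name, members in pops.items():
            if not members:
                raise ValueError(f"population {name!r} has no samples")
            for sample, ploidy in members:
                if ploidy not in (1, 2):
                    raise ValueError(
                        f"sample {sample!r}: ploidy must be 1 or 2, got {ploidy}")
                if sample in seen:
                    raise ValueError(
                        f"sample {sample!r} appears in both {seen[sample]!r} "
                        f"and {name!r}")
                seen[sample] = name
        sweep, ref = self.focal_pair
        for pop in (sweep, ref):
            if pop not in pops:
                raise ValueError(f"focal population {pop!r} not defined")
            if self.n_chrom(pop) < 2:
                raise ValueError(
                    f"focal population {pop!r} has fewer than 2 chromosomes")
        if sweep == ref:
            raise ValueError("focal populations must differ")
        if self.outgroup is not None:
            if self.outgroup not in pops:
                raise ValueError(f"outgroup {self.outgroup!r} not defined")
            if self.outgroup in self.focal_pair:
                raise ValueError("outgroup cannot be a focal population")

    # -- convenience accessors -------------------------------------------

    @property
    def pop_names(self) -> tuple[str, ...]:
        return tuple(self.populations)

    @property
    def sweep_pop(self) -> str:
        return self.focal_pair[0]

    @property
    def reference_pop(self) -> str:
        return self.focal_pair[1]

    def samples_of(self, pop: str) -> tuple[tuple[str, int], ...]:
        return self.populations[pop]

    def n_chrom(self, pop: str) -> int:
        """Chromosome sample size of *pop* (sum of sample ploidies)."""
        return sum(p for _, p in self.populations[pop])

    def all_samples(self) -> list[tuple[str, str, int]]:
        """All samples as ``(sample, population, ploidy)`` in spec order."""
        return [(s, name, p)
                for name, members in self.populations.items()
                for s, p in members]


class SiteTable:
    """Per-site alternate-allele counts over fully observed biallelic SNVs.

    Columns are parallel numpy arrays sorted by (contig, position).  Counts
    are chromosome counts; at every retained site every sample is called, so
    the number of observed chromosomes per population equals the population's
    chromosome sample size.

    Attributes
    ----------
    contig : ndarray of str, per site
    pos : ndarray of int64, 0-based positions, strictly increasing per contig
    alt : dict pop -> ndarray of int, alternate-allele chromosome counts
    n : dict pop -> int, chromosome sample size
    derived_is_alt : ndarray of bool or None
        After polarization: True where the derived allele is the alternate
        allele.  Meaningful only where ``ancestral_known``.
    ancestral_known : ndarray of bool or None
    """

    def __init__(self, contig, pos, alt: Mapping[str, np.ndarray],
                 n: Mapping[str, int], derived_is_alt=None,
                 ancestral_known=None):
        self.contig = np.asarray(contig, dtype=object)
        self.pos = np.asarray(pos, dtype=np.int64)
        self.alt = {k: np.asarray(v, dtype=np.int64) for k, v in alt.items()}
        self.n = dict(n)
        self.derived_is_alt = (None if derived_is_alt is None
                               else np.asarray(derived_is_alt, dtype=bool))
        self.ancestral_known = (None if ancestral_known is None
                                else np.asarray(ancestral_known, dtype=bool))
        self._validate()

    def _validate(self):
        m = len(self.pos)
        if len(self.contig) != m:
            raise ValueError("contig/pos length mismatch")
        for pop, a in self.alt.items():
            if len(a) != m:
                raise ValueError(f"count array for {pop!r} has wrong length")
            n = self.n[pop]
            if m and (a.min() < 0 or a.max() > n):
                raise ValueError(f"alt counts for {pop!r} outside [0, {n}]")
        for arr in (self.derived_is_alt, self.ancestral_known):
            if arr is not None and len(arr) != m:
                raise ValueError("polarization array has wrong length")
        # strictly increasing positions within each contig block
        if m > 1:
            same = self.contig[1:] == self.contig[:-1]
            if np.any(same & (np.diff(self.pos) <= 0)):
                raise ValueError("positions not strictly increasing per contig")

    # -- basics -----------------------------------------------------------

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def is_polarized(self) -> bool:
        return self.derived_is_alt is not None

    def contigs(self) -> list[str]:
        out, seen = [], set()
        for c in self.contig:
            if c not in seen:
                seen.add(c)
                out.append(c)
        return out

    def take(self, index) -> "SiteTable":
        """Subset by integer or boolean index, preserving order."""
        return SiteTable(
            self.contig[index], self.pos[index],
            {k: v[index] for k, v in self.alt.items()}, self.n,
            None if self.derived_is_alt is None else self.derived_is_alt[index],
            None if self.ancestral_known is None else self.ancestral_known[index],
        )

    def contig_slice(self, name: str) -> "SiteTable":
        return self.take(self.contig == name)

    def derived(self, pop: str) -> np.ndarray:
        """Derived-allele chromosome counts (requires polarization).

        Values at sites with ``ancestral_known == False`` are placeholders
        and must be gated by that flag by the caller.
        """
        if not self.is_polarized:
            raise ValueError("SiteTable is not polarized")
        a = self.alt[pop]
        return np.where(self.derived_is_alt, a, self.n[pop] - a)

    def restrict_to(self, intervals: "IntervalSet") -> "SiteTable":
        """Keep only sites falling inside *intervals*."""
        return self.take(intervals.contains(self.contig, self.pos))

    @staticmethod
    def concat(tables: Sequence["SiteTable"]) -> "SiteTable":
        """Concatenate and sort by (contig, position).

        All tables must share the same populations and sample sizes; later
        tables win on duplicate (contig, position) keys.
        """
        if not tables:
            raise ValueError("nothing to concatenate")
        n = tables[0].n
        for t in tables[1:]:
            if t.n != n:
                raise ValueError("sample configurations differ")
        contig = np.concatenate([t.contig for t in tables])
        pos = np.concatenate([t.pos for t in tables])
        alt = {p: np.concatenate([t.alt[p] for t in tables]) for p in n}
        polarized = all(t.is_polarized for t in tables)
        dia = (np.concatenate([t.derived_is_alt for t in tables])
               if polarized else None)
        ak = (np.concatenate([t.ancestral_known for t in tables])
              if polarized else None)
        # stable sort keeps the *last* duplicate after reversing
        order = np.lexsort((pos, contig))
        contig, pos = contig[order], pos[order]
        alt = {p: v[order] for p, v in alt.items()}
        if polarized:
            dia, ak = dia[order], ak[order]
        keep = np.ones(len(pos), dtype=bool)
        if len(pos) > 1:
            dup = (contig[1:] == contig[:-1]) & (pos[1:] == pos[:-1])
            keep[:-1][dup] = False
        return SiteTable(contig[keep], pos[keep],
                         {p: v[keep] for p, v in alt.items()}, n,
                         dia[keep] if polarized else None,
                         ak[keep] if polarized else None)


class IntervalSet:
    """Normalized set of 0-based half-open genomic intervals.

    Intervals are sorted and merged (overlapping or book-ended intervals
    collapse) at construction, so normalization is idempotent and the total
    length is invariant under input permutation.
    """

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        by_contig: dict[str, list[tuple[int, int]]] = {}
        for contig, start, end in intervals:
            start, end = int(start), int(end)
            if start >= end:
                raise ValueError(
                    f"degenerate interval {contig}:{start}-{end} (start >= end)")
            by_contig.setdefault(str(contig), []).append((start, end))
        self._ivals: dict[str, np.ndarray] = {}
        for contig, ivs in sorted(by_contig.items()):
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1]:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self._ivals[contig] = np.asarray(merged, dtype=np.int64)

    def __iter__(self):
        for contig, arr in self._ivals.items():
            for s, e in arr:
                yield contig, int(s), int(e)

    def __len__(self) -> int:
        return sum(len(a) for a in self._ivals.values())

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        if set(self._ivals) != set(other._ivals):
            return False
        return all(np.array_equal(self._ivals[c], other._ivals[c])
                   for c in self._ivals)

    def contigs(self) -> list[str]:
        return list(self._ivals)

    def intervals(self, contig: str) -> np.ndarray:
        """(k, 2) array of [start, end) for *contig* (empty if absent)."""
        return self._ivals.get(contig, np.empty((0, 2), dtype=np.int64))

    @property
    def total_length(self) -> int:
        return int(sum((a[:, 1] - a[:, 0]).sum() for a in self._ivals.values()))

    def length_in(self, contig: str, start: int, end: int) -> int:
        """Total covered bp inside [start, end) on *contig*."""
        arr = self.intervals(contig)
        if not len(arr):
            return 0
        s, e = arr[:, 0], arr[:, 1]
        lo = np.searchsorted(e, start, side="right")
        hi = np.searchsorted(s, end, side="left")
        if lo >= hi:
            return 0
        return int(np.sum(np.minimum(e[lo:hi], end) - np.maximum(s[lo:hi], start)))

    def contains(self, contig, pos) -> np.ndarray:
        """Boolean array: does each (contig[i], pos[i]) fall in the set?"""
        contig = np.asarray(contig, dtype=object)
        pos = np.asarray(pos, dtype=np.int64)
        out = np.zeros(len(pos), dtype=bool)
        for c in np.unique(contig):
            arr = self.intervals(c)
            sel = contig == c
            if not len(arr):
                continue
            p = pos[sel]
            idx = np.searchsorted(arr[:, 0], p, side="right") - 1
            ok = idx >= 0
            ok[ok] &= p[ok] < arr[idx[ok], 1]
            out[sel] = ok
        return out

    def to_records(self) -> list[tuple[str, int, int]]:
        return list(self)
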