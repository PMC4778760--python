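"""Window statistics against brute-force pair-enumeration oracles and the
stated edge-case rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sweepscan.popspec import IntervalSet, PopulationSpec, SiteTable
from sweepscan.windows import (WindowSpec, compute_window_stats, delta_pi,
                               fst, pi_between, pi_within, sliding_windows,
                               tajimas_d)

from conftest import make_sites


# ---------------------------------------------------------------------------
# brute-force oracles over explicit genotype matrices (chromosomes x sites)
# ---------------------------------------------------------------------------

def pi_within_oracle(G, L):
    """Mean pairwise Hamming distance per site by O(n^2) enumeration."""
    n = G.shape[0]
    total = sum(np.sum(G[i] != G[j])
                for i in range(n) for j in range(i + 1, n))
    return total / (n * (n - 1) / 2) / L


def pi_between_oracle(GA, GB, L):
    total = sum(np.sum(a != b) for a in GA for b in GB)
    return total / (GA.shape[0] * GB.shape[0]) / L


def tajima_oracle(S, pi_sum, n):
    """Independent constant-by-constant Tajima (1989) implementation."""
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n * n + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1, e2 = c1 / a1, c2 / (a1**2 + a2)
    return (pi_sum - S / a1) / np.sqrt(e1 * S + e2 * S * (S - 1))


def matrices_to_sites(Gd, Gw, L):
    m = Gd.shape[1]
    return SiteTable(["c"] * m, np.arange(m),
                     {"dog": Gd.sum(axis=0), "wolf": Gw.sum(axis=0)},
                     {"dog": Gd.shape[0], "wolf": Gw.shape[0]})


class TestSlidingWindows:
    def test_grid_arithmetic(self):
        w = sliding_windows({"c": 120_000}, WindowSpec())
        assert list(w["start"]) == list(range(0, 120_000, 10_000))
        assert w["end"].max() == 120_000

    def test_single_window_contig(self):
        w = sliding_windows({"c": 100_000}, WindowSpec())
        assert (w["start"] == 0).iloc[0] and w["end"].iloc[0] == 100_000
        # later partial windows exist but are truncated at the contig end
        assert (w["end"] <= 100_000).all()

    def test_step_larger_than_size_rejected(self):
        with pytest.raises(ValueError):
            WindowSpec(size=5, step=10)


class TestPi:
    def test_single_site_arithmetic(self):
        sites = make_sites("chr1", [3], [2], [0], n={"dog": 5, "wolf": 6,
                                                     "outgroup": 2})
        assert pi_within(sites, "dog", (0, 10), 10) == pytest.approx(0.06)

    def test_monomorphic_is_zero(self, tiny_sites):
        sites = make_sites("chr1", [1, 2], [0, 5], [0, 6])
        assert pi_within(sites, "dog", (0, 10), 10) == 0.0
        assert pi_within(sites, "wolf", (0, 10), 10) == 0.0

    def test_fixed_difference_is_one_per_bp(self):
        sites = make_sites("chr1", [0], [5], [0])
        assert pi_between(sites, "dog", "wolf", (0, 1), 1) == 1.0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_matches_bruteforce_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = rng.integers(2, 9, size=2)
        m, L = int(rng.integers(1, 60)), 200
        Gd = rng.integers(0, 2, size=(n1, m))
        Gw = rng.integers(0, 2, size=(n2, m))
        sites = matrices_to_sites(Gd, Gw, L)
        got = pi_within(sites, "dog", (0, m), L)
        assert got == pytest.approx(pi_within_oracle(Gd, L), abs=1e-12)
        got_b = pi_between(sites, "dog", "wolf", (0, m), L)
        assert got_b == pytest.approx(pi_between_oracle(Gd, Gw, L),
                                      abs=1e-12)


class TestFst:
    def test_half(self):
        assert fst(0.2, 0.1, 0.1) == pytest.approx(0.5)

    def test_zero_when_within_equals_between(self):
        assert fst(0.1, 0.1, 0.1) == 0.0

    def test_one_for_pure_fixed_differences(self):
        assert fst(0.3, 0.0, 0.0) == 1.0

    def test_undefined_when_between_zero(self):
        assert np.isnan(fst(0.0, 0.0, 0.0))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            fst(0.1, -0.1, 0.1)


class TestTajimasD:
    def test_undefined_without_segregating_sites(self):
        assert np.isnan(tajimas_d(0, 0.0, 6))

    def test_zero_at_neutral_identity(self):
        a1 = sum(1.0 / i for i in range(1, 6))
        assert tajimas_d(10, 10 / a1, 6) == pytest.approx(0.0)

    def test_known_value_and_oracle_agreement(self):
        assert tajimas_d(10, 3.0, 6) == pytest.approx(-1.89, abs=0.005)
        for S, pi_sum, n in [(10, 3.0, 6), (5, 8.0, 4), (37, 20.0, 11)]:
            assert tajimas_d(S, pi_sum, n) == pytest.approx(
                tajima_oracle(S, pi_sum, n), abs=1e-12)

    def test_requires_two_chromosomes(self):
        with pytest.raises(ValueError):
            tajimas_d(3, 1.0, 1)


class TestDeltaPi:
    def test_log_ratio(self):
        assert delta_pi(0.002, 0.001, 10_000, 5) == pytest.approx(np.log(2))

    def test_zero_at_equal_diversity(self):
        assert delta_pi(0.001, 0.001, 10_000, 5) == 0.0

    def test_epsilon_rule_for_zero_sweep_diversity(self):
        # denominator becomes 0.5/(10000 * C(5,2)) = 5e-6
        got = delta_pi(0.002, 0.0, 10_000, 5)
        assert got == pytest.approx(np.log(0.002 / 5e-6))

    def test_undefined_when_reference_zero(self):
        assert np.isnan(delta_pi(0.0, 0.001, 10_000, 5))


class TestComputeWindowStats:
    @pytest.fixture
    def pops(self):
        return PopulationSpec(
            populations={"dog": (("d1", 2), ("d2", 2), ("d0", 1)),
                         "wolf": (("w1", 2), ("w2", 2), ("w3", 2))},
            focal_pair=("dog", "wolf"))

    def test_callable_threshold_boundary(self, pops):
        sites = make_sites("chr1", [10], [2], [3])
        spec = WindowSpec(size=100_000, step=100_000, min_callable=30_000)
        below = IntervalSet([("chr1", 0, 29_999)])
        at = IntervalSet([("chr1", 0, 30_000)])
        lengths = {"chr1": 100_000}
        assert len(compute_window_stats(sites, below, spec, pops,
                                        lengths)) == 0
        out = compute_window_stats(sites, at, spec, pops, lengths)
        assert len(out) == 1 and out["callable_bp"].iloc[0] == 30_000

    def test_vectorized_equals_scalar_ops(self, pops, rng):
        m = 150
        pos = np.sort(rng.choice(50_000, m, replace=False))
        sites = make_sites("chr1", pos, rng.integers(0, 6, m),
                           rng.integers(0, 7, m))
        mask = IntervalSet([("chr1", 0, 40_000), ("chr1", 45_000, 60_000)])
        spec = WindowSpec(size=20_000, step=5_000, min_callable=5_000)
        out = compute_window_stats(sites, mask, spec, pops,
                                   {"chr1": 60_000})
        masked = sites.restrict_to(mask)
        for row in out.itertuples(index=False):
            w = (row.start, row.end)
            cb = mask.length_in("chr1", *w)
            assert row.callable_bp == cb
            assert row.pi_dog == pytest.approx(
                pi_within(masked, "dog", w, cb), abs=1e-15)
            assert row.pi_between == pytest.approx(
                pi_between(masked, "dog", "wolf", w, cb), abs=1e-15)

    def test_differentiated_block_attains_max_fst(self, pops, rng):
        # neutral-ish polymorphism plus a 100 kb block of fixed differences
        pos_bg = np.arange(0, 1_000_000, 2_000)
        alt_d = rng.integers(1, 5, len(pos_bg))
        alt_w = alt_d + rng.integers(0, 2, len(pos_bg))
        block = (pos_bg >= 400_000) & (pos_bg < 500_000)
        alt_d[block], alt_w[block] = 5, 0
        sites = make_sites("chr1", pos_bg, alt_d, alt_w)
        mask = IntervalSet([("chr1", 0, 1_000_000)])
        out = compute_window_stats(sites, mask, WindowSpec(), pops,
                                   {"chr1": 1_000_000})
        best = out.loc[out["fst"].idxmax()]
        assert best["start"] == 400_000
        assert best["fst"] == 1.0  # no shared polymorphism in the block

    def test_focal_swap_negates_contrasts(self, rng):
        pops = PopulationSpec(
            populations={"dog": (("d1", 2), ("d2", 2), ("d0", 1)),
                         "wolf": (("w1", 2), ("w2", 2), ("w3", 2))},
            focal_pair=("dog", "wolf"))
        swapped = PopulationSpec(
            populations=pops.populations, focal_pair=("wolf", "dog"))
        m = 120
        pos = np.sort(rng.choice(40_000, m, replace=False))
        sites = make_sites("chr1", pos, rng.integers(1, 5, m),
                           rng.integers(1, 6, m))
        mask = IntervalSet([("chr1", 0, 40_000)])
        spec = WindowSpec(size=40_000, step=40_000, min_callable=1_000)
        a = compute_window_stats(sites, mask, spec, pops, {"chr1": 40_000})
        b = compute_window_stats(sites, mask, spec, swapped,
                                 {"chr1": 40_000})
        assert b["delta_pi"].iloc[0] == pytest.approx(
            -a["delta_pi"].iloc[0], abs=1e-12)
        assert b["delta_td"].iloc[0] == pytest.approx(
            -a["delta_td"].iloc[0], abs=1e-12)
        assert b["fst"].iloc[0] == pytest.approx(a["fst"].iloc[0],
                                                 abs=1e-12)
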