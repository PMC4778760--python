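"""Coalescent null simulation: determinism, closed-form neutral
expectations, posterior-draw equivalence, and model plumbing."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ks_2samp

from sweepscan.nullsim import (DemographicModel, NullDistribution,
                               apply_draw, default_model, model_from_yaml,
                               model_to_yaml, simulate_null,
                               simulate_null_posterior,
                               simulate_window_table)


def panmictic_pair(n_eff=10_000.0):
    """Two populations splitting one generation ago with equal sizes —
    effectively a single panmictic population, so closed-form neutral
    expectations apply to each and F_ST is centred on zero."""
    return DemographicModel(
        populations={"dog": ((0.0, n_eff),), "wolf": ((0.0, n_eff),),
                     "anc": ((0.0, n_eff),)},
        splits=((1.0, ("dog", "wolf"), "anc"),),
        samples={"dog": 5, "wolf": 6},
        mutation_rate=1e-8, recombination_rate=1e-8)


class TestSimulateNull:
    def test_same_seed_bit_identical(self):
        a = simulate_null(default_model(), 40, 50_000, seed=9)
        b = simulate_null(default_model(), 40, 50_000, seed=9)
        for stat in a.values:
            assert np.array_equal(a.values[stat], b.values[stat])
        assert a.n_excluded == b.n_excluded

    def test_neutral_closed_form_expectations(self):
        # theta = 4*N*mu per bp; E[pi] = theta, E[TD] ~ 0, E[FST] ~ 0
        model = panmictic_pair()
        tab = simulate_window_table(model, 400, 50_000, seed=123)
        theta = 4 * 10_000 * 1e-8
        for pop in ("dog", "wolf"):
            pi = tab[f"pi_{pop}"]
            se = pi.std() / np.sqrt(len(pi))
            assert abs(pi.mean() - theta) < 3 * se
            td = tab[f"td_{pop}"].dropna()
            assert abs(td.mean()) < 3 * td.std() / np.sqrt(len(td))
        fst = tab["fst"].dropna()
        assert abs(fst.mean()) < 3 * fst.std() / np.sqrt(len(fst))

    def test_zero_mutation_rate_rejected(self):
        model = DemographicModel(
            populations={"dog": ((0.0, 100.0),), "wolf": ((0.0, 100.0),),
                         "anc": ((0.0, 100.0),)},
            splits=((1.0, ("dog", "wolf"), "anc"),),
            samples={"dog": 5, "wolf": 6},
            mutation_rate=0.0, recombination_rate=1e-8)
        with pytest.raises(ValueError, match="utation"):
            simulate_null(model, 5, 10_000, seed=1)

    def test_save_load_round_trip(self, tmp_path):
        dist = simulate_null(default_model(), 30, 50_000, seed=5)
        dist.save(tmp_path / "null.tsv")
        back = NullDistribution.load(tmp_path / "null.tsv")
        for stat in dist.values:
            assert np.allclose(back.values[stat], dist.values[stat])
        assert back.mode == "fixed" and back.n_sims == 30


class TestPosterior:
    def test_draw_count_arithmetic(self):
        draws = pd.DataFrame({"size:dog:0": [4000.0, 6000.0]})
        dist = simulate_null_posterior(default_model(), draws,
                                       reps_per_draw=3, window_bp=20_000,
                                       seed=2)
        assert dist.n_sims == 6
        assert dist.mode == "posterior"

    def test_empty_draw_table_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_null_posterior(default_model(), pd.DataFrame(),
                                    reps_per_draw=2, window_bp=10_000,
                                    seed=1)

    def test_invalid_draw_names_row(self):
        draws = pd.DataFrame({"size:dog:0": [5000.0, -1.0]})
        with pytest.raises(ValueError, match="row 1"):
            simulate_null_posterior(default_model(), draws,
                                    reps_per_draw=1, window_bp=10_000,
                                    seed=1)

    def test_degenerate_posterior_matches_fixed_in_distribution(self):
        # one draw equal to the fixed parameters: the posterior-mode null
        # must be statistically indistinguishable from the fixed-mode null
        model = default_model()
        draws = pd.DataFrame(
            {"size:dog:0": [model.populations["dog"][0][1]]})
        R = 1200
        fixed = simulate_null(model, R, 20_000, seed=31)
        post = simulate_null_posterior(model, draws, reps_per_draw=R,
                                       window_bp=20_000, seed=77)
        for stat in ("fst", "delta_pi", "delta_td"):
            ks = ks_2samp(fixed.values[stat], post.values[stat])
            assert ks.pvalue > 0.01, stat

    def test_fdr_estimates_agree_between_modes(self):
        # posterior concentrated near the fixed values -> per-statistic
        # q-value vectors on the same observed table correlate > 0.99
        from sweepscan.scan import bh_qvalues, empirical_pvalue
        from sweepscan.synthetic import with_local_sweep

        model = default_model()
        # observed table spanning the signal range: neutral windows plus
        # sweep-emulated windows (as a real scanned genome would)
        obs = pd.concat([
            simulate_window_table(model, 200, 20_000, seed=55),
            simulate_window_table(with_local_sweep(model, "dog", 100.0),
                                  80, 20_000, seed=56),
        ], ignore_index=True)
        fixed = simulate_null(model, 4000, 20_000, seed=66)
        size0 = model.populations["dog"][0][1]
        draws = pd.DataFrame(
            {"size:dog:0": size0 * np.array([0.98, 0.99, 1.0, 1.01,
                                             1.02])})
        post = simulate_null_posterior(model, draws, reps_per_draw=800,
                                       window_bp=20_000, seed=88)
        for stat in ("fst", "delta_pi", "delta_td"):
            v = obs[stat].to_numpy()
            qa = bh_qvalues(empirical_pvalue(v, fixed.values[stat]))
            qb = bh_qvalues(empirical_pvalue(v, post.values[stat]))
            ok = ~np.isnan(qa) & ~np.isnan(qb)
            r = np.corrcoef(qa[ok], qb[ok])[0, 1]
            assert r > 0.99, (stat, r)


def test_bottleneck_severity_shifts_delta_pi_right():
    """A more severe recent bottleneck in the sweep population reduces its
    diversity, shifting the simulated delta_pi distribution rightward."""
    base = default_model()
    pops = dict(base.populations)
    pops["dog"] = ((0.0, 5000.0), (2500.0, 200.0), (3000.0, 15000.0))
    severe = DemographicModel(
        populations=pops, splits=base.splits, samples=base.samples,
        mutation_rate=1e-8, recombination_rate=1e-8)
    a = simulate_window_table(base, 800, 20_000, seed=41)
    b = simulate_window_table(severe, 800, 20_000, seed=42)
    da, db = a["delta_pi"].dropna(), b["delta_pi"].dropna()
    se = np.hypot(da.std() / np.sqrt(len(da)), db.std() / np.sqrt(len(db)))
    assert db.mean() - da.mean() > 3 * se


class TestModelPlumbing:
    def test_yaml_round_trip(self, tmp_path):
        model = default_model(with_outgroup=True)
        model_to_yaml(model, tmp_path / "m.yaml")
        assert model_from_yaml(tmp_path / "m.yaml") == model

    def test_apply_draw_paths(self):
        model = default_model()
        got = apply_draw(model, {"size:dog:1": 1234.0,
                                 "split:anc_dw": 9000.0,
                                 "mutation_rate": 2e-8})
        assert got.populations["dog"][1][1] == 1234.0
        assert got.splits[0][0] == 9000.0
        assert got.mutation_rate == 2e-8

    def test_unknown_parameter_rejected(self):
        with pytest.raises(KeyError):
            apply_draw(default_model(), {"nonsense": 1.0})

    def test_epoch_ordering_enforced(self):
        with pytest.raises(ValueError, match="backward"):
            DemographicModel(
                populations={"dog": ((0.0, 100.0), (50.0, 10.0),
                                     (20.0, 5.0)),
                             "wolf": ((0.0, 100.0),),
                             "anc": ((0.0, 100.0),)},
                splits=((100.0, ("dog", "wolf"), "anc"),),
                samples={"dog": 2, "wolf": 2},
                mutation_rate=1e-8, recombination_rate=1e-8)
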