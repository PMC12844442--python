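import numpy as np
import pandas as pd
import pytest
from scipy import integrate, stats

from microscale import (
    OtuTable,
    SimConfig,
    compute_nst,
    fit_ncm,
    make_metacommunity,
    ncm_predict,
    niche_breadth,
    simulate_neutral,
    simulate_niche,
)
from microscale.assembly import ncm_predict_exact, _null_counts
from tests.conftest import flat_frame


class TestNcmPredict:
    def test_large_nm_limits(self):
        assert ncm_predict(0.01, 1e7, 0.0005) == pytest.approx(1.0, abs=1e-6)
        assert ncm_predict(0.0001, 1e7, 0.0005) == pytest.approx(0.0, abs=1e-6)

    def test_matches_numerical_beta_integration(self):
        # p = 0.01, Nm = 1000, d = 0.0005: oracle integrates the Beta density
        a, b, d = 1000 * 0.01, 1000 * 0.99, 0.0005
        tail, _ = integrate.quad(lambda q: stats.beta.pdf(q, a, b), d, 1.0)
        assert ncm_predict(0.01, 1000, d) == pytest.approx(tail, abs=1e-8)

    def test_monotone_in_p_and_nm(self):
        p_grid = np.linspace(0.001, 0.2, 50)
        f = ncm_predict(p_grid, 500, 0.001)
        assert (np.diff(f) >= -1e-12).all()  # saturates at 1 in float
        assert f[-1] > f[0]
        nm_grid = np.linspace(50, 5000, 40)
        f2 = np.array([float(ncm_predict(0.01, nm, 0.001)) for nm in nm_grid])
        assert (np.diff(f2) >= -1e-12).all()  # may saturate at 1 in float
        assert f2[-1] > f2[0]

    def test_exact_detection_matches_beta_binomial_zero_mass(self):
        a, b, N = 2.0, 198.0, 500
        # oracle: integrate (1-q)^N against the Beta density
        zero_mass, _ = integrate.quad(lambda q: stats.beta.pdf(q, a, b) * (1 - q) ** N, 0, 1)
        assert ncm_predict_exact(0.01, 200, N) == pytest.approx(1 - zero_mass, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            ncm_predict(0.5, -1, 0.001)
        with pytest.raises(ValueError):
            ncm_predict(1.5, 100, 0.001)
        with pytest.raises(ValueError):
            ncm_predict(0.5, 100, 1.5)


class TestFitNcm:
    def test_migration_rate_recovery(self):
        meta = make_metacommunity(500, 2.0, seed=7)
        cfg = SimConfig(m=0.1, N_reads=2000, S_meta=500)
        t = simulate_neutral(meta, cfg, flat_frame(100), seed=123)
        fit = fit_ncm(t)
        assert fit.m == pytest.approx(0.1, rel=0.2)
        assert fit.r2 >= 0.8
        assert {"above", "within", "below"} >= set(fit.taxa["partition"])

    def test_estimates_ordered_in_true_m(self):
        meta = make_metacommunity(400, 2.0, seed=2)
        fits = []
        for m in (0.05, 0.5):
            cfg = SimConfig(m=m, N_reads=1000, S_meta=400)
            t = simulate_neutral(meta, cfg, flat_frame(60), seed=55)
            fits.append(fit_ncm(t).m)
        assert fits[0] < fits[1]

    def test_non_uniform_depth_rejected(self):
        t = OtuTable([[5, 5], [3, 3]], ["a", "b"], ["t1", "t2"])
        with pytest.raises(ValueError, match="rarefy"):
            fit_ncm(t)

    def test_beta_tail_mode_runs(self):
        meta = make_metacommunity(200, 1.5, seed=3)
        cfg = SimConfig(m=0.2, N_reads=1000, S_meta=200)
        t = simulate_neutral(meta, cfg, flat_frame(40), seed=9)
        fit = fit_ncm(t, detection="beta-tail")
        assert fit.Nm > 0 and fit.r2 <= 1


class TestComputeNst:
    def test_values_clipped_to_unit_interval(self, rng):
        for seed in range(5):
            counts = rng.integers(0, 20, size=(8, 30))
            counts[:, 0] += 1
            t = OtuTable(counts, [f"G_s{i}" for i in range(8)], [f"t{j}" for j in range(30)])
            frame = flat_frame(8)
            t = OtuTable(counts, frame.sample_ids, t.taxon_ids)
            res = compute_nst(t, frame, n_null=25, seed=seed)["G"]
            assert 0.0 <= res.nst <= 1.0
            assert res.se >= 0

    def test_null_model_data_scores_highly_stochastic(self):
        """Self-consistency: communities drawn from the null model itself."""
        rng = np.random.default_rng(4)
        frame = flat_frame(10)
        occ = rng.uniform(0.2, 0.9, size=40)
        rel = rng.dirichlet(np.ones(40))
        richness = np.full(10, 25)
        totals = np.full(10, 1500)
        vals = []
        for rep in range(5):
            counts = _null_counts(np.random.default_rng(100 + rep), richness, totals, occ, rel)
            t = OtuTable(counts, frame.sample_ids, [f"t{j}" for j in range(40)])
            vals.append(compute_nst(t, frame, n_null=100, seed=rep)["G"].nst)
        assert np.mean(vals) > 0.5

    def test_direction_separates_neutral_from_niche(self):
        cfg = SimConfig(levels=4, n_plots=2, samples_per_level=2, N_reads=2000, m=0.3, S_meta=150, lognormal_sigma=1.2)
        from microscale import generate_nested_design

        frame = generate_nested_design(cfg, group="G1")
        meta = make_metacommunity(150, 1.2, 100)
        neutral = simulate_neutral(meta, cfg, frame, seed=200)
        nst_neutral = compute_nst(neutral, frame, n_null=100, seed=300)["G1"].nst
        ncfg = SimConfig(levels=4, n_plots=2, samples_per_level=2, N_reads=2000, m=0.3, S_meta=150, lognormal_sigma=1.2, niche_strength=10.0)
        niche, _ = simulate_niche(meta, ncfg, frame, seed=400)
        nst_niche = compute_nst(niche, frame, n_null=100, seed=500)["G1"].nst
        assert nst_neutral > 0.5 > nst_niche

    def test_small_groups_skipped(self):
        frame = flat_frame(3)
        t = OtuTable(np.ones((3, 5), dtype=int), frame.sample_ids, [f"t{j}" for j in range(5)])
        with pytest.raises(ValueError, match="at least 4"):
            compute_nst(t, frame, n_null=10, seed=0)


class TestNicheBreadth:
    def test_uniform_occupancy_gives_sample_count(self):
        t = OtuTable(np.full((5, 1), 4), [f"s{i}" for i in range(5)], ["t"])
        assert niche_breadth(t).breadth["t"] == pytest.approx(5.0)

    def test_single_sample_taxon_gives_one(self):
        counts = np.zeros((4, 1), dtype=int)
        counts[2, 0] = 9
        t = OtuTable(counts, [f"s{i}" for i in range(4)], ["t"])
        assert niche_breadth(t).breadth["t"] == pytest.approx(1.0)

    def test_half_half_distribution_gives_two(self):
        counts = np.array([[5], [5], [0], [0]])
        t = OtuTable(counts, [f"s{i}" for i in range(4)], ["t"])
        assert niche_breadth(t).breadth["t"] == pytest.approx(2.0)

    def test_matches_brute_force_oracle(self, rng):
        counts = rng.integers(0, 10, size=(6, 15))
        t = OtuTable(counts, [f"s{i}" for i in range(6)], [f"t{j}" for j in range(15)])
        res = niche_breadth(t)
        for j, tax in enumerate(t.taxon_ids):
            tot = counts[:, j].sum()
            if tot == 0:
                assert tax not in res.breadth.index
                continue
            P = counts[:, j] / tot
            assert res.breadth[tax] == pytest.approx(1.0 / (P**2).sum(), abs=1e-12)

    def test_bounds(self, rng):
        counts = rng.integers(0, 10, size=(7, 20)) + 0
        counts[:, 0] += 1
        t = OtuTable(counts, [f"s{i}" for i in range(7)], [f"t{j}" for j in range(20)])
        res = niche_breadth(t)
        assert ((res.breadth >= 1.0 - 1e-9) & (res.breadth <= 7.0 + 1e-9)).all()
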