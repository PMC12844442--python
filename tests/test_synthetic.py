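import numpy as np
import pytest
from scipy import stats
from scipy.spatial.distance import pdist

from microscale import (
    GuildSpec,
    SimConfig,
    generate_nested_design,
    make_metacommunity,
    simulate_guilds,
    simulate_neutral,
    simulate_niche,
)
from microscale.assembly import ncm_predict_exact
from microscale.synthetic import assign_guild_members
from tests.conftest import flat_frame


class TestMetacommunity:
    def test_frequencies_sum_to_one(self):
        for seed in (0, 1, 2):
            meta = make_metacommunity(50, 2.0, seed)
            assert meta.p.sum() == pytest.approx(1.0)
            assert (meta.p >= 0).all()

    def test_sigma_zero_is_uniform(self):
        meta = make_metacommunity(10, 0.0, 0)
        assert np.allclose(meta.p, 0.1)

    def test_rank_abundance_non_increasing_after_sorting(self):
        meta = make_metacommunity(100, 1.5, 7)
        ranked = np.sort(meta.p)[::-1]
        assert (np.diff(ranked) <= 0).all()

    def test_too_few_taxa(self):
        with pytest.raises(ValueError):
            make_metacommunity(1, 1.0, 0)


class TestNestedDesign:
    def test_areas_double_per_level(self):
        cfg = SimConfig(levels=3, side0=0.5)
        frame = generate_nested_design(cfg)
        assert sorted(frame.data["area"].unique()) == pytest.approx([0.25, 1.0, 4.0])

    def test_thirteen_levels_reach_2048m_side(self):
        cfg = SimConfig(levels=13, side0=0.5, n_plots=1)
        frame = generate_nested_design(cfg)
        top = frame.data.loc[frame.data["level"] == 12, "area"].iloc[0]
        assert np.sqrt(top) == pytest.approx(2048.0)
        assert frame.data["area"].min() == pytest.approx(0.25)

    def test_samples_nest_inside_largest_quadrat(self):
        cfg = SimConfig(levels=5, side0=0.5, n_plots=2)
        frame = generate_nested_design(cfg)
        side_max = cfg.side0 * 2 ** (cfg.levels - 1)
        assert (frame.data["x"] <= side_max).all()
        assert (frame.data["y"] <= side_max).all()
        # level-k samples lie within the level-(k+1) extent
        side_next = cfg.side0 * 2.0 ** (frame.data["level"] + 1)
        assert (frame.data["x"] <= side_next).all()


class TestSimulateNeutral:
    def test_deterministic_and_conserves_depth(self):
        meta = make_metacommunity(80, 1.0, 1)
        cfg = SimConfig(levels=3, n_plots=1, N_reads=500, m=0.2)
        a = simulate_neutral(meta, cfg, seed=9)
        b = simulate_neutral(meta, cfg, seed=9)
        assert (a.counts == b.counts).all()
        assert (a.sample_totals() == 500).all()

    def test_zero_migration_rejected(self):
        meta = make_metacommunity(10, 1.0, 1)
        with pytest.raises(ValueError, match="m = 0"):
            simulate_neutral(meta, SimConfig(m=0.0), seed=0)

    def test_high_migration_concentrates_near_metacommunity(self):
        meta = make_metacommunity(50, 1.0, 2)
        cfg = SimConfig(levels=3, n_plots=2, samples_per_level=4, N_reads=20000, m=1.0)
        t = simulate_neutral(meta, cfg, seed=5)
        obs = t.relative_abundance().mean(axis=0)
        assert np.corrcoef(obs, meta.p)[0, 1] > 0.999

    def test_occupancy_matches_beta_binomial_prediction(self):
        """Chi-square calibration of detection frequencies at n = 150 samples."""
        meta = make_metacommunity(200, 1.5, 3)
        cfg = SimConfig(N_reads=1000, m=0.2)
        frame = flat_frame(150)
        t = simulate_neutral(meta, cfg, frame, seed=11)
        n = t.n_samples
        F_exp = ncm_predict_exact(np.clip(meta.p, 1e-12, 1 - 1e-12), cfg.N_reads * cfg.m, cfg.N_reads)
        occ = (t.counts > 0).sum(axis=0)
        informative = (F_exp > 0.05) & (F_exp < 0.95)
        z2 = (occ[informative] - n * F_exp[informative]) ** 2 / (
            n * F_exp[informative] * (1 - F_exp[informative])
        )
        pval = stats.chi2.sf(z2.sum(), df=int(informative.sum()))
        assert pval > 0.01


class TestSimulateNiche:
    def test_requires_positive_strength(self):
        meta = make_metacommunity(10, 1.0, 0)
        with pytest.raises(ValueError):
            simulate_niche(meta, SimConfig(niche_strength=0.0), seed=0)

    def test_depth_conserved_and_env_matches_samples(self):
        meta = make_metacommunity(60, 1.0, 4)
        cfg = SimConfig(levels=4, n_plots=2, niche_strength=3.0, N_reads=800)
        t, env = simulate_niche(meta, cfg, seed=6)
        assert (t.sample_totals() == 800).all()
        assert list(env.index) == t.sample_ids
        assert {"env", "noise1", "noise2"} <= set(env.columns)

    def test_strong_filtering_produces_distance_decay(self):
        """Bray-Curtis rises with environmental separation under strong
        filtering; oracle = expected-share formula evaluated at the two
        environments."""
        meta = make_metacommunity(120, 1.0, 5)
        cfg = SimConfig(levels=7, n_plots=2, samples_per_level=2, niche_strength=10.0, N_reads=5000)
        t, env = simulate_niche(meta, cfg, seed=8)
        e = env["env"].to_numpy()
        d_comm = pdist(t.relative_abundance(), metric="braycurtis")
        d_env = pdist(e[:, None], metric="euclidean")
        near = d_comm[d_env < np.quantile(d_env, 0.2)]
        far = d_comm[d_env > np.quantile(d_env, 0.8)]
        assert far.mean() > near.mean() + 0.1


class TestSimulateGuilds:
    def _setup(self, collapse, loading=1.5, seed=3):
        cfg = SimConfig(
            levels=10, side0=0.5, n_plots=2, samples_per_level=2,
            N_reads=4000, m=0.9, S_meta=100, lognormal_sigma=0.8,
        )
        guilds = [GuildSpec(size=5, loading=loading, collapse_level=collapse, field_scale=cfg.max_side / 8)]
        meta = make_metacommunity(100, 0.8, seed)
        frame = generate_nested_design(cfg, group="G")
        base = simulate_neutral(meta, cfg, frame, seed=seed)
        out = simulate_guilds(base, guilds, frame, seed=seed, max_side=cfg.max_side)
        return base, out, guilds, frame

    def test_zero_loading_is_identity(self):
        base, out, *_ = self._setup(collapse=99, loading=0.0)
        assert (base.counts == out.counts).all()

    def test_within_guild_correlation_exceeds_threshold(self):
        base, out, guilds, _ = self._setup(collapse=99, loading=1.5, seed=3)
        mem = assign_guild_members(base, guilds)[0]
        r, _ = stats.spearmanr(out.select_taxa(mem).counts)
        assert (r[np.triu_indices(5, 1)] > 0.8).all()

    def test_collapsed_guild_has_no_edges(self):
        base, out, guilds, _ = self._setup(collapse=0, loading=1.5, seed=3)
        mem = assign_guild_members(base, guilds)[0]
        r, _ = stats.spearmanr(out.select_taxa(mem).counts)
        assert np.abs(r[np.triu_indices(5, 1)]).max() < 0.8

    def test_totals_conserved_and_deterministic(self):
        base, out, guilds, frame = self._setup(collapse=99)
        assert (out.sample_totals() == base.sample_totals()).all()
        again = simulate_guilds(base, guilds, frame, seed=3, max_side=0.5 * 2**9)
        assert (again.counts == out.counts).all()

    def test_overlapping_guilds_impossible_by_construction(self):
        base, _, _, frame = self._setup(collapse=99)
        too_big = [GuildSpec(size=60, loading=1.0, collapse_level=5), GuildSpec(size=60, loading=1.0, collapse_level=5)]
        with pytest.raises(ValueError, match="more taxa"):
            simulate_guilds(base, too_big, frame, seed=0)
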