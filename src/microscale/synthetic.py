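"""Synthetic nested-design communities with known ground truth.

The generator emulates the data layout of a nested quadrat survey: replicate
plots per grassland-like group, quadrats whose side doubles per nested level
(side0 * 2**k, e.g. 0.5 m up to 2048 m over 13 levels), and per-sample
amplicon count vectors at a fixed read depth.

Communities are assembled under one of two regimes, each with a tunable
parameter that downstream estimators must recover:

* **neutral** -- each sample's relative abundances are drawn from the
  stationary distribution of Sloan's neutral model, Beta(N*m*p_i,
  N*m*(1-p_i)) around metacommunity frequencies p, then counts are drawn
  multinomially at the read depth.  Ground truth: migration rate ``m``.
* **niche** -- a smooth environmental field E(x, y) (linear gradient plus
  Gaussian bumps) filters each taxon through a Gaussian response around a
  taxon-specific optimum; ``niche_strength`` scales the filtering.

On top of either base table, correlated **guilds** can be imposed: the member
taxa of a guild share a smooth spatial latent factor, so their abundances
co-vary once the sampled extent is large enough for the factor to vary --
co-occurrence emerges with spatial scale.  For samples at nested levels at or
above a guild's ``collapse_level`` the factor is re-drawn independently per
taxon, destroying the correlation at large scales and creating a designed
tipping point in the node-area relationship.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .io_model import (
    OtuTable,
    SampleFrame,
    write_env_table,
    write_otu_table,
    write_sample_frame,
)

__all__ = [
    "Metacommunity",
    "GuildSpec",
    "SimConfig",
    "make_metacommunity",
    "generate_nested_design",
    "simulate_neutral",
    "simulate_niche",
    "simulate_guilds",
    "assign_guild_members",
    "nar_guild_fixture",
    "simulate_dataset",
    "write_fixture",
]

logger = logging.getLogger("microscale")


@dataclass
class Metacommunity:
    """Regional species pool: relative abundances p summing to one."""

    p: np.ndarray

    def __post_init__(self) -> None:
        self.p = np.asarray(self.p, dtype=float)
        if (self.p < 0).any():
            raise ValueError("metacommunity frequencies must be non-negative")
        s = self.p.sum()
        if not math.isclose(s, 1.0, rel_tol=1e-9):
            raise ValueError("metacommunity frequencies must sum to 1")

    @property
    def S_meta(self) -> int:
        return self.p.size


@dataclass
class GuildSpec:
    """One correlated guild: member count, latent-factor loading, and the
    nested level at which the shared factor collapses into per-taxon noise.

    ``field_scale`` is the wavelength (m) of the smooth spatial factor; None
    selects half the largest quadrat side, so the factor is nearly constant
    within small extents and fully varies across the design.
    """

    size: int
    loading: float
    collapse_level: int
    field_scale: float | None = None


@dataclass
class SimConfig:
    """Study-design and assembly parameters for one simulated group.

    Defaults mirror a desk-scale rendition of the survey geometry: quadrat
    sides doubling from 0.5 m, three replicate plots, and a per-sample read
    depth of 2000.
    """

    levels: int = 9
    side0: float = 0.5
    n_plots: int = 3
    samples_per_level: int = 2
    N_reads: int = 2000
    m: float = 0.3
    niche_strength: float = 0.0
    env_range: float = 1.0
    guild_spec: list[GuildSpec] = field(default_factory=list)
    S_meta: int = 300
    lognormal_sigma: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.levels < 3:
            raise ValueError("need at least 3 nested levels")
        if not (0 <= self.m <= 1):
            raise ValueError("migration rate m must lie in [0, 1]")
        if self.N_reads < 1:
            raise ValueError("N_reads must be >= 1")
        if self.side0 <= 0:
            raise ValueError("side0 must be positive")
        if self.samples_per_level < 1 or self.samples_per_level > 4:
            raise ValueError("samples_per_level must be 1..4 (quadrat corners)")

    @property
    def max_side(self) -> float:
        return self.side0 * 2.0 ** (self.levels - 1)


def make_metacommunity(S: int, lognormal_sigma: float, seed: int) -> Metacommunity:
    """Lognormal species-abundance distribution, normalised to sum one."""
    if S < 2:
        raise ValueError("need at least 2 taxa")
    if lognormal_sigma < 0:
        raise ValueError("lognormal_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.lognormal(mean=0.0, sigma=lognormal_sigma, size=S)
    return Metacommunity(raw / raw.sum())


# the four corners of a unit quadrat, in the order samples are placed
_CORNERS = [(1.0, 1.0), (1.0, 0.0), (0.0, 1.0), (0.0, 0.0)]


def generate_nested_design(cfg: SimConfig, group: str = "G1") -> SampleFrame:
    """Emit sample locations at quadrat corners for each plot and level.

    All quadrats of a plot share the origin, so the level-k quadrat nests
    inside the level-(k+1) quadrat; samples sit on the corners of their own
    quadrat (corner (side, side) first, so successive levels sample distinct
    locations).
    """
    rows = []
    for p in range(cfg.n_plots):
        plot_id = f"{group}_P{p + 1}"
        for k in range(cfg.levels):
            side = cfg.side0 * 2.0**k
            for i in range(cfg.samples_per_level):
                cx, cy = _CORNERS[i]
                rows.append(
                    {
                        "sample_id": f"{group}_P{p + 1}_L{k}_S{i + 1}",
                        "group": group,
                        "plot_id": plot_id,
                        "x": cx * side,
                        "y": cy * side,
                        "level": k,
                        "area": side * side,
                    }
                )
    return SampleFrame(pd.DataFrame(rows))


def _plot_offsets(frame: SampleFrame, spacing: float) -> dict[str, tuple[float, float]]:
    """Global offset per plot so plots occupy disjoint stretches of the
    simulated landscape (plots laid out along the x axis)."""
    plots = list(pd.unique(frame.data["plot_id"]))
    return {pl: (i * spacing, 0.0) for i, pl in enumerate(plots)}


def _global_coords(frame: SampleFrame, spacing: float) -> np.ndarray:
    off = _plot_offsets(frame, spacing)
    xy = frame.data[["x", "y"]].to_numpy(dtype=float).copy()
    for i, pl in enumerate(frame.data["plot_id"]):
        ox, oy = off[pl]
        xy[i, 0] += ox
        xy[i, 1] += oy
    return xy


def simulate_neutral(
    meta: Metacommunity, cfg: SimConfig, frame: SampleFrame | None = None, seed: int | None = None
) -> OtuTable:
    """Sample communities from the stationary Sloan neutral distribution.

    Per sample and taxon the local relative abundance is Beta(N*m*p_i,
    N*m*(1-p_i)) with N = ``cfg.N_reads``; rows are renormalised and counts
    drawn multinomially at depth N.  Pure function of (inputs, seed).
    """
    if cfg.m <= 0:
        raise ValueError("m = 0 is degenerate for the stationary Beta; use m >= 1e-4")
    if frame is None:
        frame = generate_nested_design(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    n = len(frame.sample_ids)
    Nm = cfg.N_reads * cfg.m
    a = np.clip(Nm * meta.p, 1e-12, None)
    b = np.clip(Nm * (1.0 - meta.p), 1e-12, None)
    q = rng.beta(a[None, :], b[None, :], size=(n, meta.S_meta))
    row_sums = q.sum(axis=1, keepdims=True)
    # a row of all-zero draws is vanishingly unlikely for S >= 2; guard anyway
    row_sums[row_sums == 0] = 1.0
    q /= row_sums
    counts = np.empty((n, meta.S_meta), dtype=np.int64)
    for j in range(n):
        counts[j] = rng.multinomial(cfg.N_reads, q[j])
    taxa = [f"OTU{i + 1}" for i in range(meta.S_meta)]
    return OtuTable(counts, frame.sample_ids, taxa)


def _environment_field(xy: np.ndarray, cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Linear gradient plus smooth Gaussian bumps, standardised to unit
    variance and scaled by ``env_range``."""
    lo = xy.min(axis=0)
    hi = xy.max(axis=0)
    span = np.maximum(hi - lo, 1e-9)
    u = ((xy - lo) / span).sum(axis=1) / 2.0  # gradient along x+y, in [0, 1]
    e = u - 0.5
    n_bumps = 4
    centers = rng.uniform(0.0, 1.0, size=(n_bumps, 2))
    amps = rng.normal(0.0, 0.35, size=n_bumps)
    width = 0.25
    unit = (xy - lo) / span
    for c, a in zip(centers, amps):
        d2 = ((unit - c) ** 2).sum(axis=1)
        e = e + a * np.exp(-d2 / (2.0 * width**2))
    sd = e.std()
    if sd > 0:
        e = (e - e.mean()) / sd
    return cfg.env_range * e


def simulate_niche(
    meta: Metacommunity, cfg: SimConfig, frame: SampleFrame | None = None, seed: int | None = None
) -> tuple[OtuTable, pd.DataFrame]:
    """Environmentally filtered communities plus the matching soil table.

    Each taxon carries an optimum E_i on the standardised field; its expected
    share in a sample at environment E is p_i * exp(-niche_strength *
    (E - E_i)**2), renormalised, then counts are multinomial at depth N.
    The returned environment table holds the filtering axis (``env``) and two
    pure-noise variables mimicking uninformative soil measurements.
    """
    if cfg.niche_strength <= 0:
        raise ValueError("niche_strength must be > 0 for simulate_niche")
    if frame is None:
        frame = generate_nested_design(cfg)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    xy = _global_coords(frame, spacing=2.0 * cfg.max_side)
    env = _environment_field(xy, cfg, rng)
    optima = rng.uniform(env.min(), env.max(), size=meta.S_meta)
    w = meta.p[None, :] * np.exp(-cfg.niche_strength * (env[:, None] - optima[None, :]) ** 2)
    w_sums = w.sum(axis=1, keepdims=True)
    w_sums[w_sums == 0] = 1.0
    w /= w_sums
    n = len(frame.sample_ids)
    counts = np.empty((n, meta.S_meta), dtype=np.int64)
    for j in range(n):
        counts[j] = rng.multinomial(cfg.N_reads, w[j])
    taxa = [f"OTU{i + 1}" for i in range(meta.S_meta)]
    table = OtuTable(counts, frame.sample_ids, taxa)
    env_df = pd.DataFrame(
        {
            "env": env,
            "noise1": rng.normal(0.0, 1.0, size=n),
            "noise2": rng.normal(0.0, 1.0, size=n),
        },
        index=frame.sample_ids,
    )
    env_df.index.name = "sample_id"
    return table, env_df


def assign_guild_members(base: OtuTable, guild_spec: list[GuildSpec]) -> list[list[str]]:
    """Deterministic guild membership: guilds take consecutive blocks of the
    most abundant taxa (abundant members keep count noise low relative to the
    shared factor).  Guilds never overlap."""
    need = sum(g.size for g in guild_spec)
    if need > base.n_taxa:
        raise ValueError("guilds require more taxa than the table contains")
    order = np.argsort(-base.counts.sum(axis=0), kind="stable")
    members: list[list[str]] = []
    cursor = 0
    for g in guild_spec:
        if g.size < 2:
            raise ValueError("a guild needs at least 2 members")
        block = order[cursor : cursor + g.size]
        members.append([base.taxon_ids[j] for j in block])
        cursor += g.size
    return members


def simulate_guilds(
    base: OtuTable,
    guild_spec: list[GuildSpec],
    frame: SampleFrame,
    seed: int,
    max_side: float | None = None,
) -> OtuTable:
    """Impose correlated guilds on a base table.

    For each guild, a smooth spatial latent factor f(x, y) = exp(loading *
    sin(2*pi*u.(x, y)/lambda + phase)) multiplies the member taxa's expected
    shares; samples within a small extent see nearly the same factor (no
    induced correlation), samples spread over ~lambda or more see it vary
    (strong positive rank correlation among members).  The factor is a
    function of the within-plot coordinates, so it repeats identically
    across replicate plots (a microhabitat response tied to position in the
    quadrat layout): the induced correlation depends only on the sampled
    extent, not on which plots enter the sample set.  For samples at nested
    levels >= ``collapse_level`` the factor is re-drawn independently per
    member taxon, which destroys the correlation at large scales.  Counts
    are re-drawn multinomially at each sample's original depth, so sample
    totals are conserved.
    """
    if not guild_spec:
        return base
    members = assign_guild_members(base, guild_spec)
    rng = np.random.default_rng(seed)
    if max_side is None:
        max_side = frame.side0 * 2.0 ** int(frame.data["level"].max())
    xy = frame.data[["x", "y"]].to_numpy(dtype=float)
    levels = frame.data["level"].to_numpy()
    totals = base.sample_totals()
    w = base.counts.astype(float)
    tpos = {t: j for j, t in enumerate(base.taxon_ids)}
    n = base.n_samples
    for g, mem in zip(guild_spec, members):
        lam = g.field_scale if g.field_scale is not None else max_side / 2.0
        theta = rng.uniform(0.0, 2.0 * np.pi)
        u = np.array([np.cos(theta), np.sin(theta)])
        phase = rng.uniform(0.0, 2.0 * np.pi)
        gfield = np.sin(2.0 * np.pi * (xy @ u) / lam + phase)
        collapsed = levels >= g.collapse_level
        cols = [tpos[t] for t in mem]
        if g.loading == 0:
            continue
        for j in cols:
            gj = gfield.copy()
            # sine has variance 1/2; matched-variance independent noise
            gj[collapsed] = rng.normal(0.0, np.sqrt(0.5), size=int(collapsed.sum()))
            w[:, j] *= np.exp(g.loading * gj)
    if all(g.loading == 0 for g in guild_spec):
        return base
    w_sums = w.sum(axis=1, keepdims=True)
    w_sums[w_sums == 0] = 1.0
    w /= w_sums
    counts = np.empty_like(base.counts)
    for j in range(n):
        counts[j] = rng.multinomial(int(totals[j]), w[j])
    return OtuTable(counts, list(base.sample_ids), list(base.taxon_ids))


def nar_guild_fixture(
    collapse_level: int,
    seed: int,
    levels: int = 9,
    n_guilds: int = 10,
    guild_size: int = 6,
    loading: float = 2.0,
) -> tuple[OtuTable, SampleFrame]:
    """Canonical guild fixture for node-area analyses.

    Nine nested levels, three plots, two corner samples per level; a weakly
    noisy neutral base (m = 0.9, 4000 reads, 100 taxa) carrying ten guilds of
    six abundant taxa whose shared factor field has wavelength max_side / 8,
    so within-guild correlation emerges around mid levels and saturates near
    r ~ 0.9.  ``collapse_level`` near the top of the range produces a
    unimodal node-area curve; 0 produces guilds that never cohere, leaving
    only small-sample spurious edges that die off with scale.
    """
    cfg = SimConfig(
        levels=levels,
        side0=0.5,
        n_plots=3,
        samples_per_level=2,
        N_reads=4000,
        m=0.9,
        S_meta=100,
        lognormal_sigma=0.8,
        seed=seed,
    )
    guilds = [
        GuildSpec(size=guild_size, loading=loading, collapse_level=collapse_level, field_scale=cfg.max_side / 8.0)
        for _ in range(n_guilds)
    ]
    cfg.guild_spec = guilds
    meta = make_metacommunity(cfg.S_meta, cfg.lognormal_sigma, seed + 1)
    frame = generate_nested_design(cfg, group="G1")
    base = simulate_neutral(meta, cfg, frame, seed=seed + 2)
    table = simulate_guilds(base, guilds, frame, seed=seed + 3, max_side=cfg.max_side)
    return table, frame


def simulate_dataset(
    group_cfgs: dict[str, SimConfig],
    regimes: dict[str, str],
    seed: int,
) -> tuple[OtuTable, SampleFrame, pd.DataFrame, dict]:
    """Assemble a multi-group dataset (one regime and config per group).

    ``regimes[group]`` is ``"neutral"`` or ``"niche"``; guilds from each
    group's ``guild_spec`` are applied on top.  Returns the combined count
    table, sample frame, environment table and a ground-truth dictionary.
    """
    tables = []
    frames = []
    envs = []
    truth: dict = {"seed": seed, "groups": {}}
    ss = np.random.SeedSequence(seed)
    child = {g: s for g, s in zip(sorted(group_cfgs), ss.spawn(len(group_cfgs)))}
    for g in group_cfgs:
        cfg = group_cfgs[g]
        regime = regimes.get(g, "neutral")
        sub = np.random.default_rng(child[g])
        s_meta, s_comm, s_guild = (int(x) for x in sub.integers(0, 2**31 - 1, size=3))
        meta = make_metacommunity(cfg.S_meta, cfg.lognormal_sigma, s_meta)
        frame = generate_nested_design(cfg, group=g)
        if regime == "neutral":
            table = simulate_neutral(meta, cfg, frame, seed=s_comm)
            # the environment is still measured, the community just ignores it
            xy = _global_coords(frame, spacing=2.0 * cfg.max_side)
            env = pd.DataFrame(
                {
                    "env": _environment_field(xy, cfg, sub),
                    "noise1": sub.normal(size=len(frame.sample_ids)),
                    "noise2": sub.normal(size=len(frame.sample_ids)),
                },
                index=frame.sample_ids,
            )
            env.index.name = "sample_id"
        elif regime == "niche":
            table, env = simulate_niche(meta, cfg, frame, seed=s_comm)
        else:
            raise ValueError(f"unknown regime {regime!r} for group {g!r}")
        if cfg.guild_spec:
            table = simulate_guilds(table, cfg.guild_spec, frame, seed=s_guild, max_side=cfg.max_side)
        # prefix taxon ids per group?  No: groups share the taxon space only
        # within a group's own pool, so give each group its own taxon block.
        table = OtuTable(table.counts, table.sample_ids, [f"{g}_{t}" for t in table.taxon_ids])
        tables.append(table)
        frames.append(frame)
        envs.append(env)
        truth["groups"][g] = {
            "regime": regime,
            "m": cfg.m,
            "niche_strength": cfg.niche_strength,
            "guilds": [asdict(gs) for gs in cfg.guild_spec],
            "S_meta": cfg.S_meta,
            "N_reads": cfg.N_reads,
            "levels": cfg.levels,
        }
    all_samples = [s for f in frames for s in f.sample_ids]
    all_taxa = [t for tb in tables for t in tb.taxon_ids]
    counts = np.zeros((len(all_samples), len(all_taxa)), dtype=np.int64)
    r0 = 0
    c0 = 0
    for tb in tables:
        counts[r0 : r0 + tb.n_samples, c0 : c0 + tb.n_taxa] = tb.counts
        r0 += tb.n_samples
        c0 += tb.n_taxa
    table = OtuTable(counts, all_samples, all_taxa)
    frame = SampleFrame(pd.concat([f.data for f in frames], ignore_index=True))
    env = pd.concat(envs)
    env.index.name = "sample_id"
    return table, frame, env, truth


def write_fixture(
    out_dir,
    table: OtuTable,
    frame: SampleFrame,
    env: pd.DataFrame,
    truth: dict,
    seed: int | None = None,
) -> None:
    """Write a complete fixture directory: otu.tsv, samples.tsv, env.tsv and
    truth.json with the ground-truth parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_otu_table(table, out / "otu.tsv", seed=seed)
    write_sample_frame(frame, out / "samples.tsv", seed=seed)
    write_env_table(env, out / "env.tsv", seed=seed)
    with open(out / "truth.json", "w", encoding="utf-8") as fh:
        json.dump(truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
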