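"""Config-driven end-to-end runner.

Executes the full analysis on a fixture directory -- rarefaction and
filtering, diversity and environmental heterogeneity, taxa-area fits and
slope tests, node-area curves and breakpoints, neutral-model and
stochasticity-ratio and niche-breadth inference, and per-variable Mantel
tests -- writing every stage's tables as TSV plus a JSON manifest of the
configuration, derived seeds and warnings.  Outputs are byte-identical
across runs with the same config and seed.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import assembly, diversity, network, sar
from .io_model import (
    TOOL_VERSION,
    filter_taxa,
    rarefy,
    read_env_table,
    read_otu_table,
    read_sample_frame,
)

__all__ = ["PipelineConfig", "run_pipeline", "ALL_STAGES"]

logger = logging.getLogger("microscale")

ALL_STAGES = ("diversity", "tar", "nar", "assembly", "mantel")


@dataclass
class PipelineConfig:
    """All thresholds and seeds for one pipeline run.

    Defaults follow the analysis conventions of the field: taxa are filtered
    at 0.1% overall relative abundance and 20% prevalence before network
    construction; network edges require |Spearman r| > 0.80 at p < 0.05;
    taxa-area models use log10 area.
    """

    otu: str = "otu.tsv"
    samples: str = "samples.tsv"
    env: str | None = "env.tsv"
    orientation: str = "samples"
    rarefaction_depth: int | None = None  # None = skip rarefaction
    min_rel_abund: float = 0.001
    min_prevalence: float = 0.2
    r_thresh: float = 0.80
    p_thresh: float = 0.05
    correction: str = "none"
    min_samples: int = 8
    nar_mode: str = "cumulative"
    tar_models: tuple[str, ...] = ("logarithm", "power")
    log_base: float = 10.0
    n_perm: int = 999
    mantel_method: str = "pearson"
    nst_metric: str = "braycurtis"
    n_null: int = 1000
    env_metric: str = "euclidean"
    seed: int = 0
    stages: tuple[str, ...] = ALL_STAGES

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        for key in ("tar_models", "stages"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def validate(self) -> None:
        if not (0 <= self.min_rel_abund <= 1 and 0 <= self.min_prevalence <= 1):
            raise ValueError("filter thresholds must lie in [0, 1]")
        if not (0 < self.r_thresh <= 1):
            raise ValueError("r_thresh must lie in (0, 1]")
        if not (0 < self.p_thresh <= 1):
            raise ValueError("p_thresh must lie in (0, 1]")
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")


def _stage_seed(seed: int, stage: str) -> int:
    """Derived, logged sub-seed per random stage (stable, below 2**31)."""
    return int(np.random.SeedSequence([seed, ALL_STAGES.index(stage)]).generate_state(1)[0] % (2**31))


class _WarningCollector(logging.Handler):
    def __init__(self) -> None:
        super().__init__(level=logging.WARNING)
        self.messages: list[str] = []

    def emit(self, record: logging.LogRecord) -> None:
        self.messages.append(record.getMessage())


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False, index_label=None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# microscale v{TOOL_VERSION}\n")
        df.to_csv(fh, sep="\t", index=index, index_label=index_label, lineterminator="\n", float_format="%.10g")


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Run the requested stages and write all outputs under *out_dir*.

    Returns the manifest dictionary (also written as run_manifest.json).  On
    a stage failure, files already written by that stage are renamed with a
    ``.partial`` suffix and the error is re-raised with a stage tag.
    """
    cfg.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    collector = _WarningCollector()
    logger.addHandler(collector)
    manifest: dict = {
        "tool_version": TOOL_VERSION,
        "config": {k: (list(v) if isinstance(v, tuple) else v) for k, v in asdict(cfg).items()},
        "stage_seeds": {},
        "warnings": collector.messages,
        "outputs": [],
    }
    t_start = time.perf_counter()
    try:
        table = read_otu_table(cfg.otu, orientation=cfg.orientation)
        frame = read_sample_frame(cfg.samples)
        frame_ids = set(frame.sample_ids)
        table = table.select_samples([s for s in table.sample_ids if s in frame_ids])
        if table.n_samples < len(frame.sample_ids):
            missing = sorted(frame_ids - set(table.sample_ids))
            raise ValueError(f"samples missing from count table: {missing}")
        env = read_env_table(cfg.env) if cfg.env else None

        if cfg.rarefaction_depth is not None:
            s = _stage_seed(cfg.seed, "diversity")
            manifest["stage_seeds"]["rarefy"] = s
            table = rarefy(table, cfg.rarefaction_depth, seed=s)
            kept = set(table.sample_ids)
            frame = frame.subset(frame.data["sample_id"].isin(kept).to_numpy())

        for stage in ALL_STAGES:
            if stage not in cfg.stages:
                continue
            t0 = time.perf_counter()
            written: list[Path] = []
            try:
                if stage == "diversity":
                    _stage_diversity(cfg, table, frame, env, out, written)
                elif stage == "tar":
                    _stage_tar(cfg, table, frame, out, written)
                elif stage == "nar":
                    _stage_nar(cfg, table, frame, out, written)
                elif stage == "assembly":
                    _stage_assembly(cfg, table, frame, out, written, manifest)
                elif stage == "mantel":
                    _stage_mantel(cfg, table, frame, env, out, written, manifest)
            except Exception as e:
                for f in written:
                    if f.exists():
                        f.rename(f.with_suffix(f.suffix + ".partial"))
                raise RuntimeError(f"stage {stage!r} failed: {e}") from e
            manifest["outputs"].extend(str(f.relative_to(out)) for f in written)
            logger.info("stage %s finished in %.2f s", stage, time.perf_counter() - t0)

        manifest_path = out / "run_manifest.json"
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        logger.info("pipeline finished in %.2f s", time.perf_counter() - t_start)
        return manifest
    finally:
        logger.removeHandler(collector)


def _stage_diversity(cfg, table, frame, env, out: Path, written: list[Path]) -> None:
    alpha = diversity.alpha_diversity_table(table)
    alpha.insert(0, "group", frame.data.set_index("sample_id").loc[alpha.index, "group"].to_numpy())
    p = out / "alpha_diversity.tsv"
    _write_tsv(alpha, p, index=True, index_label="sample_id")
    written.append(p)
    bc = diversity.bray_curtis(table)
    p = out / "bray_curtis.tsv"
    _write_tsv(bc.to_dataframe(), p, index=True, index_label="sample_id")
    written.append(p)
    if env is not None:
        het = diversity.env_heterogeneity(env, frame, metric=cfg.env_metric)
        df = pd.DataFrame(
            [
                {"group": g, "mean_distance": h["mean"], "n_samples": h["n_samples"], "metric": cfg.env_metric}
                for g, h in het.items()
            ]
        )
        p = out / "env_heterogeneity.tsv"
        _write_tsv(df, p)
        written.append(p)


def _stage_tar(cfg, table, frame, out: Path, written: list[Path]) -> None:
    curves = sar.build_tar(table, frame)
    pts = pd.concat([c.points.assign(group=g) for g, c in curves.items()], ignore_index=True)
    p = out / "tar_points.tsv"
    _write_tsv(pts, p)
    written.append(p)
    fits = []
    for g, c in curves.items():
        for model in cfg.tar_models:
            f = sar.fit_sar(c, model=model, log_base=cfg.log_base)
            fits.append({"group": g, **asdict(f)})
    p = out / "tar_fits.tsv"
    _write_tsv(pd.DataFrame(fits), p)
    written.append(p)
    seed = _stage_seed(cfg.seed, "tar")
    tests = []
    groups = sorted(curves)
    for i, ga in enumerate(groups):
        for gb in groups[i + 1 :]:
            for model in cfg.tar_models:
                st = sar.compare_slopes(
                    curves[ga], curves[gb], model=model, n_perm=cfg.n_perm, seed=seed, log_base=cfg.log_base
                )
                tests.append({"group_a": ga, "group_b": gb, **asdict(st)})
    if tests:
        p = out / "tar_slope_tests.tsv"
        _write_tsv(pd.DataFrame(tests), p)
        written.append(p)


def _stage_nar(cfg, table, frame, out: Path, written: list[Path]) -> None:
    curves = network.build_nar(
        table,
        frame,
        min_rel_abund=cfg.min_rel_abund,
        min_prevalence=cfg.min_prevalence,
        r_thresh=cfg.r_thresh,
        p_thresh=cfg.p_thresh,
        correction=cfg.correction,
        min_samples=cfg.min_samples,
        mode=cfg.nar_mode,
    )
    pts = pd.concat([c.points.assign(group=g) for g, c in curves.items()], ignore_index=True)
    p = out / "nar_curve.tsv"
    _write_tsv(pts, p)
    written.append(p)
    breaks = []
    for g, c in curves.items():
        if len(c.points) >= 5:
            bp = network.fit_nar_breakpoint(c)
            breaks.append({"group": g, **asdict(bp)})
        else:
            logger.warning("nar: group %r has %d points (< 5); breakpoint fit skipped", g, len(c.points))
    if breaks:
        p = out / "nar_breakpoints.tsv"
        _write_tsv(pd.DataFrame(breaks), p)
        written.append(p)
    # full-data network edge lists per group (largest cumulative level)
    for g in frame.groups:
        gf = frame.for_group(g)
        sub = filter_taxa(table.select_samples(gf.sample_ids), cfg.min_rel_abund, cfg.min_prevalence)
        if sub.n_taxa < 2:
            continue
        corr = network.spearman_matrix(sub)
        net = network.build_network(corr, cfg.r_thresh, cfg.p_thresh, cfg.correction)
        p = out / f"network_edges_{g}.tsv"
        _write_tsv(net.edges, p)
        written.append(p)


def _stage_assembly(cfg, table, frame, out: Path, written: list[Path], manifest: dict) -> None:
    seed = _stage_seed(cfg.seed, "assembly")
    manifest["stage_seeds"]["nst"] = seed
    ncm_rows = []
    niche_rows = []
    for g in frame.groups:
        gf = frame.for_group(g)
        sub = table.select_samples(gf.sample_ids)
        sub = sub.select_taxa([tx for tx, tot in zip(sub.taxon_ids, sub.counts.sum(axis=0)) if tot > 0])
        try:
            fit = assembly.fit_ncm(sub)
            ncm_rows.append(
                {"group": g, "Nm": fit.Nm, "m": fit.m, "N": fit.N, "d": fit.d, "r2": fit.r2, "n_samples": fit.n_samples}
            )
            p = out / f"ncm_taxa_{g}.tsv"
            _write_tsv(fit.taxa, p, index=True, index_label="taxon_id")
            written.append(p)
        except ValueError as e:
            logger.warning("assembly: NCM fit skipped for group %r: %s", g, e)
        nb = assembly.niche_breadth(sub)
        niche_rows.append(
            {"group": g, "bcom": nb.bcom, "weighted_bcom": nb.weighted_bcom, "n_taxa": len(nb.breadth)}
        )
    if ncm_rows:
        p = out / "ncm_fit.tsv"
        _write_tsv(pd.DataFrame(ncm_rows), p)
        written.append(p)
    p = out / "niche_breadth.tsv"
    _write_tsv(pd.DataFrame(niche_rows), p)
    written.append(p)
    nst = assembly.compute_nst(table, frame, metric=cfg.nst_metric, n_null=cfg.n_null, seed=seed)
    df = pd.DataFrame(
        [
            {"group": g, "nst": r.nst, "se": r.se, "n_pairs": r.n_pairs, "n_null": r.n_null, "metric": r.metric}
            for g, r in nst.items()
        ]
    )
    p = out / "nst.tsv"
    _write_tsv(df, p)
    written.append(p)


def _stage_mantel(cfg, table, frame, env, out: Path, written: list[Path], manifest: dict) -> None:
    if env is None:
        logger.warning("mantel: no environment table; stage skipped")
        return
    seed = _stage_seed(cfg.seed, "mantel")
    manifest["stage_seeds"]["mantel"] = seed
    rows = []
    variables = [c for c in env.columns]
    for g in frame.groups:
        gf = frame.for_group(g)
        ids = gf.sample_ids
        if len(ids) < 4:
            logger.warning("mantel: group %r has < 4 samples; skipped", g)
            continue
        comm = diversity.bray_curtis(table.select_samples(ids))
        sub_env = env.loc[ids]
        for var in variables:
            vals = sub_env[var].to_numpy(dtype=float)
            if vals.std(ddof=1) == 0:
                logger.warning("mantel: variable %r constant in group %r; skipped", var, g)
                continue
            z = (vals - vals.mean()) / vals.std(ddof=1)
            d = np.abs(z[:, None] - z[None, :])
            env_dm = diversity.DistanceMatrix(ids, d, metric="euclidean")
            res = diversity.mantel(
                comm, env_dm, method=cfg.mantel_method, n_perm=cfg.n_perm, seed=seed, tail="greater"
            )
            rows.append(
                {"group": g, "variable": var, "r": res.r, "p": res.p, "n_perm": res.n_perm, "method": res.method}
            )
    if rows:
        p = out / "mantel.tsv"
        _write_tsv(pd.DataFrame(rows), p)
        written.append(p)
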