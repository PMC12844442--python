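"""Taxa-area relationships: nested pooling, model fitting, slope comparison.

For each replicate plot, samples are pooled cumulatively over nested levels
(everything inside the level-k quadrat) and richness of the pooled community
is recorded against sampled area.  Two classical species-area models are
fitted:

* logarithmic, S = c + z * log(A) -- ordinary least squares on log area;
* power, S = c * A**z -- nonlinear least squares on the original scale,
  initialised from log-log OLS.

The slope z is the spatial turnover rate; groups are compared by a
permutation test that reassigns (area, richness) points between groups and
refits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io_model import OtuTable, SampleFrame, pool_samples, rarefy

__all__ = ["TarCurve", "SarFit", "SlopeTest", "build_tar", "fit_sar", "compare_slopes"]

logger = logging.getLogger("microscale")


@dataclass
class TarCurve:
    """Richness-vs-area points of one group (one point per plot and level)."""

    points: pd.DataFrame = field(repr=False)  # columns: area, richness, plot_id, level
    group: str = ""

    def __post_init__(self) -> None:
        need = {"area", "richness", "plot_id"}
        if not need.issubset(self.points.columns):
            raise ValueError(f"points must have columns {sorted(need)}")
        if (self.points["area"] <= 0).any():
            raise ValueError("areas must be positive")
        if (self.points["richness"] < 1).any():
            raise ValueError("richness must be >= 1")
        for _, sub in self.points.groupby("plot_id"):
            s = sub.sort_values("area")["richness"].to_numpy()
            if (np.diff(s) < 0).any():
                raise ValueError("richness must be non-decreasing in area within a plot")


@dataclass
class SarFit:
    model: str  # "logarithm" | "power"
    c: float
    z: float
    r2: float
    n_points: int
    log_base: float = 10.0


@dataclass
class SlopeTest:
    z_a: float
    z_b: float
    delta: float
    p: float
    n_perm: int
    seed: int
    model: str
    unit: str


def build_tar(
    t: OtuTable,
    frame: SampleFrame,
    rarefy_depth: int | None = None,
    seed: int = 0,
) -> dict[str, TarCurve]:
    """Cumulative nested pooling: one richness-vs-area point per plot/level.

    For each plot and level k, all samples of the plot at levels <= k (i.e.
    inside the level-k quadrat extent) are pooled and the richness of the
    pooled count vector recorded against the level-k area.  Plots with a
    single level are excluded with a warning.  If *rarefy_depth* is given,
    each pooled vector is rarefied to that depth before counting richness.
    """
    curves: dict[str, TarCurve] = {}
    rng_seed = seed
    for g in frame.groups:
        gf = frame.for_group(g)
        rows = []
        for plot_id, sub in gf.data.groupby("plot_id", sort=True):
            levels = sorted(sub["level"].unique())
            if len(levels) < 2:
                logger.warning("build_tar: plot %r has a single level; excluded", plot_id)
                continue
            for k in levels:
                ids = list(sub.loc[sub["level"] <= k, "sample_id"])
                pooled = pool_samples(t, ids)
                if rarefy_depth is not None:
                    one = OtuTable(pooled[None, :], ["pool"], list(t.taxon_ids))
                    pooled = rarefy(one, rarefy_depth, seed=rng_seed).counts[0]
                    rng_seed += 1
                rows.append(
                    {
                        "area": gf.area_of_level(k),
                        "richness": int((pooled > 0).sum()),
                        "plot_id": plot_id,
                        "level": k,
                    }
                )
        if rows:
            curves[g] = TarCurve(pd.DataFrame(rows), group=g)
    if not curves:
        raise ValueError("no plot has at least two nested levels")
    return curves


def _ols_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    xm = x.mean()
    ym = y.mean()
    vx = ((x - xm) ** 2).sum()
    if vx == 0:
        raise ValueError("need at least two distinct areas")
    z = float(((x - xm) * (y - ym)).sum() / vx)
    return ym - z * xm, z


def _r2(y: np.ndarray, yhat: np.ndarray) -> float:
    sstot = float(((y - y.mean()) ** 2).sum())
    ssres = float(((y - yhat) ** 2).sum())
    if sstot == 0:
        return 1.0 if ssres < 1e-12 else 0.0
    return 1.0 - ssres / sstot


def _fit_arrays(area: np.ndarray, S: np.ndarray, model: str, log_base: float) -> tuple[float, float, float]:
    """Fit (c, z, r2) on raw arrays; shared by fit_sar and the permutations."""
    if np.unique(area).size < 3:
        raise ValueError("need at least 3 distinct areas to fit")
    if model == "logarithm":
        x = np.log(area) / np.log(log_base)
        c, z = _ols_slope(x, S)
        return c, z, _r2(S, c + z * x)
    if model == "power":
        # initialise from log-log OLS (richness >= 1 so logs are finite)
        lc, lz = _ols_slope(np.log(area), np.log(S))
        p0 = (float(np.exp(lc)), float(lz))
        last_err: Exception | None = None
        for jitter in (1.0, 0.5, 2.0, 0.1):
            try:
                popt, _ = curve_fit(
                    lambda A, c, z: c * A**z,
                    area,
                    S,
                    p0=(p0[0] * jitter, p0[1]),
                    maxfev=20000,
                )
                c, z = float(popt[0]), float(popt[1])
                return c, z, _r2(S, c * area**z)
            except RuntimeError as e:  # pragma: no cover - rarely triggered
                last_err = e
        raise RuntimeError(f"power-model fit did not converge after restarts (p0={p0}): {last_err}")
    raise ValueError(f"unknown model: {model!r}")


def fit_sar(curve: TarCurve, model: str = "logarithm", log_base: float = 10.0) -> SarFit:
    """Fit one species-area model to a curve's pooled points.

    R-squared is computed on the original richness scale for both models so
    they are directly comparable.  The logarithm of area uses *log_base*
    (default 10); z's magnitude depends on this choice and the base is
    reported alongside.
    """
    pts = curve.points
    area = pts["area"].to_numpy(dtype=float)
    S = pts["richness"].to_numpy(dtype=float)
    c, z, r2 = _fit_arrays(area, S, model, log_base)
    return SarFit(model, c, z, r2, len(S), log_base)


def compare_slopes(
    a: TarCurve,
    b: TarCurve,
    model: str = "logarithm",
    n_perm: int = 999,
    seed: int = 0,
    log_base: float = 10.0,
    unit: str = "point",
) -> SlopeTest:
    """Permutation test for a difference in spatial turnover rate.

    The observed statistic is delta = z_a - z_b.  Null curves are built by
    randomly reassigning the pooled (area, richness) points -- or whole
    plots, with ``unit="plot"`` -- to the two groups, preserving group sizes,
    and refitting; p = (1 + #{|delta_perm| >= |delta_obs|}) / (n_perm + 1).
    """
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if unit not in ("point", "plot"):
        raise ValueError(f"unknown permutation unit: {unit!r}")
    fit_a = fit_sar(a, model, log_base)
    fit_b = fit_sar(b, model, log_base)
    delta_obs = fit_a.z - fit_b.z
    pool = pd.concat(
        [a.points.assign(_src="a"), b.points.assign(_src="b")], ignore_index=True
    )
    rng = np.random.default_rng(seed)

    area = pool["area"].to_numpy(dtype=float)
    S = pool["richness"].to_numpy(dtype=float)
    if unit == "plot":
        # plots are distinct per source group even when the ids collide
        keys = list(zip(pool["_src"], pool["plot_id"]))
        plot_rows = [
            np.flatnonzero([k == key for k in keys]) for key in dict.fromkeys(keys)
        ]
        na = a.points["plot_id"].nunique()
        deltas = np.empty(n_perm)
        for i in range(n_perm):
            order = rng.permutation(len(plot_rows))
            ia = np.concatenate([plot_rows[j] for j in order[:na]])
            ib = np.concatenate([plot_rows[j] for j in order[na:]])
            deltas[i] = (
                _fit_arrays(area[ia], S[ia], model, log_base)[1]
                - _fit_arrays(area[ib], S[ib], model, log_base)[1]
            )
    elif model == "logarithm":
        # closed-form OLS slopes for every permutation at once
        x = np.log(area) / np.log(log_base)
        na = len(a.points)
        perms = np.argsort(rng.random((n_perm, len(pool))), axis=1)
        deltas = _perm_slope_deltas(x, S, perms, na)
    else:
        na = len(a.points)
        deltas = np.empty(n_perm)
        for i in range(n_perm):
            order = rng.permutation(len(pool))
            deltas[i] = (
                _fit_arrays(area[order[:na]], S[order[:na]], model, log_base)[1]
                - _fit_arrays(area[order[na:]], S[order[na:]], model, log_base)[1]
            )
    p = (1 + int((np.abs(deltas) >= abs(delta_obs) - 1e-12).sum())) / (n_perm + 1)
    return SlopeTest(fit_a.z, fit_b.z, delta_obs, p, n_perm, seed, model, unit)


def _perm_slope_deltas(x: np.ndarray, y: np.ndarray, perms: np.ndarray, na: int) -> np.ndarray:
    def slopes(idx: np.ndarray) -> np.ndarray:
        xs = x[idx]
        ys = y[idx]
        xm = xs.mean(axis=1, keepdims=True)
        ym = ys.mean(axis=1, keepdims=True)
        num = ((xs - xm) * (ys - ym)).sum(axis=1)
        den = ((xs - xm) ** 2).sum(axis=1)
        return num / den

    return slopes(perms[:, :na]) - slopes(perms[:, na:])
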