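"""Alpha/beta diversity, environmental heterogeneity and the Mantel test."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .io_model import OtuTable, SampleFrame

__all__ = [
    "DistanceMatrix",
    "MantelResult",
    "alpha_diversity",
    "alpha_diversity_table",
    "bray_curtis",
    "env_heterogeneity",
    "mantel",
]

logger = logging.getLogger("microscale")


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with sample ids and a metric label."""

    ids: list[str]
    matrix: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.matrix), 0.0, atol=1e-12):
            raise ValueError("distance matrix must have a zero diagonal")
        if (self.matrix < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def condensed(self) -> np.ndarray:
        """Lower-triangle entries in scipy condensed order."""
        return squareform(self.matrix, checks=False)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.ids, columns=self.ids)


def alpha_diversity(counts) -> dict[str, float]:
    """Richness, Shannon-Wiener (natural log) and Gini-Simpson of one sample."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector")
    q = counts[counts > 0] / total
    return {
        "richness": int((counts > 0).sum()),
        "shannon": float(-(q * np.log(q)).sum()),
        "simpson": float(1.0 - (q**2).sum()),
    }


def alpha_diversity_table(t: OtuTable) -> pd.DataFrame:
    """Per-sample alpha diversity indices as a DataFrame."""
    rows = [alpha_diversity(t.counts[i]) for i in range(t.n_samples)]
    return pd.DataFrame(rows, index=t.sample_ids)


def bray_curtis(t: OtuTable) -> DistanceMatrix:
    """Pairwise Bray-Curtis dissimilarity, d = sum|a-b| / sum(a+b)."""
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    totals = t.sample_totals()
    if (totals == 0).any():
        empty = [s for s, tt in zip(t.sample_ids, totals) if tt == 0]
        raise ValueError(f"samples with zero total counts: {empty}")
    d = squareform(pdist(t.counts.astype(float), metric="braycurtis"))
    return DistanceMatrix(list(t.sample_ids), d, metric="braycurtis")


def env_heterogeneity(
    env: pd.DataFrame,
    frame: SampleFrame,
    metric: str = "euclidean",
) -> dict[str, dict]:
    """Within-group environmental distances on z-scored variables.

    Variables are standardised (sample sd, ddof=1) over *all* samples of the
    frame, then pairwise distances are computed within each group under the
    chosen metric (``euclidean`` or ``braycurtis``).  Constant variables are
    dropped with a warning.  Returns per group the condensed distance vector
    and its mean -- the group's environmental heterogeneity.
    """
    if metric not in ("euclidean", "braycurtis"):
        raise ValueError(f"unknown metric: {metric!r}")
    missing = [s for s in frame.sample_ids if s not in env.index]
    if missing:
        raise KeyError(f"samples missing from environment table: {missing}")
    sub = env.loc[frame.sample_ids].astype(float)
    sd = sub.std(ddof=1)
    constant = list(sd.index[(sd == 0) | sd.isna()])
    if constant:
        logger.warning("env_heterogeneity: dropping constant variable(s): %s", constant)
        sub = sub.drop(columns=constant)
        sd = sd.drop(index=constant)
    if sub.shape[1] == 0:
        raise ValueError("no non-constant environmental variables")
    z = (sub - sub.mean()) / sd
    out: dict[str, dict] = {}
    for g in frame.groups:
        ids = frame.for_group(g).sample_ids
        if len(ids) < 2:
            logger.warning("env_heterogeneity: group %r has < 2 samples; skipped", g)
            continue
        dist = pdist(z.loc[ids].to_numpy(), metric=metric)
        out[g] = {"distances": dist, "mean": float(dist.mean()), "n_samples": len(ids)}
    return out


@dataclass
class MantelResult:
    r: float
    p: float
    n_perm: int
    method: str
    tail: str
    seed: int
    n: int


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x @ x) * (y @ y))
    return float(x @ y / denom) if denom > 0 else 0.0


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
    tail: str = "greater",
) -> MantelResult:
    """Mantel test between two distance matrices over the same samples.

    The statistic is the Pearson (or Spearman) correlation of the lower
    triangles; the null distribution permutes the rows and columns of the
    second matrix jointly.  p = (1 + #{r_perm >= r_obs}) / (n_perm + 1) for
    ``tail="greater"``; ``"two-sided"`` compares |r_perm| >= |r_obs|.
    """
    if d1.ids != d2.ids:
        raise ValueError("distance matrices have mismatched sample ids")
    if n_perm < 99:
        raise ValueError("n_perm must be >= 99")
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown method: {method!r}")
    if tail not in ("greater", "two-sided"):
        raise ValueError(f"unknown tail: {tail!r}")
    n = len(d1.ids)
    if n < 4:
        raise ValueError("need at least 4 samples")
    v1 = d1.condensed()
    if method == "spearman":
        v1 = rankdata(v1)
    m2 = d2.matrix
    iu = np.triu_indices(n, k=1)

    def stat(mat: np.ndarray) -> float:
        v2 = mat[iu]
        if method == "spearman":
            v2 = rankdata(v2)
        return _corr(v1, v2)

    r_obs = stat(m2)
    rng = np.random.default_rng(seed)
    # all permutations at once: permute rows/cols of d2 jointly
    perms = np.argsort(rng.random((n_perm, n)), axis=1)
    permuted = m2[perms[:, :, None], perms[:, None, :]]  # (n_perm, n, n)
    v2s = permuted[:, iu[0], iu[1]]  # (n_perm, n_pairs)
    if method == "spearman":
        v2s = rankdata(v2s, axis=1)
    a = v1 - v1.mean()
    b = v2s - v2s.mean(axis=1, keepdims=True)
    denom = np.sqrt((a @ a) * (b * b).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r_perm = np.where(denom > 0, b @ a / denom, 0.0)
    if tail == "greater":
        hits = int((r_perm >= r_obs - 1e-12).sum())
    else:
        hits = int((np.abs(r_perm) >= abs(r_obs) - 1e-12).sum())
    p = (1 + hits) / (n_perm + 1)
    return MantelResult(r=r_obs, p=p, n_perm=n_perm, method=method, tail=tail, seed=seed, n=n)
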