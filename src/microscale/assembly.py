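"""Community-assembly inference: neutral model, stochasticity ratio, niche breadth.

Three estimators that together separate stochastic from deterministic
assembly:

* **Sloan neutral community model (NCM)** -- at stationarity a taxon with
  metacommunity frequency p has local relative abundance distributed
  Beta(Nm*p, Nm*(1-p)), so its expected occurrence frequency across samples
  of depth N is F(p) = 1 - I_d(Nm*p, Nm*(1-p)), the upper tail of the Beta
  distribution above a detection limit d (one read: d = 1/N).  Fitting Nm to
  the observed frequency-vs-abundance cloud yields the migration rate
  m = Nm/N; high R-squared means the cloud is shaped as neutral dynamics
  predict.
* **Normalised stochasticity ratio (NST)** -- compares observed pairwise
  dissimilarities with their expectation under a null model that preserves
  per-sample richness and draws occupancy/abundance from the regional pool;
  values above 0.5 are read as stochasticity-dominated assembly.
* **Levins niche breadth** -- B_i = 1 / sum_j P_ij^2 over samples j, the
  inverse concentration of a taxon's abundance distribution; community-level
  breadth is the mean over taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special
from scipy.spatial.distance import pdist
from statsmodels.stats.proportion import proportion_confint

from .io_model import OtuTable, SampleFrame

__all__ = [
    "NcmFit",
    "NstResult",
    "NicheBreadthResult",
    "ncm_predict",
    "fit_ncm",
    "compute_nst",
    "niche_breadth",
]

logger = logging.getLogger("microscale")


# ---------------------------------------------------------------------------
# Sloan neutral community model
# ---------------------------------------------------------------------------


def ncm_predict(p, Nm: float, d: float):
    """Predicted occurrence frequency 1 - I_d(Nm*p, Nm*(1-p)).

    ``p`` may be a scalar or array of mean relative abundances in (0, 1);
    ``d`` is the detection limit on the relative-abundance scale.
    """
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if not (0 < d < 1):
        raise ValueError("detection limit d must lie in (0, 1)")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("mean relative abundances must lie strictly in (0, 1)")
    return 1.0 - special.betainc(Nm * p, Nm * (1.0 - p), d)


def ncm_predict_exact(p, Nm: float, N: int):
    """Detection probability under Beta abundances compounded with
    multinomial sampling at depth N.

    With local abundance q ~ Beta(a, b), a = Nm*p, b = Nm*(1-p), the chance
    of drawing zero of N reads is E[(1-q)^N] = B(a, b+N) / B(a, b), so the
    occurrence frequency is one minus that (a beta-binomial zero
    probability).  Unlike the Beta-tail approximation at d = 1/N, this
    accounts for the read-sampling step and is unbiased when presence means
    "at least one read".
    """
    p = np.asarray(p, dtype=float)
    if Nm <= 0:
        raise ValueError("Nm must be positive")
    if N < 1:
        raise ValueError("depth N must be >= 1")
    if ((p <= 0) | (p >= 1)).any():
        raise ValueError("mean relative abundances must lie strictly in (0, 1)")
    a = Nm * p
    b = Nm * (1.0 - p)
    return 1.0 - np.exp(special.betaln(a, b + N) - special.betaln(a, b))


@dataclass
class NcmFit:
    """Fitted neutral-model parameters and the per-taxon frequency table."""

    Nm: float
    m: float
    N: int
    d: float
    r2: float
    n_samples: int
    taxa: pd.DataFrame = field(repr=False)  # p_mean, F_obs, F_pred, ci_low, ci_high, partition


def fit_ncm(
    t: OtuTable,
    d: float | None = None,
    ci_alpha: float = 0.05,
    detection: str = "exact",
) -> NcmFit:
    """Fit Nm by least squares of observed vs predicted occurrence frequency.

    Requires a uniform per-sample depth (rarefy first).  ``detection``
    selects the frequency prediction: ``"exact"`` (default) uses the
    beta-binomial zero probability at depth N, which is unbiased when
    presence means at least one read; ``"beta-tail"`` is the classic upper
    Beta tail above the detection limit d (default one read, d = 1/N).  Nm
    is located by a log-spaced grid search refined with bounded scalar
    minimisation; the 95% band around the prediction uses Wilson binomial
    intervals at the sample count, and each taxon is partitioned as above /
    within / below that band.
    """
    if detection not in ("exact", "beta-tail"):
        raise ValueError(f"unknown detection mode: {detection!r}")
    totals = t.sample_totals()
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    if np.unique(totals).size != 1:
        raise ValueError(
            "fit_ncm requires a uniform per-sample depth; rarefy the table first "
            f"(depths range {totals.min()}..{totals.max()})"
        )
    N = int(totals[0])
    if d is None:
        d = 1.0 / N
    if t.n_samples < 20:
        logger.warning("fit_ncm: only %d samples; estimates will be noisy", t.n_samples)
    rel = t.relative_abundance()
    p_mean = rel.mean(axis=0)
    F_obs = (t.counts > 0).mean(axis=0)
    keep = (p_mean > 0) & (p_mean < 1)
    if keep.sum() < 3:
        raise ValueError("too few taxa with usable mean abundances")
    p_use = p_mean[keep]
    F_use = F_obs[keep]

    def predict(nm: float) -> np.ndarray:
        if detection == "exact":
            return ncm_predict_exact(p_use, nm, N)
        return ncm_predict(p_use, nm, d)

    def sse(log_nm: float) -> float:
        resid = F_use - predict(float(np.exp(log_nm)))
        return float(resid @ resid)

    grid = np.log(np.logspace(0, np.log10(100.0 * N), 60))
    losses = [sse(g) for g in grid]
    best = int(np.argmin(losses))
    lo = grid[max(best - 1, 0)]
    hi = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(sse, bounds=(lo, hi), method="bounded")
    if not res.success:
        raise RuntimeError(f"NCM fit failed to converge: {res.message}; grid best Nm={np.exp(grid[best]):.3g}")
    Nm = float(np.exp(res.x))
    if best == len(grid) - 1:
        logger.warning("fit_ncm: Nm at the upper grid bound (saturated occurrences?)")
    F_pred = predict(Nm)
    sstot = float(((F_use - F_use.mean()) ** 2).sum())
    ssres = float(((F_use - F_pred) ** 2).sum())
    r2 = 1.0 - ssres / sstot if sstot > 0 else (1.0 if ssres < 1e-12 else 0.0)
    n = t.n_samples
    ci_low, ci_high = proportion_confint(np.round(F_pred * n), n, alpha=ci_alpha, method="wilson")
    partition = np.where(F_use > ci_high, "above", np.where(F_use < ci_low, "below", "within"))
    taxa = pd.DataFrame(
        {
            "p_mean": p_use,
            "F_obs": F_use,
            "F_pred": F_pred,
            "ci_low": ci_low,
            "ci_high": ci_high,
            "partition": partition,
        },
        index=[tx for tx, k in zip(t.taxon_ids, keep) if k],
    )
    return NcmFit(Nm=Nm, m=Nm / N, N=N, d=d, r2=r2, n_samples=n, taxa=taxa)


# ---------------------------------------------------------------------------
# Normalised stochasticity ratio
# ---------------------------------------------------------------------------


@dataclass
class NstResult:
    group: str
    nst: float
    se: float
    n_pairs: int
    n_null: int
    metric: str
    null_model: str
    d_obs: np.ndarray = field(repr=False)
    e_null: np.ndarray = field(repr=False)
    n_excluded: int = 0


def _pair_dissim(counts: np.ndarray, metric: str) -> np.ndarray:
    if metric == "braycurtis":
        return pdist(counts.astype(float), metric="braycurtis")
    if metric == "jaccard":
        return pdist(counts > 0, metric="jaccard")
    raise ValueError(f"unknown metric: {metric!r}")


def _null_counts(
    rng: np.random.Generator,
    richness: np.ndarray,
    totals: np.ndarray,
    occ_freq: np.ndarray,
    rel_abund: np.ndarray,
) -> np.ndarray:
    """One null community matrix: per-sample richness fixed, occupancy drawn
    proportional to regional occurrence frequency, abundances re-assigned
    proportional to regional relative abundances."""
    n = richness.size
    S = occ_freq.size
    pool = np.flatnonzero(occ_freq > 0)
    probs = occ_freq[pool] / occ_freq[pool].sum()
    out = np.zeros((n, S), dtype=np.int64)
    for j in range(n):
        k = min(int(richness[j]), pool.size)
        occ = rng.choice(pool, size=k, replace=False, p=probs)
        a = rel_abund[occ]
        a_sum = a.sum()
        a = a / a_sum if a_sum > 0 else np.full(k, 1.0 / k)
        out[j, occ] = rng.multinomial(int(totals[j]), a)
    return out


def compute_nst(
    t: OtuTable,
    frame: SampleFrame,
    metric: str = "braycurtis",
    n_null: int = 1000,
    seed: int = 0,
    null_model: str = "proportional",
) -> dict[str, NstResult]:
    """Normalised stochasticity ratio per group.

    For each within-group sample pair, the deviation of the observed
    dissimilarity D from its null expectation E is scaled to a selection
    strength C = (D - E) / (Dmax - E) when D > E (Dmax = 1) and
    C = (E - D) / E otherwise; stochasticity is ST = 1 - C and NST is the
    mean ST over pairs, clipped to [0, 1], with its standard error over
    pairs.  Groups with fewer than 4 samples are skipped with a warning;
    pairs with E = 0 are excluded and counted.
    """
    if null_model != "proportional":
        raise ValueError(f"unknown null model: {null_model!r}")
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    results: dict[str, NstResult] = {}
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(frame.groups))
    for g, child in zip(frame.groups, children):
        gf = frame.for_group(g)
        if len(gf.sample_ids) < 4:
            logger.warning("compute_nst: group %r has < 4 samples; skipped", g)
            continue
        sub = t.select_samples(gf.sample_ids)
        counts = sub.counts
        richness = (counts > 0).sum(axis=1)
        totals = counts.sum(axis=1)
        occ_freq = (counts > 0).mean(axis=0)
        rel_abund = counts.sum(axis=0) / counts.sum()
        d_obs = _pair_dissim(counts, metric)
        rng = np.random.default_rng(child)
        e_sum = np.zeros_like(d_obs)
        for _ in range(n_null):
            null = _null_counts(rng, richness, totals, occ_freq, rel_abund)
            e_sum += _pair_dissim(null, metric)
        e_null = e_sum / n_null
        usable = e_null > 0
        n_excluded = int((~usable).sum())
        if n_excluded:
            logger.warning("compute_nst: group %r: %d pair(s) with zero null expectation excluded", g, n_excluded)
        D = d_obs[usable]
        E = e_null[usable]
        C = np.where(D > E, (D - E) / (1.0 - E), (E - D) / E)
        st = 1.0 - C
        nst = float(np.clip(st.mean(), 0.0, 1.0))
        se = float(st.std(ddof=1) / np.sqrt(st.size)) if st.size > 1 else 0.0
        results[g] = NstResult(
            group=g,
            nst=nst,
            se=se,
            n_pairs=int(st.size),
            n_null=n_null,
            metric=metric,
            null_model=null_model,
            d_obs=d_obs,
            e_null=e_null,
            n_excluded=n_excluded,
        )
    if not results:
        raise ValueError("no group has at least 4 samples")
    return results


# ---------------------------------------------------------------------------
# Levins niche breadth
# ---------------------------------------------------------------------------


@dataclass
class NicheBreadthResult:
    breadth: pd.Series  # per-taxon Levins B
    bcom: float  # community-level mean
    weighted_bcom: float  # abundance-weighted mean


def niche_breadth(t: OtuTable) -> NicheBreadthResult:
    """Levins niche breadth B_i = 1 / sum_j P_ij^2 per taxon.

    P_ij is the share of taxon i's total found in sample j, so B ranges from
    1 (confined to one sample) to the number of samples (perfectly even).
    Taxa with zero total are excluded; the community value is the unweighted
    mean of B over the remaining taxa (abundance-weighted mean also
    reported).
    """
    if t.n_samples < 2:
        raise ValueError("need at least 2 samples")
    col_tot = t.counts.sum(axis=0).astype(float)
    keep = col_tot > 0
    P = t.counts[:, keep] / col_tot[keep]
    B = 1.0 / (P**2).sum(axis=0)
    ids = [tx for tx, k in zip(t.taxon_ids, keep) if k]
    weights = col_tot[keep] / col_tot[keep].sum()
    return NicheBreadthResult(
        breadth=pd.Series(B, index=ids, name="levins_B"),
        bcom=float(B.mean()),
        weighted_bcom=float((B * weights).sum()),
    )
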