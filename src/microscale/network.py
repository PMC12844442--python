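"""Co-occurrence networks and the node-area relationship (NAR).

A co-occurrence network connects taxa whose abundance profiles across samples
show a strong, significant Spearman correlation (|r| > 0.80, p < 0.05 by
default).  Taxa are pre-filtered by overall relative abundance and
prevalence.  The NAR tracks how the number of network nodes (co-occurring
taxa) changes as the sampled area grows: for each nested level the network is
rebuilt from the cumulative sample set inside that area.  A two-piece
segmented regression on log area detects the tipping point where co-occurring
richness stops rising and declines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io_model import OtuTable, SampleFrame, filter_taxa

__all__ = [
    "CorrelationMatrix",
    "Network",
    "NetworkStats",
    "NarCurve",
    "BreakpointFit",
    "spearman_matrix",
    "build_network",
    "network_properties",
    "build_nar",
    "fit_nar_breakpoint",
]

logger = logging.getLogger("microscale")


@dataclass
class CorrelationMatrix:
    taxon_ids: list[str]
    r: np.ndarray
    p: np.ndarray
    n_samples: int
    constant_taxa: list[str] = field(default_factory=list)


def spearman_matrix(t: OtuTable, min_samples: int = 5) -> CorrelationMatrix:
    """All-pairs Spearman correlation with t-approximation p-values.

    Ranks use average tie handling; two-sided p-values come from the
    t-distribution on r * sqrt((n-2)/(1-r^2)), with p = 0 at exactly
    |r| = 1.  Constant taxon vectors have undefined correlations; their
    entries are recorded as r = 0, p = 1 and the taxa flagged.
    """
    n = t.n_samples
    if n < min_samples:
        raise ValueError(f"need at least {min_samples} samples for correlation p-values (got {n})")
    X = t.counts.astype(float)
    const = X.std(axis=0) == 0
    ranks = stats.rankdata(X, axis=0)
    Z = ranks - ranks.mean(axis=0)
    sd = Z.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    Zn = Z / sd_safe
    r = (Zn.T @ Zn) / n
    r = np.clip(r, -1.0, 1.0)
    r[const, :] = 0.0
    r[:, const] = 0.0
    np.fill_diagonal(r, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    p[np.abs(r) >= 1.0 - 1e-12] = 0.0
    p[const, :] = 1.0
    p[:, const] = 1.0
    np.fill_diagonal(p, 0.0)
    return CorrelationMatrix(
        taxon_ids=list(t.taxon_ids),
        r=r,
        p=p,
        n_samples=n,
        constant_taxa=[tx for tx, c in zip(t.taxon_ids, const) if c],
    )


@dataclass
class Network:
    """Thresholded correlation graph; nodes are taxa with at least one edge."""

    graph: nx.Graph
    r_thresh: float
    p_thresh: float
    correction: str

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> pd.DataFrame:
        rows = [
            {"taxon_a": u, "taxon_b": v, "r": d["r"], "p": d["p"], "sign": d["sign"]}
            for u, v, d in self.graph.edges(data=True)
        ]
        cols = ["taxon_a", "taxon_b", "r", "p", "sign"]
        return pd.DataFrame(rows, columns=cols)


def build_network(
    c: CorrelationMatrix,
    r_thresh: float = 0.80,
    p_thresh: float = 0.05,
    correction: str = "none",
) -> Network:
    """Edges where |r| strictly exceeds *r_thresh* and the (optionally
    BH-corrected) p-value is below *p_thresh*; isolated taxa are not nodes."""
    if correction not in ("none", "bh"):
        raise ValueError(f"unknown correction: {correction!r}")
    S = len(c.taxon_ids)
    iu = np.triu_indices(S, k=1)
    pvals = c.p[iu]
    if correction == "bh" and pvals.size:
        pvals = multipletests(pvals, method="fdr_bh")[1]
    rvals = c.r[iu]
    keep = (np.abs(rvals) > r_thresh) & (pvals < p_thresh)
    g = nx.Graph()
    for a, b, r, p in zip(iu[0][keep], iu[1][keep], rvals[keep], pvals[keep]):
        g.add_edge(
            c.taxon_ids[a],
            c.taxon_ids[b],
            r=float(r),
            p=float(p),
            sign="+" if r > 0 else "-",
        )
    return Network(graph=g, r_thresh=r_thresh, p_thresh=p_thresh, correction=correction)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    pos_fraction: float
    mean_degree: float
    density: float
    n_components: int


def network_properties(net: Network) -> NetworkStats:
    """Topological summary; an empty network yields all zeros."""
    g = net.graph
    n = g.number_of_nodes()
    e = g.number_of_edges()
    if n == 0:
        return NetworkStats(0, 0, 0.0, 0.0, 0.0, 0)
    pos = sum(1 for _, _, d in g.edges(data=True) if d["sign"] == "+")
    return NetworkStats(
        n_nodes=n,
        n_edges=e,
        pos_fraction=pos / e if e else 0.0,
        mean_degree=2.0 * e / n,
        density=nx.density(g),
        n_components=nx.number_connected_components(g),
    )


@dataclass
class NarCurve:
    """Node/edge counts against area, one row per usable nested level."""

    points: pd.DataFrame = field(repr=False)
    # columns: level, area, n_nodes, n_edges, pos_fraction, n_samples, n_taxa_filtered
    group: str = ""


def build_nar(
    t: OtuTable,
    frame: SampleFrame,
    min_rel_abund: float = 0.001,
    min_prevalence: float = 0.2,
    r_thresh: float = 0.80,
    p_thresh: float = 0.05,
    correction: str = "none",
    min_samples: int = 8,
    mode: str = "cumulative",
) -> dict[str, NarCurve]:
    """Node-area curves per group.

    For each nested level k of a group, the network is built from the
    samples at levels <= k across the group's plots (``mode="cumulative"``,
    mirroring the nested pooling of the taxa-area curves) or from the
    level-k samples only (``mode="per-level"``).  The abundance/prevalence
    filter is re-applied to each level's sample set before correlation.
    Levels whose sample count is below *min_samples* are skipped with a
    warning.
    """
    if mode not in ("cumulative", "per-level"):
        raise ValueError(f"unknown mode: {mode!r}")
    curves: dict[str, NarCurve] = {}
    for g in frame.groups:
        gf = frame.for_group(g)
        rows = []
        for k in sorted(gf.data["level"].unique()):
            if mode == "cumulative":
                ids = list(gf.data.loc[gf.data["level"] <= k, "sample_id"])
            else:
                ids = list(gf.data.loc[gf.data["level"] == k, "sample_id"])
            if len(ids) < min_samples:
                logger.warning(
                    "build_nar: group %r level %d has %d sample(s) < min_samples=%d; skipped",
                    g, k, len(ids), min_samples,
                )
                continue
            sub = filter_taxa(t.select_samples(ids), min_rel_abund, min_prevalence)
            if sub.n_taxa < 2:
                stats_ = NetworkStats(0, 0, 0.0, 0.0, 0.0, 0)
            else:
                corr = spearman_matrix(sub, min_samples=min(min_samples, 5))
                net = build_network(corr, r_thresh, p_thresh, correction)
                stats_ = network_properties(net)
            rows.append(
                {
                    "level": int(k),
                    "area": gf.area_of_level(int(k)),
                    "n_nodes": stats_.n_nodes,
                    "n_edges": stats_.n_edges,
                    "pos_fraction": stats_.pos_fraction,
                    "n_samples": len(ids),
                    "n_taxa_filtered": sub.n_taxa,
                }
            )
        if not rows:
            raise ValueError(f"group {g!r}: no level reaches min_samples={min_samples}")
        curves[g] = NarCurve(pd.DataFrame(rows), group=g)
    return curves


@dataclass
class BreakpointFit:
    shape: str  # "unimodal" | "monotonic-increasing" | "monotonic-decreasing"
    break_level: int | None
    break_area: float | None
    slope_before: float
    slope_after: float
    sse_segmented: float
    sse_line: float
    line_slope: float


def fit_nar_breakpoint(curve: NarCurve, min_improvement: float = 0.10) -> BreakpointFit:
    """Tipping-point detection on (log10 area, node count).

    A single line and a continuous two-piece linear model (breakpoint
    searched over the interior observed levels by an SSE grid) are fitted.
    The curve is classified unimodal when the segmented model improves SSE by
    at least *min_improvement* (fraction) over the line AND the slopes flip
    from positive to negative; otherwise it is monotonic, by the sign of the
    single-line slope (a flat line counts as decreasing).  Deterministic.
    """
    pts = curve.points.sort_values("area")
    if len(pts) < 5:
        raise ValueError("need at least 5 node-area points")
    x = np.log10(pts["area"].to_numpy(dtype=float))
    y = pts["n_nodes"].to_numpy(dtype=float)
    levels = pts["level"].to_numpy()
    X1 = np.column_stack([np.ones_like(x), x])
    beta1, res1, *_ = np.linalg.lstsq(X1, y, rcond=None)
    sse_line = float(((y - X1 @ beta1) ** 2).sum())
    line_slope = float(beta1[1])

    best = None
    for i in range(1, len(x) - 1):
        xb = x[i]
        Xs = np.column_stack([np.ones_like(x), x, np.maximum(0.0, x - xb)])
        beta, *_ = np.linalg.lstsq(Xs, y, rcond=None)
        sse = float(((y - Xs @ beta) ** 2).sum())
        if best is None or sse < best[0]:
            best = (sse, i, float(beta[1]), float(beta[1] + beta[2]))
    sse_seg, i_break, slope_before, slope_after = best
    unimodal = (
        sse_line > 0
        and sse_seg <= (1.0 - min_improvement) * sse_line
        and slope_before > 0
        and slope_after < 0
    )
    if unimodal:
        return BreakpointFit(
            shape="unimodal",
            break_level=int(levels[i_break]),
            break_area=float(pts["area"].to_numpy()[i_break]),
            slope_before=slope_before,
            slope_after=slope_after,
            sse_segmented=sse_seg,
            sse_line=sse_line,
            line_slope=line_slope,
        )
    shape = "monotonic-increasing" if line_slope > 0 else "monotonic-decreasing"
    return BreakpointFit(
        shape=shape,
        break_level=None,
        break_area=None,
        slope_before=slope_before,
        slope_after=slope_after,
        sse_segmented=sse_seg,
        sse_line=sse_line,
        line_slope=line_slope,
    )
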