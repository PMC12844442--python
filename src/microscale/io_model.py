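"""Core data containers and tab-separated I/O for community tables.

Everything downstream (diversity, taxa-area curves, co-occurrence networks,
assembly inference) operates on three objects:

* :class:`OtuTable` -- a samples x taxa matrix of non-negative integer counts.
* :class:`SampleFrame` -- per-sample metadata for a nested quadrat design:
  group, replicate plot, quadrat corner coordinates, nested scale level and
  sampled area.
* an environment table -- a plain :class:`pandas.DataFrame` of numeric soil
  variables indexed by sample id (see :func:`read_env_table`).

The module also provides the shared preprocessing steps: rarefaction to even
depth, abundance/prevalence filtering of taxa, and pooling of samples into a
single composite count vector.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "OtuTable",
    "SampleFrame",
    "read_otu_table",
    "write_otu_table",
    "read_sample_frame",
    "write_sample_frame",
    "read_env_table",
    "write_env_table",
    "rarefy",
    "filter_taxa",
    "pool_samples",
]

logger = logging.getLogger("microscale")

TOOL_VERSION = "0.1.0"


def _check_unique(ids, kind: str) -> None:
    seen = set()
    for i in ids:
        if i in seen:
            raise ValueError(f"duplicate {kind} id: {i!r}")
        seen.add(i)


@dataclass
class OtuTable:
    """Samples x taxa matrix of non-negative integer counts.

    Rows are samples, columns are taxa (OTUs at whatever similarity
    threshold produced them); ids are kept in stable order so that a
    write/read round trip is exact.
    """

    counts: np.ndarray
    sample_ids: list[str]
    taxon_ids: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.taxon_ids, "taxon")
        if not np.issubdtype(self.counts.dtype, np.integer):
            rounded = np.rint(self.counts)
            if not np.allclose(self.counts, rounded, atol=1e-9):
                bad = np.argwhere(~np.isclose(self.counts, rounded))[0]
                raise ValueError(
                    "non-integer count at sample "
                    f"{self.sample_ids[bad[0]]!r}, taxon {self.taxon_ids[bad[1]]!r}"
                )
            self.counts = rounded.astype(np.int64)
        if (self.counts < 0).any():
            bad = np.argwhere(self.counts < 0)[0]
            raise ValueError(
                "negative count at sample "
                f"{self.sample_ids[bad[0]]!r}, taxon {self.taxon_ids[bad[1]]!r}"
            )

    # -- basic accessors -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Row-normalised matrix of per-sample relative abundances."""
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            empty = [s for s, t in zip(self.sample_ids, totals) if t == 0]
            raise ValueError(f"samples with zero total counts: {empty}")
        return self.counts / totals[:, None]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "OtuTable":
        return cls(df.to_numpy(), list(df.index), list(df.columns))

    def select_samples(self, sample_ids) -> "OtuTable":
        idx = self._sample_indices(sample_ids)
        return OtuTable(self.counts[idx], [self.sample_ids[i] for i in idx], list(self.taxon_ids))

    def select_taxa(self, taxon_ids) -> "OtuTable":
        pos = {t: j for j, t in enumerate(self.taxon_ids)}
        try:
            idx = [pos[t] for t in taxon_ids]
        except KeyError as e:
            raise KeyError(f"unknown taxon id: {e.args[0]!r}") from None
        return OtuTable(self.counts[:, idx], list(self.sample_ids), [self.taxon_ids[j] for j in idx])

    def _sample_indices(self, sample_ids) -> list[int]:
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        try:
            return [pos[s] for s in sample_ids]
        except KeyError as e:
            raise KeyError(f"unknown sample id: {e.args[0]!r}") from None


#: required columns of a sample frame, in canonical order
SAMPLE_COLUMNS = ["sample_id", "group", "plot_id", "x", "y", "level", "area"]


@dataclass
class SampleFrame:
    """Per-sample metadata for a nested quadrat design.

    Each replicate plot holds quadrats at levels k = 0, 1, 2, ... whose side
    doubles per level (side0 * 2**k), so sampled area is (side0 * 2**k)**2 in
    m^2.  Quadrats of one plot share an origin: every level-k quadrat lies
    inside the level-(k+1) quadrat.  ``x``/``y`` are corner coordinates in
    meters from the plot origin.
    """

    data: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.data.copy()
        missing = [c for c in SAMPLE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"sample frame missing columns: {missing}")
        df["sample_id"] = df["sample_id"].astype(str)
        _check_unique(df["sample_id"], "sample")
        df["level"] = df["level"].astype(int)
        for c in ("x", "y", "area"):
            df[c] = df[c].astype(float)
        if (df["level"] < 0).any():
            raise ValueError("nested level must be >= 0")
        if (df["area"] <= 0).any():
            raise ValueError("area must be positive")
        # area must equal (side0 * 2**level)**2 with a single side0 > 0
        side = np.sqrt(df["area"].to_numpy()) / 2.0 ** df["level"].to_numpy()
        if not np.allclose(side, side[0], rtol=1e-6):
            raise ValueError("areas are not consistent with a doubling nested design")
        self.side0 = float(side[0])
        # geometric nesting: a level-k sample sits on/in its own quadrat,
        # hence inside every larger quadrat of the same (shared-origin) plot
        side_k = self.side0 * 2.0 ** df["level"].to_numpy()
        eps = 1e-9 + 1e-9 * side_k
        if ((df["x"].to_numpy() < -eps[0]) | (df["y"].to_numpy() < -eps[0])).any() or (
            (df["x"].to_numpy() > side_k + eps) | (df["y"].to_numpy() > side_k + eps)
        ).any():
            raise ValueError("sample coordinates fall outside their own quadrat extent")
        self.data = df.reset_index(drop=True)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data["sample_id"])

    @property
    def groups(self) -> list[str]:
        return list(pd.unique(self.data["group"]))

    def area_of_level(self, level: int) -> float:
        return (self.side0 * 2.0**level) ** 2

    def subset(self, mask) -> "SampleFrame":
        return SampleFrame(self.data[mask].reset_index(drop=True))

    def for_group(self, group: str) -> "SampleFrame":
        sub = self.data[self.data["group"] == group]
        if sub.empty:
            raise KeyError(f"unknown group: {group!r}")
        return SampleFrame(sub.reset_index(drop=True))


# ---------------------------------------------------------------------------
# TSV I/O.  Dialect: tab-separated, UTF-8, '#'-prefixed comment lines ignored;
# every file written carries a header comment with the tool version (and the
# seed when the content is stochastic).
# ---------------------------------------------------------------------------


def _header_comment(seed: int | None = None) -> str:
    line = f"# microscale v{TOOL_VERSION}"
    if seed is not None:
        line += f" seed={seed}"
    return line + "\n"


def read_otu_table(path, orientation: str = "samples", sample_ids=None) -> OtuTable:
    """Read a count table from TSV.

    Parameters
    ----------
    orientation:
        ``"samples"`` -- rows are samples (the native layout);
        ``"taxa"`` -- rows are taxa (classic OTU-table layout), transposed on
        read; ``"auto"`` -- decided by overlap of the row ids with
        *sample_ids* (requires *sample_ids*).
    """
    # pandas silently renames duplicated header ids; check them verbatim first
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.strip() and not line.startswith("#"):
                _check_unique(line.rstrip("\n").split("\t")[1:], "column")
                break
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    if df.empty:
        raise ValueError(f"empty table: {path}")
    if orientation == "auto":
        if sample_ids is None:
            raise ValueError("orientation='auto' requires sample_ids")
        known = set(map(str, sample_ids))
        row_hits = sum(str(i) in known for i in df.index)
        col_hits = sum(str(c) in known for c in df.columns)
        if row_hits == 0 and col_hits == 0:
            raise ValueError("cannot auto-detect orientation: no id overlap")
        orientation = "samples" if row_hits >= col_hits else "taxa"
    if orientation == "taxa":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation: {orientation!r}")
    df.index = df.index.map(str)
    df.columns = df.columns.map(str)
    bad = df.columns[df.apply(lambda c: pd.to_numeric(c, errors="coerce").isna().any())]
    if len(bad):
        raise ValueError(f"non-numeric counts in column(s): {list(bad)}")
    return OtuTable.from_dataframe(df)


def write_otu_table(t: OtuTable, path, orientation: str = "samples", seed: int | None = None) -> None:
    df = t.to_dataframe()
    if orientation == "taxa":
        df = df.T
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        df.to_csv(fh, sep="\t", index_label="id", lineterminator="\n")


def read_sample_frame(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    return SampleFrame(df)


def write_sample_frame(frame: SampleFrame, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        frame.data.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_env_table(path) -> pd.DataFrame:
    """Read a sample x variable table of numeric environmental measurements."""
    df = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    df.index = df.index.map(str)
    _check_unique(df.index, "sample")
    df = df.apply(pd.to_numeric)
    if not np.isfinite(df.to_numpy(dtype=float)).all():
        raise ValueError("environment table contains non-finite values")
    return df


def write_env_table(env: pd.DataFrame, path, seed: int | None = None) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header_comment(seed))
        env.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def rarefy(t: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to *depth* reads without replacement.

    Samples whose total is below *depth* are dropped with a logged warning;
    the survivors are exact multivariate-hypergeometric subsamples summing to
    *depth*.  Deterministic for a fixed seed.
    """
    depth = int(depth)
    if depth <= 0:
        raise ValueError("rarefaction depth must be >= 1")
    totals = t.sample_totals()
    keep = totals >= depth
    if not keep.any():
        raise ValueError(f"all samples have fewer than {depth} reads")
    dropped = [s for s, k in zip(t.sample_ids, keep) if not k]
    if dropped:
        logger.warning("rarefy: dropping %d sample(s) below depth %d: %s", len(dropped), depth, dropped)
    rng = np.random.default_rng(seed)
    rows = []
    ids = []
    for i in np.flatnonzero(keep):
        row = t.counts[i]
        if totals[i] == depth:
            rows.append(row.copy())
        else:
            rows.append(rng.multivariate_hypergeometric(row, depth))
        ids.append(t.sample_ids[i])
    return OtuTable(np.asarray(rows, dtype=np.int64), ids, list(t.taxon_ids))


def filter_taxa(t: OtuTable, min_rel_abund: float = 0.001, min_prevalence: float = 0.2) -> OtuTable:
    """Drop taxa by overall relative abundance and prevalence.

    A taxon is kept when its share of the grand total is >= *min_rel_abund*
    AND it is detected (count > 0) in at least *min_prevalence* of the
    samples of the table handed in.  The sample set is unchanged; per-group
    filtering is achieved by subsetting first.
    """
    if not (0 <= min_rel_abund <= 1 and 0 <= min_prevalence <= 1):
        raise ValueError("thresholds must lie in [0, 1]")
    grand = t.counts.sum()
    if grand == 0:
        raise ValueError("table has no counts")
    share = t.counts.sum(axis=0) / grand
    prevalence = (t.counts > 0).mean(axis=0)
    keep = (share >= min_rel_abund) & (prevalence >= min_prevalence)
    if not keep.any():
        logger.warning("filter_taxa: no taxon passes thresholds; returning empty table")
    kept_ids = [tax for tax, k in zip(t.taxon_ids, keep) if k]
    return OtuTable(t.counts[:, keep], list(t.sample_ids), kept_ids)


def pool_samples(t: OtuTable, sample_ids) -> np.ndarray:
    """Element-wise sum of the selected sample rows (composite community)."""
    idx = t._sample_indices(sample_ids)
    if not idx:
        raise ValueError("no samples to pool")
    return t.counts[idx].sum(axis=0)
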