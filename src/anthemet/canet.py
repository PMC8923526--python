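"""Correspondence analysis of predictor-metabolite profiles and the
association networks built from it, plus the diurnal-stability screen.

The standardized metabolite matrix is shifted by its single global minimum
to make every entry nonnegative, then decomposed by classical
correspondence analysis (SVD of the standardized chi-square residuals).
Both leaf samples (rows) and metabolites (columns) receive principal
coordinates in all min(n, m) - 1 dimensions -- the symmetric map, matching
the procedure of the study; note that row-to-column distances on a
symmetric map are not chi-square distances, which is accepted here to
mirror that procedure.

Associations are declared where Euclidean distances over all dimensions
fall strictly below the 15th percentile of all distances; metabolite-to-
characteristic networks aggregate passed metabolite-sample pairs by the
mean distance to samples of each characteristic level.

The diurnal screen ranks panel metabolites by the population SD of their
0-1-scaled time series (small SD = sampling-time-robust marker) and flags
day/night associations from the sampling-time network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist, squareform

from .preprocess import MetaboliteMatrix, scale01

DAY_HOURS = frozenset(range(6, 19))           # 06:00-18:00 inclusive
NIGHT_HOURS = frozenset([20, 21, 22, 23, 0, 1, 2, 3, 4])  # 20:00-04:00


class CAError(ValueError):
    pass


def nonneg_shift(matrix: MetaboliteMatrix) -> MetaboliteMatrix:
    """Subtract the single global minimum from every entry so the matrix is
    nonnegative with minimum exactly 0 (idempotent on such matrices)."""
    v = matrix.values
    lo = float(v.to_numpy().min())
    shifted = v - lo if lo != 0 else v.copy()
    from dataclasses import replace
    return replace(matrix, values=shifted)


@dataclass
class CAResult:
    """Row (sample) and column (metabolite) principal coordinates with the
    inertia decomposition of the table's chi-square statistic."""

    row_coords: pd.DataFrame
    col_coords: pd.DataFrame
    singular_values: np.ndarray
    principal_inertias: np.ndarray
    total_inertia: float
    row_masses: np.ndarray
    col_masses: np.ndarray

    @property
    def d(self) -> int:
        return self.row_coords.shape[1]


def correspondence_analysis(values: pd.DataFrame | np.ndarray) -> CAResult:
    """Classical CA of a nonnegative table.

    P = N/grand total; standardized residuals S_ij = (P_ij - r_i c_j) /
    sqrt(r_i c_j) are decomposed by SVD; principal coordinates are
    diag(r)^(-1/2) U Sigma for rows and diag(c)^(-1/2) V Sigma for columns,
    keeping all d = min(n, m) - 1 dimensions.  Total inertia equals the
    Pearson chi-square statistic divided by the grand total.
    """
    if isinstance(values, pd.DataFrame):
        row_index, col_index = values.index, values.columns
        N = values.to_numpy(dtype=float)
    else:
        N = np.asarray(values, dtype=float)
        row_index = pd.RangeIndex(N.shape[0])
        col_index = pd.RangeIndex(N.shape[1])
    if np.any(N < 0):
        raise CAError("correspondence analysis requires nonnegative entries")
    zero_rows = np.where(N.sum(axis=1) <= 0)[0]
    zero_cols = np.where(N.sum(axis=0) <= 0)[0]
    if zero_rows.size or zero_cols.size:
        raise CAError(
            f"zero-sum rows {list(row_index[zero_rows])} / columns {list(col_index[zero_cols])}"
        )
    total = N.sum()
    P = N / total
    r = P.sum(axis=1)
    c = P.sum(axis=0)
    S = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    U, s, Vt = np.linalg.svd(S, full_matrices=False)
    d = min(N.shape) - 1
    U, s, Vt = U[:, :d], s[:d], Vt[:d]
    # deterministic sign convention, as for PCA
    for k in range(d):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            Vt[k] *= -1
            U[:, k] *= -1
    total_inertia = float((S ** 2).sum())
    if total_inertia <= 1e-15:
        warnings.warn("table has (numerically) independent rows and columns; "
                      "all CA coordinates are zero", RuntimeWarning)
    rows = (U * s) / np.sqrt(r)[:, None]
    cols = (Vt.T * s) / np.sqrt(c)[:, None]
    dims = [f"Dim{k + 1}" for k in range(d)]
    return CAResult(
        row_coords=pd.DataFrame(rows, index=row_index, columns=dims),
        col_coords=pd.DataFrame(cols, index=col_index, columns=dims),
        singular_values=s,
        principal_inertias=s ** 2,
        total_inertia=total_inertia,
        row_masses=r,
        col_masses=c,
    )


def cross_distances(ca: CAResult) -> pd.DataFrame:
    """Euclidean distances between every metabolite (column) and leaf
    sample (row) over all CA dimensions: metabolites x samples."""
    d = cdist(ca.col_coords.to_numpy(), ca.row_coords.to_numpy())
    return pd.DataFrame(d, index=ca.col_coords.index, columns=ca.row_coords.index)


def pairwise_distances(coords: pd.DataFrame) -> pd.DataFrame:
    """Symmetric Euclidean distance matrix among one coordinate set."""
    d = squareform(pdist(coords.to_numpy()))
    return pd.DataFrame(d, index=coords.index, columns=coords.index)


@dataclass
class EdgeList:
    """Thresholded association edges with the threshold that produced them."""

    edges: pd.DataFrame          # node_a, node_b, distance, passed
    threshold_value: float
    percentile: float

    @property
    def passed(self) -> pd.DataFrame:
        return self.edges[self.edges["passed"]]

    def to_tsv(self, path) -> None:
        out = self.edges.copy()
        out.to_csv(path, sep="\t", index=False, float_format="%.8g")

    def to_graphml(self, path, passed_only: bool = True) -> None:
        import networkx as nx

        g = nx.Graph()
        rows = self.passed if passed_only else self.edges
        for row in rows.itertuples(index=False):
            g.add_edge(row.node_a, row.node_b, weight=float(row.distance))
        nx.write_graphml(g, path)


def percentile_threshold(
    distances, percentile: float = 0.15, *, kind_a: str = "metabolite",
    kind_b: str = "sample",
) -> tuple[float, EdgeList]:
    """Empirical percentile (linear interpolation) of all distances as the
    association threshold; an edge passes iff its distance is strictly
    below the threshold."""
    if isinstance(distances, pd.DataFrame):
        long = distances.stack()
        node_a = long.index.get_level_values(0)
        node_b = long.index.get_level_values(1)
        values = long.to_numpy(dtype=float)
    else:
        values = np.asarray(distances, dtype=float).ravel()
        node_a = pd.RangeIndex(values.size)
        node_b = pd.RangeIndex(values.size)
    if values.size == 0:
        raise CAError("no distances supplied")
    threshold = float(np.percentile(values, percentile * 100))
    edges = pd.DataFrame({
        "node_a": node_a, "node_b": node_b,
        "distance": values, "passed": values < threshold,
    })
    return threshold, EdgeList(edges, threshold, percentile)


def upper_triangle_edges(sym: pd.DataFrame) -> pd.DataFrame:
    """Unique unordered pairs (upper triangle) of a symmetric distance
    matrix as a long frame."""
    labels = list(sym.columns)
    iu = np.triu_indices(len(labels), k=1)
    return pd.DataFrame({
        "node_a": [labels[i] for i in iu[0]],
        "node_b": [labels[j] for j in iu[1]],
        "distance": sym.to_numpy()[iu],
    })


def metabolite_network(
    coords_cols: pd.DataFrame, percentile: float = 0.15
) -> tuple[float, EdgeList]:
    """Metabolite-metabolite network: pairwise CA-coordinate distances
    thresholded at the percentile of all unique pairs."""
    sym = pairwise_distances(coords_cols)
    long = upper_triangle_edges(sym)
    if long.empty:
        raise CAError("need at least two metabolites")
    threshold = float(np.percentile(long["distance"], percentile * 100))
    long["passed"] = long["distance"] < threshold
    return threshold, EdgeList(long, threshold, percentile)


def day_night_labels(sample_meta: pd.DataFrame) -> pd.Series:
    """'day' for clock times 06:00-18:00, 'night' for 20:00-04:00; any
    other (off-grid) sampling time is an error."""
    times = pd.to_datetime(sample_meta["datetime"])
    out = []
    for ts in times:
        if ts.minute or ts.second:
            raise CAError(f"off-grid sampling time {ts}")
        if ts.hour in DAY_HOURS:
            out.append("day")
        elif ts.hour in NIGHT_HOURS:
            out.append("night")
        else:
            raise CAError(f"sampling hour {ts.hour:02d}:00 is outside the day/night windows")
    return pd.Series(out, index=sample_meta.index, name="day_night")


def aggregate_by_characteristic(
    edge_list: EdgeList,
    sample_meta: pd.DataFrame,
    characteristic: str,
    *,
    mode: str = "threshold-first",
) -> pd.DataFrame:
    """Metabolite-to-characteristic-level network.

    ``characteristic`` is a metadata column ('experiment', 'cultivar', ...)
    or the derived labels 'sampling_time' (clock time) / 'day_night'.  In
    the default threshold-first mode each (metabolite, level) edge is the
    mean distance of the metabolite's *passed* sample pairs to samples of
    that level, and levels with no passed pair get no edge.  In
    'aggregate-first' mode mean distances over *all* pairs are computed
    first and the percentile threshold is re-applied to those means.
    """
    if characteristic == "sampling_time":
        labels = pd.to_datetime(sample_meta["datetime"]).dt.strftime("%H:%M")
    elif characteristic == "day_night":
        labels = day_night_labels(sample_meta)
    else:
        if characteristic not in sample_meta.columns:
            raise CAError(f"samples are not labeled for {characteristic!r}")
        labels = sample_meta[characteristic]
    if labels.isna().any():
        raise CAError(f"unlabeled samples for characteristic {characteristic!r}")
    edges = edge_list.edges.copy()
    edges["level"] = labels.reindex(edges["node_b"]).to_numpy()
    if edges["level"].isna().any():
        missing = edges.loc[edges["level"].isna(), "node_b"].unique()[:5]
        raise CAError(f"edge samples missing from metadata: {list(missing)}")
    if mode == "threshold-first":
        passed = edges[edges["passed"]]
        agg = (passed.groupby(["node_a", "level"], sort=True)["distance"]
               .agg(["mean", "size"]).reset_index())
        agg.columns = ["metabolite", "level", "mean_distance", "n_pairs"]
        return agg
    if mode == "aggregate-first":
        means = (edges.groupby(["node_a", "level"], sort=True)["distance"]
                 .agg(["mean", "size"]).reset_index())
        means.columns = ["metabolite", "level", "mean_distance", "n_pairs"]
        thr = float(np.percentile(means["mean_distance"], edge_list.percentile * 100))
        return means[means["mean_distance"] < thr].reset_index(drop=True)
    raise CAError(f"unknown aggregation mode {mode!r}")


@dataclass
class StabilityRecord:
    metabolite_id: str
    sd_scaled: float
    day_association: bool
    night_association: bool


def diurnal_stability(
    matrix: MetaboliteMatrix,
    panel_ids,
    day_night_network: pd.DataFrame | None = None,
) -> list[StabilityRecord]:
    """Diurnal-stability screen over time-series samples.

    Each panel metabolite is 0-1 scaled over the supplied samples and
    scored by the population SD of the scaled series (bounded by 0.5);
    records are returned sorted ascending so the most sampling-time-robust
    markers come first.  Day/night association flags are filled from a
    metabolite-to-day/night characteristic network when one is supplied.
    """
    sub = matrix.subset(list(panel_ids))
    if sub.n_samples < 2:
        raise CAError("need at least two timepoints")
    scaled = scale01(sub)
    sds = scaled.values.std(axis=0, ddof=0)
    day_set, night_set = set(), set()
    if day_night_network is not None and len(day_night_network):
        day_set = set(day_night_network.loc[
            day_night_network["level"] == "day", "metabolite"])
        night_set = set(day_night_network.loc[
            day_night_network["level"] == "night", "metabolite"])
    records = [
        StabilityRecord(m, float(sds[m]), m in day_set, m in night_set)
        for m in scaled.values.columns
    ]
    records.sort(key=lambda rec: (rec.sd_scaled, rec.metabolite_id))
    return records
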