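"""Anthesis rates from cumulative flower counts, and rank-based group tests.

The anthesis rate of a group (cultivar or experiment) over an interval is the
gradient of the straight line between two neighboring points of the
cumulative-anthesis curve, expressed in flowers per week.  Each leaf sample
inherits the rate of the interval containing its sampling date, so all
2-hourly samples of one cultivar-week share one rate.

Group comparisons use the Mann-Whitney U test (two groups) and the
Kruskal-Wallis test with Conover-Iman pairwise comparisons (three or more),
implemented on midranks with tie corrections.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as _sps


class RateError(ValueError):
    """Raised when an anthesis series or rate pairing is invalid."""


@dataclass
class AnthesisSeries:
    """Cumulative flower counts of one group over ordered dates."""

    group: str
    dates: pd.DatetimeIndex
    cumulative_counts: np.ndarray

    def __post_init__(self) -> None:
        self.dates = pd.DatetimeIndex(self.dates)
        self.cumulative_counts = np.asarray(self.cumulative_counts, dtype=float)
        if len(self.dates) != len(self.cumulative_counts):
            raise RateError("dates and counts differ in length")
        if self.dates.duplicated().any():
            raise RateError(f"duplicate dates in series {self.group!r}")
        if not self.dates.is_monotonic_increasing:
            raise RateError(f"dates must be strictly increasing in series {self.group!r}")
        if np.any(np.diff(self.cumulative_counts) < 0):
            raise RateError(f"cumulative counts decrease in series {self.group!r}")
        if np.any(self.cumulative_counts < 0):
            raise RateError("cumulative counts must be nonnegative")

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> list["AnthesisSeries"]:
        """Build one series per group from a long table with columns
        (group, date, cumulative_count)."""
        out = []
        for group, sub in df.groupby("group", sort=True):
            sub = sub.sort_values("date")
            out.append(cls(str(group), pd.DatetimeIndex(sub["date"]),
                           sub["cumulative_count"].to_numpy()))
        return out


def anthesis_rates(series: AnthesisSeries) -> pd.DataFrame:
    """Per-interval anthesis rates: (C_{k+1} - C_k)/(t_{k+1} - t_k), time in
    7-day weeks.  Returns a RateTable frame with columns
    (group, date_start, date_end, rate)."""
    if len(series.dates) < 2:
        raise RateError("need at least two dates to form a rate")
    dt_weeks = np.diff(series.dates.view("int64")) / (7 * 24 * 3600 * 1e9)
    rates = np.diff(series.cumulative_counts) / dt_weeks
    return pd.DataFrame({
        "group": series.group,
        "date_start": series.dates[:-1],
        "date_end": series.dates[1:],
        "rate": rates,
    })


def rate_table(series_list: list[AnthesisSeries]) -> pd.DataFrame:
    return pd.concat([anthesis_rates(s) for s in series_list], ignore_index=True)


def assign_rates_to_samples(
    rates: pd.DataFrame,
    sample_meta: pd.DataFrame,
    group_column: str = "group",
    *,
    nearest_fallback: bool = False,
) -> pd.Series:
    """Give each sample the rate of the (date_start, date_end] interval that
    contains its sampling date, matched on the group label.

    A sample dated exactly on an interval boundary takes the interval ending
    at that date.  Samples outside every interval raise (or take the nearest
    interval under ``nearest_fallback``).
    """
    if group_column not in sample_meta.columns:
        raise RateError(f"sample metadata lacks a {group_column!r} column")
    sample_dates = pd.to_datetime(sample_meta["datetime"]).dt.normalize()
    y = pd.Series(np.nan, index=sample_meta.index, name="rate")
    unmatched: list = []
    for idx, (grp, date) in enumerate(zip(sample_meta[group_column], sample_dates)):
        sub = rates[rates["group"] == grp]
        if sub.empty:
            unmatched.append(sample_meta.index[idx])
            continue
        starts = pd.to_datetime(sub["date_start"]).dt.normalize()
        ends = pd.to_datetime(sub["date_end"]).dt.normalize()
        hit = sub[(starts < date) & (date <= ends)]
        if len(hit):
            y.iloc[idx] = hit["rate"].iloc[0]
        elif nearest_fallback:
            mid = starts + (ends - starts) / 2
            y.iloc[idx] = sub["rate"].iloc[int(np.argmin(np.abs(mid - date)))]
        else:
            unmatched.append(sample_meta.index[idx])
    if unmatched:
        raise RateError(f"samples outside all rate intervals: {unmatched[:10]}"
                        + ("..." if len(unmatched) > 10 else ""))
    return y


# ---------------------------------------------------------------------------
# rank tests
# ---------------------------------------------------------------------------

def _midranks(x: np.ndarray) -> np.ndarray:
    return _sps.rankdata(x, method="average")


def mann_whitney_u(a, b, *, exact_limit: int = 8) -> tuple[float, float]:
    """Mann-Whitney U statistic of group A with a two-sided p-value.

    U is computed from midrank sums.  When both groups have at most
    ``exact_limit`` observations the null distribution is enumerated exactly
    over all assignments of the pooled midranks (valid under ties); otherwise
    the normal approximation with tie correction and continuity correction
    is used.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise RateError("both groups must be nonempty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = _midranks(pooled)
    u_a = ranks[:na].sum() - na * (na + 1) / 2
    mu = na * nb / 2
    if na <= exact_limit and nb <= exact_limit:
        # exact permutation distribution of U over C(N, na) selections
        n_total = na + nb
        dev = abs(u_a - mu)
        hits = 0
        for combo in itertools.combinations(range(n_total), na):
            u = ranks[list(combo)].sum() - na * (na + 1) / 2
            if abs(u - mu) >= dev - 1e-12:
                hits += 1
        p = hits / comb(n_total, na)
    else:
        n_total = na + nb
        _, counts = np.unique(pooled, return_counts=True)
        tie_term = ((counts ** 3 - counts).sum()) / (n_total * (n_total - 1))
        sigma2 = na * nb / 12 * (n_total + 1 - tie_term)
        if sigma2 <= 0:
            p = 1.0
        else:
            z = (abs(u_a - mu) - 0.5) / sqrt(sigma2)
            p = float(min(1.0, 2 * _sps.norm.sf(max(z, 0.0))))
    return float(u_a), float(p)


def kruskal_wallis_conover(
    groups: list[np.ndarray] | dict[str, np.ndarray],
    *,
    adjust: str | None = None,
) -> dict:
    """Kruskal-Wallis H test with Conover-Iman pairwise comparisons.

    H uses midranks with the tie correction; pairwise statistics follow
    t_ab = (Rbar_a - Rbar_b) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_a + 1/n_b))
    with S^2 the variance of all midranks, referred to Student t with N-k
    degrees of freedom (two-sided).  ``adjust='holm'`` applies a step-down
    adjustment to the pairwise p-values; the default reports them unadjusted.

    Returns a dict with 'H', 'p', and a 'pairwise' DataFrame.
    """
    if isinstance(groups, dict):
        labels = list(groups.keys())
        data = [np.asarray(groups[k], dtype=float) for k in labels]
    else:
        data = [np.asarray(g, dtype=float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(data))]
    k = len(data)
    if k < 3:
        raise RateError("need at least 3 groups; use mann_whitney_u for two")
    if any(g.size < 2 for g in data):
        raise RateError("each group needs at least 2 observations")
    sizes = np.array([g.size for g in data])
    n_total = int(sizes.sum())
    pooled = np.concatenate(data)
    ranks = _midranks(pooled)
    bounds = np.cumsum(sizes)[:-1]
    rank_groups = np.split(ranks, bounds)
    rank_sums = np.array([r.sum() for r in rank_groups])
    h = 12 / (n_total * (n_total + 1)) * np.sum(rank_sums ** 2 / sizes) - 3 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1 - (counts ** 3 - counts).sum() / (n_total ** 3 - n_total)
    if tie <= 0:  # all observations identical
        h_corrected = 0.0
    else:
        h_corrected = float(h / tie)
    p = float(_sps.chi2.sf(h_corrected, k - 1)) if h_corrected > 0 else 1.0

    s2 = float(np.sum(ranks ** 2) - n_total * (n_total + 1) ** 2 / 4) / (n_total - 1)
    df = n_total - k
    scale = s2 * max(n_total - 1 - h_corrected, 0.0) / df
    means = rank_sums / sizes
    rows = []
    for (i, j) in itertools.combinations(range(k), 2):
        denom = sqrt(scale * (1 / sizes[i] + 1 / sizes[j]))
        if denom == 0:
            t, pv = 0.0, 1.0
        else:
            t = (means[i] - means[j]) / denom
            pv = float(min(1.0, 2 * _sps.t.sf(abs(t), df)))
        rows.append({"group_a": labels[i], "group_b": labels[j],
                     "t": float(t), "p": pv})
    pairwise = pd.DataFrame(rows)
    if adjust == "holm":
        order = np.argsort(-np.abs(pairwise["t"].to_numpy()))
        m = len(pairwise)
        adj = np.empty(m)
        running = 0.0
        for rank_pos, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank_pos) * pairwise["p"].iloc[idx]))
            adj[idx] = running
        pairwise["p_adjusted"] = adj
    elif adjust is not None:
        raise RateError(f"unknown adjustment {adjust!r}")
    return {"H": h_corrected, "p": p, "pairwise": pairwise}
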