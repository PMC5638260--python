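"""Empirical check-in analysis: heavy tails, co-coincidences, encounter nets.

Works on location-based-social-network check-in streams (one record per
event: anonymous user, UTC timestamp + timezone offset, lat/lon, venue).
The pipeline measures the inter-event time and displacement distributions
with power-law fits (continuous MLE, KS-optimal lower cutoff in the
Clauset style), detects hourly co-coincidences of user pairs within a
radius ``delta_r``, and builds the cumulative encounter network whose
links mark pairs with at least ``c`` co-coincident hours.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import networkx as nx
from scipy.optimize import minimize_scalar

from .spatial import haversine_km
from .encounters import average_degree, clustering

# Column order of the public NYC/Tokyo check-in dump (TSV, no header).
DEFAULT_COLUMNS = (
    "user_id", "venue_id", "venue_category_id", "venue_category",
    "lat", "lon", "tz_offset", "utc_time",
)
_TIME_FORMAT = "%a %b %d %H:%M:%S %z %Y"


@dataclass
class CheckinTable:
    """Validated check-in records plus a count of rejected input rows."""

    records: pd.DataFrame
    n_malformed: int = 0

    def __post_init__(self) -> None:
        need = {"user_id", "utc_time", "tz_offset", "lat", "lon"}
        missing = need - set(self.records.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def n_users(self) -> int:
        return self.records["user_id"].nunique()

    def by_user(self) -> pd.core.groupby.DataFrameGroupBy:
        """Per-user chronological view."""
        return self.records.sort_values(["user_id", "utc_time"]).groupby(
            "user_id", sort=False)


def read_checkins(path, columns=DEFAULT_COLUMNS, time_format: str = _TIME_FORMAT,
                  encoding: str = "utf-8", encoding_errors: str = "replace") -> CheckinTable:
    """Parse a TSV check-in dump into a validated :class:`CheckinTable`.

    Malformed rows (unparseable timestamp or out-of-range coordinates) are
    counted and reported with a warning, never silently dropped.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=list(columns),
                     encoding=encoding, encoding_errors=encoding_errors,
                     dtype={"user_id": str}, on_bad_lines="warn")
    if df.empty:
        warnings.warn(f"{path}: empty check-in file")
        return CheckinTable(_empty_frame(columns), 0)
    t = pd.to_datetime(df["utc_time"], format=time_format, errors="coerce", utc=True)
    lat = pd.to_numeric(df["lat"], errors="coerce")
    lon = pd.to_numeric(df["lon"], errors="coerce")
    tz = pd.to_numeric(df["tz_offset"], errors="coerce")
    bad = (t.isna() | lat.isna() | lon.isna() | tz.isna()
           | (lat.abs() > 90) | (lon.abs() > 180))
    if bad.any():
        lines = (df.index[bad] + 1).tolist()
        warnings.warn(
            f"{path}: dropped {bad.sum()} malformed row(s) at lines "
            f"{lines[:10]}{'...' if len(lines) > 10 else ''}")
    out = df.loc[~bad].copy()
    out["utc_time"] = t[~bad]
    out["lat"] = lat[~bad]
    out["lon"] = lon[~bad]
    out["tz_offset"] = tz[~bad].astype(int)
    return CheckinTable(out.reset_index(drop=True), int(bad.sum()))


def _empty_frame(columns) -> pd.DataFrame:
    df = pd.DataFrame({c: [] for c in columns})
    df["utc_time"] = pd.to_datetime(df["utc_time"], utc=True)
    return df


def interevent_times(table: CheckinTable) -> np.ndarray:
    """Gaps tau (hours) between successive check-ins, per user, pooled.

    Users with a single check-in contribute nothing; gaps are never taken
    across users.
    """
    out = []
    for _, g in table.by_user():
        if len(g) < 2:
            continue
        dt = g["utc_time"].diff().dropna().dt.total_seconds().to_numpy() / 3600.0
        out.append(dt)
    if not out:
        return np.empty(0)
    return np.concatenate(out)


def displacements(table: CheckinTable) -> np.ndarray:
    """Great-circle distances r (km) between successive check-ins, pooled."""
    out = []
    for _, g in table.by_user():
        if len(g) < 2:
            continue
        lat = g["lat"].to_numpy()
        lon = g["lon"].to_numpy()
        out.append(haversine_km(lat[:-1], lon[:-1], lat[1:], lon[1:]))
    if not out:
        return np.empty(0)
    return np.concatenate(out)


@dataclass(frozen=True)
class PowerLawFit:
    """P(x) ~ x^-exponent for x >= x_min (or on a fixed [lo, hi] range)."""

    exponent: float
    x_min: float
    ks_distance: float
    n_tail: int
    x_max: float | None = None


def _mle_exponent(tail: np.ndarray, x_min: float) -> float:
    # continuous MLE: alpha = 1 + n / sum ln(x_i / x_min)
    return 1.0 + tail.size / np.log(tail / x_min).sum()


def _ks_tail(tail_sorted: np.ndarray, x_min: float, alpha: float) -> float:
    n = tail_sorted.size
    model = 1.0 - (tail_sorted / x_min) ** (1.0 - alpha)
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.abs(ecdf_hi - model).max(), np.abs(ecdf_lo - model).max()))


def fit_power_law_xmin(samples: np.ndarray, max_candidates: int = 500,
                       min_tail: int = 10) -> PowerLawFit:
    """Continuous power-law fit with KS-optimal lower cutoff.

    Scans candidate ``x_min`` values over the unique sample values (capped
    at ``max_candidates`` log-spaced picks); for each, the MLE exponent is
    1 + n / sum ln(x/x_min), and the x_min minimising the KS distance of
    the tail wins (ties -> smallest x_min).
    """
    x = np.sort(np.asarray(samples, dtype=float))
    x = x[x > 0]
    if x.size < 50:
        raise ValueError("need at least 50 positive samples")
    uniq = np.unique(x)
    cand = uniq[:-min_tail] if uniq.size > min_tail else uniq[:1]
    if cand.size > max_candidates:
        # log-spaced thinning over the candidate range
        targets = np.geomspace(cand[0], cand[-1], max_candidates)
        idx = np.unique(np.searchsorted(cand, targets))
        idx = idx[idx < cand.size]
        cand = cand[idx]
    best = None
    for xm in cand:
        tail = x[np.searchsorted(x, xm):]
        if tail.size < min_tail:
            continue
        alpha = _mle_exponent(tail, xm)
        if not np.isfinite(alpha):
            continue
        ks = _ks_tail(tail, xm, alpha)
        if best is None or ks < best[0] - 1e-15:
            best = (ks, xm, alpha, tail.size)
    if best is None:
        raise ValueError("power-law fit failed: no viable x_min candidate")
    ks, xm, alpha, n_tail = best
    return PowerLawFit(exponent=float(alpha), x_min=float(xm),
                       ks_distance=ks, n_tail=int(n_tail))


def _trunc_log_norm(delta: float, lo: float, hi: float) -> float:
    # log of int_lo^hi x^-delta dx
    if abs(delta - 1.0) < 1e-9:
        return math.log(math.log(hi / lo))
    a = 1.0 - delta
    val = (hi ** a - lo ** a) / a
    return math.log(val)


def fit_power_law_range(samples: np.ndarray, lo: float, hi: float) -> PowerLawFit:
    """MLE for P(x) ~ x^-delta truncated to [lo, hi].

    The normalisation over the finite range makes any real exponent
    admissible (including delta < 1, impossible for an unbounded tail);
    the 1-D likelihood is maximised numerically.
    """
    if not lo < hi:
        raise ValueError("need lo < hi")
    x = np.asarray(samples, dtype=float)
    x = x[(x >= lo) & (x <= hi)]
    if x.size < 50:
        raise ValueError("need at least 50 samples inside [lo, hi]")
    if np.ptp(x) == 0:
        raise ValueError("degenerate sample: all values equal")
    sum_log = np.log(x).sum()
    n = x.size

    def nll(delta: float) -> float:
        return delta * sum_log + n * _trunc_log_norm(delta, lo, hi)

    res = minimize_scalar(nll, bounds=(-5.0, 20.0), method="bounded",
                          options={"xatol": 1e-8})
    delta = float(res.x)
    xs = np.sort(x)
    ks = _ks_truncated(xs, delta, lo, hi)
    return PowerLawFit(exponent=delta, x_min=float(lo), ks_distance=ks,
                       n_tail=int(n), x_max=float(hi))


def _ks_truncated(xs: np.ndarray, delta: float, lo: float, hi: float) -> float:
    if abs(delta - 1.0) < 1e-9:
        cdf = np.log(xs / lo) / math.log(hi / lo)
    else:
        a = 1.0 - delta
        cdf = (xs ** a - lo ** a) / (hi ** a - lo ** a)
    n = xs.size
    ecdf_hi = np.arange(1, n + 1) / n
    ecdf_lo = np.arange(0, n) / n
    return float(max(np.abs(ecdf_hi - cdf).max(), np.abs(ecdf_lo - cdf).max()))


@dataclass
class CoincidenceTable:
    """Hourly co-coincidence events per unordered user pair.

    ``events[(i, j)]`` holds the sorted distinct hour bins (integer hours
    since the Unix epoch, local or UTC per construction) in which users
    ``user_ids[i]`` and ``user_ids[j]`` were within ``delta_r_m`` metres;
    ``n`` per pair is the length of that list — at most one co-coincidence
    per pair per hour, however many check-ins fell close together.
    """

    user_ids: list
    events: dict[tuple[int, int], np.ndarray]
    delta_r_m: float
    local_hours: bool = True

    @property
    def n_users(self) -> int:
        return len(self.user_ids)

    def counts(self) -> dict[tuple[int, int], int]:
        return {pair: len(t) for pair, t in self.events.items()}


def hour_bins(table: CheckinTable, local: bool = True) -> np.ndarray:
    """Integer hour bin per check-in (hours since epoch), floor-binned.

    ``local=True`` shifts each record by its timezone offset first, so the
    bins are calendar hours of the user's local clock (daily routines are
    local-time phenomena); ``local=False`` bins on UTC.
    """
    t = table.records["utc_time"]
    epoch_s = t.astype("int64") // 10 ** 9
    if local:
        epoch_s = epoch_s + table.records["tz_offset"].to_numpy() * 60
    return (epoch_s // 3600).to_numpy()


def hourly_cocoincidences(table: CheckinTable, delta_r: float,
                          local_hours: bool = True) -> CoincidenceTable:
    """Detect user pairs within ``delta_r`` metres in the same hour bin.

    For every pair of users with check-ins in a common hour bin, that bin
    counts as one co-coincidence iff the minimum pairwise great-circle
    distance between their check-ins in the bin is <= delta_r.
    """
    if delta_r <= 0:
        raise ValueError("delta_r must be positive")
    users = sorted(table.records["user_id"].unique())
    uindex = {u: i for i, u in enumerate(users)}
    if len(table) == 0 or len(users) < 2:
        return CoincidenceTable(users, {}, delta_r, local_hours)
    df = table.records.assign(_bin=hour_bins(table, local=local_hours),
                              _u=table.records["user_id"].map(uindex))
    events: dict[tuple[int, int], list[int]] = {}
    delta_km = delta_r / 1000.0
    for b, grp in df.groupby("_bin", sort=True):
        uids = grp["_u"].to_numpy()
        if np.unique(uids).size < 2:
            continue
        lat = grp["lat"].to_numpy()
        lon = grp["lon"].to_numpy()
        d = haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])
        close = d <= delta_km
        ii, jj = np.nonzero(close)
        pairs = {(int(min(uids[i], uids[j])), int(max(uids[i], uids[j])))
                 for i, j in zip(ii, jj) if uids[i] != uids[j]}
        for p in pairs:
            events.setdefault(p, []).append(int(b))
    return CoincidenceTable(
        users,
        {p: np.asarray(sorted(set(t)), dtype=np.int64) for p, t in events.items()},
        delta_r, local_hours)


def coincidence_frequency(co: CoincidenceTable) -> dict[int, int]:
    """f(n): number of user pairs with exactly n co-coincident hours, n >= 1."""
    freq: dict[int, int] = {}
    for n in (len(t) for t in co.events.values()):
        freq[n] = freq.get(n, 0) + 1
    return dict(sorted(freq.items()))


def cumulative_network(co: CoincidenceTable, c: int, t: float) -> np.ndarray:
    """Adjacency over users: >= c co-coincidences in hour bins <= t.

    ``t`` is an hour bin on the same axis as the table's events; the edge
    set is monotone non-decreasing in t and nested across c.
    """
    if c < 1:
        raise ValueError("threshold c must be >= 1")
    n = co.n_users
    A = np.zeros((n, n), dtype=np.int8)
    for (i, j), bins in co.events.items():
        if np.searchsorted(bins, t, side="right") >= c:
            A[i, j] = A[j, i] = 1
    return A


def temporal_curves(co: CoincidenceTable, c: int,
                    grid: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """<k(t)> and <C(t)> of the cumulative network at each grid time."""
    grid = np.asarray(grid)
    if grid.size and (np.diff(grid) < 0).any():
        raise ValueError("grid must be sorted")
    mean_k = np.empty(grid.size)
    mean_C = np.empty(grid.size)
    for idx, t in enumerate(grid):
        A = cumulative_network(co, c, t)
        mean_k[idx] = average_degree(A)
        mean_C[idx] = clustering(A)[1]
    return mean_k, mean_C


@dataclass(frozen=True)
class NetworkSummary:
    """Largest-connected-component statistics of an encounter network."""

    size: int
    edges: int
    mean_degree: float
    mean_clustering: float
    diameter: int
    mean_distance: float


def largest_component_summary(A: np.ndarray) -> NetworkSummary | None:
    """Summarise the largest connected component (None for an edgeless graph).

    Node count, edge count, <k> = 2E/size, mean clustering (degree-<2
    nodes count 0), diameter and mean shortest-path length <d> — the path
    statistics are well-defined only within a component, hence the
    restriction.
    """
    G = nx.from_numpy_array(np.asarray(A))
    G.remove_nodes_from(list(nx.isolates(G)))
    if G.number_of_edges() == 0:
        return None
    comp = max(nx.connected_components(G), key=len)
    H = G.subgraph(comp)
    size = H.number_of_nodes()
    edges = H.number_of_edges()
    sub = nx.to_numpy_array(H)
    _, mean_C = clustering(sub)
    ecc = nx.eccentricity(H)
    diameter = max(ecc.values())
    mean_d = nx.average_shortest_path_length(H)
    return NetworkSummary(size=size, edges=edges,
                          mean_degree=2.0 * edges / size,
                          mean_clustering=mean_C,
                          diameter=int(diameter),
                          mean_distance=float(mean_d))
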