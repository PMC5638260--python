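"""Synthetic check-in streams with planted heavy-tailed structure.

Generates tables in the same TSV dialect as the public NYC/Tokyo
check-in dump, with the statistical features the empirical pipeline
assumes: Pareto inter-event gaps (planted exponent ``gamma_true``),
truncated-power-law displacement lengths with uniform headings
(``delta_true`` on ``r_range``), a set of shared hotspot venues that
users snap to with probability ``p_hotspot`` (inducing co-coincidences),
and an optional cohort of users with a fixed daily hotspot routine
(inducing repeated, clustered encounters).  A quadratic brute-force
co-coincidence oracle over all check-in pairs validates the pipeline's
binned detector exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import datetime, timedelta, timezone

import numpy as np
import pandas as pd

from .spatial import haversine_km, EARTH_RADIUS_KM
from .checkins import CheckinTable, CoincidenceTable, DEFAULT_COLUMNS, _TIME_FORMAT

_EPOCH = datetime(2012, 4, 12, 0, 0, 0, tzinfo=timezone.utc)  # stream start


@dataclass(frozen=True)
class SyntheticConfig:
    n_users: int = 50
    duration_h: float = 24.0 * 60      # two months of events
    gamma_true: float = 2.5            # inter-event gap exponent, P(tau) ~ tau^-gamma
    tau_floor_h: float = 0.25          # Pareto lower cutoff (hours)
    delta_true: float = 1.5            # displacement exponent on r_range
    r_range_km: tuple[float, float] = (0.001, 10.0)
    n_hotspots: int = 20
    p_hotspot: float = 0.3
    routine_cohort: float = 0.0        # fraction of users on fixed daily schedules
    city_size_km: float = 20.0
    center: tuple[float, float] = (40.75, -74.0)   # (lat, lon) of city centre
    tz_offset_min: int = -240
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.r_range_km
        if not (hi > lo > 0):
            raise ValueError("r_range_km must satisfy 0 < lo < hi")
        if not (self.gamma_true > 1):
            raise ValueError("gamma_true must exceed 1 for a normalisable tail")
        if not (0 <= self.p_hotspot <= 1 and 0 <= self.routine_cohort <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.n_users < 1 or self.duration_h <= 0:
            raise ValueError("need n_users >= 1 and positive duration")


def _pareto(rng: np.random.Generator, gamma: float, floor: float, size: int) -> np.ndarray:
    # inverse CDF of P(x) ~ x^-gamma, x >= floor
    return floor * rng.random(size) ** (-1.0 / (gamma - 1.0))


def _trunc_power(rng: np.random.Generator, delta: float, lo: float, hi: float,
                 size: int) -> np.ndarray:
    a = 1.0 - delta
    u = rng.random(size)
    if abs(a) < 1e-12:
        return lo * (hi / lo) ** u
    return (lo ** a + u * (hi ** a - lo ** a)) ** (1.0 / a)


def _km_to_deg(dlat_km: np.ndarray, dlon_km: np.ndarray, lat_deg: float):
    dlat = dlat_km / (EARTH_RADIUS_KM * math.pi / 180.0)
    dlon = dlon_km / (EARTH_RADIUS_KM * math.pi / 180.0 * math.cos(math.radians(lat_deg)))
    return dlat, dlon


def generate(config: SyntheticConfig) -> CheckinTable:
    """Build a synthetic check-in table per the planted laws of ``config``."""
    rng = np.random.default_rng(config.seed)
    clat, clon = config.center
    half = config.city_size_km / 2.0
    # shared hotspot venues in the city box
    hs_lat_km = rng.uniform(-half, half, config.n_hotspots)
    hs_lon_km = rng.uniform(-half, half, config.n_hotspots)
    hs_dlat, hs_dlon = _km_to_deg(hs_lat_km, hs_lon_km, clat)
    hs_lat = clat + hs_dlat
    hs_lon = clon + hs_dlon
    # each hotspot has a fixed daily hour (a class, a lunch rush): routine
    # users sharing a hotspot therefore meet in the same local hour bin
    hs_hour = rng.integers(8, 20, config.n_hotspots)

    n_routine = int(round(config.routine_cohort * config.n_users))
    rows = []
    for u in range(config.n_users):
        user = f"u{u:05d}"
        routine = u < n_routine
        # home point
        hx, hy = rng.uniform(-half, half, 2)
        dlat, dlon = _km_to_deg(np.array([hx]), np.array([hy]), clat)
        lat, lon = clat + dlat[0], clon + dlon[0]
        if routine:
            schedule_hotspot = int(rng.integers(config.n_hotspots))
            schedule_hour = int(hs_hour[schedule_hotspot])
        t = 0.0
        while True:
            gap = float(_pareto(rng, config.gamma_true, config.tau_floor_h, 1)[0])
            t += gap
            if t > config.duration_h:
                break
            if routine and int(t // 24) != int((t - gap) // 24):
                # once per day, the routine user visits their fixed hotspot
                day = int(t // 24)
                t_routine = day * 24.0 + schedule_hour + rng.uniform(0, 1)
                if t_routine <= config.duration_h:
                    rows.append((user, f"h{schedule_hotspot:04d}", "cat_hotspot",
                                 "Hotspot", hs_lat[schedule_hotspot],
                                 hs_lon[schedule_hotspot], t_routine))
            r = float(_trunc_power(rng, config.delta_true, *config.r_range_km, 1)[0])
            theta = rng.uniform(0, 2 * math.pi)
            dlat, dlon = _km_to_deg(np.array([r * math.sin(theta)]),
                                    np.array([r * math.cos(theta)]), lat)
            lat, lon = lat + dlat[0], lon + dlon[0]
            if rng.random() < config.p_hotspot:
                d = haversine_km(lat, lon, hs_lat, hs_lon)
                k = int(np.argmin(d))
                lat, lon = float(hs_lat[k]), float(hs_lon[k])
                venue, cat = f"h{k:04d}", "Hotspot"
            else:
                venue, cat = f"v{u:05d}_{len(rows)}", "Other"
            rows.append((user, venue, "cat", cat, lat, lon, t))

    rows.sort(key=lambda r: (r[0], r[6]))
    recs = []
    for user, venue, cat_id, cat, lat, lon, t in rows:
        utc = _EPOCH + timedelta(hours=t)
        recs.append({"user_id": user, "venue_id": venue,
                     "venue_category_id": cat_id, "venue_category": cat,
                     "lat": lat, "lon": lon,
                     "tz_offset": config.tz_offset_min,
                     "utc_time": utc})
    df = pd.DataFrame(recs, columns=list(DEFAULT_COLUMNS))
    df["utc_time"] = pd.to_datetime(df["utc_time"], utc=True)
    return CheckinTable(df, 0)


def write_tsv(table: CheckinTable, path) -> None:
    """Serialise in the standard headerless TSV dialect (byte-reproducible)."""
    df = table.records.copy()
    df["utc_time"] = df["utc_time"].dt.strftime(_TIME_FORMAT)
    df["tz_offset"] = df["tz_offset"].astype(int)
    df[list(DEFAULT_COLUMNS)].to_csv(path, sep="\t", header=False, index=False,
                                     float_format="%.8f")


def brute_force_cocoincidence_oracle(table: CheckinTable, delta_r: float,
                                     local_hours: bool = True,
                                     max_rows: int = 10_000) -> CoincidenceTable:
    """Exhaustive all-pairs co-coincidence scan (quadratic; oracle only).

    Applies the identical hour-bin + distance rule as the pipeline
    detector, but by scanning every pair of check-ins directly.
    """
    if len(table) > max_rows:
        raise ValueError(f"oracle guarded to {max_rows} rows (got {len(table)})")
    from .checkins import hour_bins
    users = sorted(table.records["user_id"].unique())
    uindex = {u: i for i, u in enumerate(users)}
    if len(table) == 0:
        return CoincidenceTable(users, {}, delta_r, local_hours)
    bins = hour_bins(table, local=local_hours)
    uid = table.records["user_id"].map(uindex).to_numpy()
    lat = table.records["lat"].to_numpy()
    lon = table.records["lon"].to_numpy()
    events: dict[tuple[int, int], set[int]] = {}
    m = len(table)
    for i in range(m):
        for j in range(i + 1, m):
            if uid[i] == uid[j] or bins[i] != bins[j]:
                continue
            d_m = float(haversine_km(lat[i], lon[i], lat[j], lon[j])) * 1000.0
            if d_m <= delta_r:
                p = (min(uid[i], uid[j]), max(uid[i], uid[j]))
                events.setdefault(p, set()).add(int(bins[i]))
    return CoincidenceTable(
        users,
        {p: np.asarray(sorted(b), dtype=np.int64) for p, b in events.items()},
        delta_r, local_hours)
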