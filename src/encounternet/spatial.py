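"""Fixed spatial substrate: location sets, distance matrices, RGG radius.

The mobility model lives on ``N`` fixed sites (venues, places) with
pairwise distances ``l_ab``.  Sites are either planar points — typically
uniform in the unit square — or (lat, lon) pairs in degrees, in which case
great-circle (haversine) distances on a sphere of radius 6371 km are used.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EARTH_RADIUS_KM = 6371.0

_METRICS = ("euclidean", "manhattan", "haversine")


@dataclass(frozen=True)
class LocationSet:
    """``N`` fixed sites with a distance metric.

    coords has shape (N, 2): planar ``(x, y)`` for euclidean/manhattan,
    or ``(lat, lon)`` in degrees for haversine.
    """

    coords: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2:
            raise ValueError("coords must have shape (N, 2)")
        if coords.shape[0] < 2:
            raise ValueError("a LocationSet needs at least 2 sites")
        if not np.isfinite(coords).all():
            raise ValueError("coordinates must be finite")
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.metric == "haversine":
            lat, lon = coords[:, 0], coords[:, 1]
            if (np.abs(lat) > 90).any() or (np.abs(lon) > 180).any():
                raise ValueError("haversine requires |lat| <= 90, |lon| <= 180")
        object.__setattr__(self, "coords", coords)

    @property
    def n(self) -> int:
        return self.coords.shape[0]


def generate_locations(
    n: int,
    region: tuple[float, float, float, float] = (0.0, 1.0, 0.0, 1.0),
    seed: int | np.random.Generator = 0,
    metric: str = "euclidean",
) -> LocationSet:
    """Draw ``n`` i.i.d. uniform points inside ``region`` = (xmin, xmax, ymin, ymax).

    Reproducible: the same seed yields the same coordinates.
    """
    if n < 2:
        raise ValueError("need n >= 2 locations")
    xmin, xmax, ymin, ymax = region
    if not (xmax > xmin and ymax > ymin):
        raise ValueError("region must have positive area")
    rng = np.random.default_rng(seed)
    pts = np.column_stack(
        [rng.uniform(xmin, xmax, size=n), rng.uniform(ymin, ymax, size=n)]
    )
    return LocationSet(pts, metric=metric)


def haversine_km(lat1, lon1, lat2, lon2) -> np.ndarray:
    """Great-circle distance in km between degree coordinates (broadcasting)."""
    lat1, lon1, lat2, lon2 = (np.radians(np.asarray(x, dtype=float)) for x in (lat1, lon1, lat2, lon2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.minimum(1.0, np.sqrt(h)))


def pairwise_distances(locations: LocationSet) -> np.ndarray:
    """Full symmetric N x N distance matrix ``l_ab`` under the set's metric.

    Units are those of the coordinates (dimensionless for planar metrics,
    km for haversine).  Duplicate points simply give l_ab = 0 off-diagonal.
    """
    c = locations.coords
    if locations.metric == "euclidean":
        d = np.linalg.norm(c[:, None, :] - c[None, :, :], axis=-1)
    elif locations.metric == "manhattan":
        d = np.abs(c[:, None, :] - c[None, :, :]).sum(axis=-1)
    else:
        d = haversine_km(c[:, None, 0], c[:, None, 1], c[None, :, 0], c[None, :, 1])
    # enforce exact symmetry / zero diagonal against round-off
    d = 0.5 * (d + d.T)
    np.fill_diagonal(d, 0.0)
    return d


def rgg_critical_radius(n: int) -> float:
    """Connectivity threshold r_c = sqrt(ln N / (pi N)) for a random
    geometric graph on N uniform points in the unit square.

    A purely local walk (alpha -> infinity) with hop radius R > r_c can
    reach every site with high probability.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    return float(np.sqrt(np.log(n) / (np.pi * n)))


def write_locations_csv(locations: LocationSet, path) -> None:
    header = "id,lat,lon" if locations.metric == "haversine" else "id,x,y"
    rows = np.column_stack([np.arange(locations.n), locations.coords])
    np.savetxt(path, rows, delimiter=",", header=header, comments="",
               fmt=["%d", "%.17g", "%.17g"])


def read_locations_csv(path, metric: str | None = None) -> LocationSet:
    import csv

    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader)
        rows = [(float(r[1]), float(r[2])) for r in reader if r]
    if metric is None:
        metric = "haversine" if header[1].strip().lower() == "lat" else "euclidean"
    return LocationSet(np.asarray(rows), metric=metric)
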