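"""Long-range (Levy-like) transition kernel on a fixed site set.

A discrete-time walker hops between ``N`` sites.  Within a radius ``R`` of
the current site every site is equally likely; beyond ``R`` the affinity
decays as an inverse power of distance:

    Omega_ab = 1            if l_ab <= R
    Omega_ab = (R/l_ab)^a   if l_ab >  R

and the transition probability is the row-normalised affinity,
w_{a->b} = Omega_ab / sum_m Omega_am.  ``alpha`` interpolates between a
uniform jump process (alpha -> 0, every entry 1/N) and purely local motion
(alpha = infinity, affinities exactly 0/1 — the walk on the random
geometric graph of radius R).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class IsolatedSiteError(ValueError):
    """A site has no reachable neighbour (zero affinity row, alpha=inf)."""

    def __init__(self, sites):
        self.sites = list(np.atleast_1d(sites))
        super().__init__(f"isolated site(s) with zero affinity row: {self.sites}")


def affinity_matrix(distances: np.ndarray, alpha: float, radius: float,
                    allow_self: bool = True) -> np.ndarray:
    """Symmetric affinity Omega for exponent ``alpha`` and neighbourhood ``radius``.

    Both limits are represented exactly: ``alpha = math.inf`` zeroes every
    entry beyond the radius (the local RGG walk), and ``alpha = 0`` sets all
    affinities to 1 (the uniform jump process, w = 1/N).  The boundary
    l_ab = R belongs to the neighbourhood (affinity 1).  With ``allow_self``
    (default) the diagonal keeps its l_aa = 0 <= R value of 1, so self-hops
    are permitted; ``allow_self=False`` zeroes it before normalisation.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if alpha < 0:
        raise ValueError("alpha must be nonnegative")
    l = np.asarray(distances, dtype=float)
    far = l > radius
    omega = np.ones_like(l)
    if math.isinf(alpha):
        omega[far] = 0.0
    else:
        with np.errstate(divide="ignore"):
            omega[far] = (radius / l[far]) ** alpha
    if not allow_self:
        np.fill_diagonal(omega, 0.0)
    return omega


def transition_matrix(omega: np.ndarray) -> np.ndarray:
    """Row-stochastic W from the affinity: W_ab = Omega_ab / sum_m Omega_am."""
    omega = np.asarray(omega, dtype=float)
    rowsums = omega.sum(axis=1)
    dead = np.flatnonzero(rowsums <= 0)
    if dead.size:
        raise IsolatedSiteError(dead)
    return omega / rowsums[:, None]


@dataclass(frozen=True)
class LevyKernel:
    """Bundle of (alpha, R) with the affinity and transition matrices."""

    alpha: float
    radius: float
    omega: np.ndarray
    W: np.ndarray

    @classmethod
    def from_distances(cls, distances: np.ndarray, alpha: float, radius: float,
                       allow_self: bool = True) -> "LevyKernel":
        omega = affinity_matrix(distances, alpha, radius, allow_self=allow_self)
        return cls(alpha=alpha, radius=radius, omega=omega,
                   W=transition_matrix(omega))

    @property
    def n(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class TrajectoryEnsemble:
    """Discrete-time site-index sequences; states has shape (walkers, T+1)."""

    states: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        s = np.atleast_2d(np.asarray(self.states))
        object.__setattr__(self, "states", s)

    @property
    def n_walkers(self) -> int:
        return self.states.shape[0]

    @property
    def n_steps(self) -> int:
        return self.states.shape[1] - 1


def _cumulative_rows(W: np.ndarray) -> np.ndarray:
    c = np.cumsum(W, axis=1)
    c[:, -1] = 1.0  # guard against round-off in searchsorted
    return c


def simulate_walk(kernel: LevyKernel, steps: int, start: int | None = None,
                  seed: int | np.random.Generator = 0) -> TrajectoryEnsemble:
    """Single-walker trajectory of ``steps`` transitions (inverse-CDF sampling).

    ``start=None`` draws the initial site uniformly.
    """
    if steps < 1:
        raise ValueError("need at least one step")
    n = kernel.n
    rng = np.random.default_rng(seed)
    if start is None:
        start = int(rng.integers(n))
    if not (0 <= start < n):
        raise ValueError(f"start index {start} outside 0..{n - 1}")
    cum = _cumulative_rows(kernel.W)
    u = rng.random(steps)
    out = np.empty(steps + 1, dtype=np.int64)
    out[0] = start
    site = start
    for t in range(steps):
        site = int(np.searchsorted(cum[site], u[t], side="right"))
        out[t + 1] = site
    return TrajectoryEnsemble(states=out[None, :])


def simulate_walkers(kernel: LevyKernel, n_walkers: int, steps: int,
                     seed: int | np.random.Generator = 0,
                     starts: np.ndarray | None = None) -> TrajectoryEnsemble:
    """Many independent walkers on the same kernel, advanced in lockstep.

    Starts are independently uniform unless given.  Sampling is vectorised
    across walkers per time step; the ensemble is reproducible per seed.
    """
    if steps < 1:
        raise ValueError("need at least one step")
    n = kernel.n
    rng = np.random.default_rng(seed)
    if starts is None:
        starts = rng.integers(n, size=n_walkers)
    states = np.empty((n_walkers, steps + 1), dtype=np.int64)
    states[:, 0] = starts
    cum = _cumulative_rows(kernel.W)
    cur = states[:, 0].copy()
    for t in range(steps):
        u = rng.random(n_walkers)
        rows = cum[cur]
        cur = (rows < u[:, None]).sum(axis=1)
        states[:, t + 1] = cur
    return TrajectoryEnsemble(states=states)


def hop_lengths(trajectory: TrajectoryEnsemble, distances: np.ndarray) -> np.ndarray:
    """Lengths l of every hop (including zero-length self-hops), pooled."""
    s = trajectory.states
    if s.shape[1] < 2:
        raise ValueError("trajectory has no hops")
    return np.asarray(distances)[s[:, :-1], s[:, 1:]].ravel()


def displacement_distribution(trajectory: TrajectoryEnsemble,
                              distances: np.ndarray,
                              bins: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Normalised histogram P(l) of hop lengths over the given bin edges.

    Returns (probability mass per bin, edges); masses sum to 1 over hops
    that fall inside the binned range plus an implicit below-range bucket
    is NOT kept — the histogram is normalised over all hops, so mass can
    be < 1 if hops fall outside the edges.
    """
    l = hop_lengths(trajectory, distances)
    counts, edges = np.histogram(l, bins=bins)
    return counts / l.size, edges


def fit_loglog_slope(prob: np.ndarray, edges: np.ndarray,
                     lo: float, hi: float) -> float:
    """Least-squares slope of log P(l)/binwidth vs log l-midpoint on [lo, hi].

    Used to check the Levy-flight scaling P(l) ~ l^{-(alpha-1)} over the
    intermediate decade of the displacement histogram.
    """
    mids = np.sqrt(edges[:-1] * edges[1:])
    dens = prob / np.diff(edges)
    keep = (mids >= lo) & (mids <= hi) & (dens > 0)
    if keep.sum() < 3:
        raise ValueError("too few populated bins in the fit range")
    slope, _ = np.polyfit(np.log(mids[keep]), np.log(dens[keep]), 1)
    return float(slope)
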