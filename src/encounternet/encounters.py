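"""Temporal encounter networks from co-located random walkers.

Walkers move independently on the same site set; an encounter is two
walkers occupying the same site at the same discrete step.  Each walker
remembers encounters over the last ``M`` steps, and an (undirected,
unweighted) link i--j exists at time t when the half-open window
(t - M, t] holds at least ``c`` encounters of the pair.  With M = inf the
rule degenerates to the cumulative "at least c encounters in [0, t]"
construction used for empirical check-in data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kernel import LevyKernel, TrajectoryEnsemble, simulate_walkers
from .spatial import generate_locations, pairwise_distances


@dataclass(frozen=True)
class EncounterConfig:
    memory: float = math.inf      # M, steps (math.inf = cumulative)
    min_contacts: int = 1         # c
    n_walkers: int = 2

    def __post_init__(self) -> None:
        if self.memory < 1:
            raise ValueError("memory M must be >= 1")
        if self.min_contacts < 1:
            raise ValueError("min contact count c must be >= 1")


def coincidence_events(trajectories: TrajectoryEnsemble) -> dict[tuple[int, int], np.ndarray]:
    """Per unordered walker pair (i < j): sorted array of encounter times.

    Pairs that never meet are omitted from the mapping.
    """
    s = trajectories.states
    n_w, n_t = s.shape
    events: dict[tuple[int, int], list[int]] = {}
    # bucket walkers by site per time step; only co-bucketed walkers can meet
    for t in range(n_t):
        col = s[:, t]
        order = np.argsort(col, kind="stable")
        sites = col[order]
        cuts = np.flatnonzero(np.diff(sites)) + 1
        for group in np.split(order, cuts):
            if group.size < 2:
                continue
            g = np.sort(group)
            for a in range(g.size - 1):
                for b in range(a + 1, g.size):
                    events.setdefault((int(g[a]), int(g[b])), []).append(t)
    return {k: np.asarray(v, dtype=np.int64) for k, v in events.items()}


def adjacency_at(events: dict[tuple[int, int], np.ndarray],
                 config: EncounterConfig, t: float) -> np.ndarray:
    """Binary symmetric adjacency A(t): window (t - M, t] holds >= c encounters."""
    n = config.n_walkers
    A = np.zeros((n, n), dtype=np.int8)
    if t < 0:
        return A
    lo = t - config.memory
    for (i, j), times in events.items():
        # count encounters with lo < time <= t
        k = np.searchsorted(times, t, side="right") - np.searchsorted(times, lo, side="right")
        if k >= config.min_contacts:
            A[i, j] = A[j, i] = 1
    return A


def average_degree(A: np.ndarray) -> float:
    """<k> = (1/N) sum_ij A_ij = 2 E / N."""
    A = np.asarray(A)
    return float(A.sum() / A.shape[0])


def clustering(A: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node clustering C_i = (A^3)_ii / (k_i (k_i - 1)) and the mean <C>.

    Nodes with degree < 2 get C_i = 0.  Returns (C vector, mean over all
    nodes).
    """
    A = np.asarray(A, dtype=float)
    k = A.sum(axis=1)
    tri = ((A @ A) * A).sum(axis=1)  # (A^3)_ii = 2 * triangles at i
    denom = k * (k - 1)
    C = np.where(denom > 0, np.divide(tri, denom, out=np.zeros_like(tri), where=denom > 0), 0.0)
    return C, float(C.mean())


def degree_distribution(A: np.ndarray) -> np.ndarray:
    """Normalised degree histogram P(k) over k = 0 .. N-1."""
    A = np.asarray(A)
    n = A.shape[0]
    k = A.sum(axis=1).astype(int)
    return np.bincount(k, minlength=n) / n


def _window_metric_series(states: np.ndarray, memory: float, c: int,
                          times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """<k(t)> and <C(t)> for one realization, via a sliding encounter count.

    Maintains the per-pair encounter count over the active window
    incrementally: add step t, drop step t - M.
    """
    n_w, n_t = states.shape
    counts = np.zeros((n_w, n_w), dtype=np.int32)
    per_step_pairs: list[np.ndarray] = []
    mean_k = np.empty(times.size)
    mean_C = np.empty(times.size)
    out_idx = 0
    times = np.asarray(times)
    for t in range(n_t):
        pairs = _pairs_at(states[:, t])
        per_step_pairs.append(pairs)
        if pairs.size:
            counts[pairs[:, 0], pairs[:, 1]] += 1
        drop = t - memory  # encounters at exactly t - M leave the window (t-M, t]
        if drop >= 0 and not math.isinf(memory):
            old = per_step_pairs[int(drop)]
            if old.size:
                counts[old[:, 0], old[:, 1]] -= 1
        while out_idx < times.size and times[out_idx] == t:
            A = (counts >= c)
            A = (A | A.T).astype(float)
            mean_k[out_idx] = average_degree(A)
            mean_C[out_idx] = clustering(A)[1]
            out_idx += 1
    if out_idx != times.size:
        raise ValueError("requested times outside the simulated range")
    return mean_k, mean_C


def _pairs_at(col: np.ndarray) -> np.ndarray:
    """Unordered (i<j) walker pairs sharing a site in one time slice."""
    order = np.argsort(col, kind="stable")
    sites = col[order]
    cuts = np.flatnonzero(np.diff(sites)) + 1
    out = []
    for group in np.split(order, cuts):
        if group.size < 2:
            continue
        g = np.sort(group)
        iu, ju = np.triu_indices(g.size, k=1)
        out.append(np.column_stack([g[iu], g[ju]]))
    if not out:
        return np.empty((0, 2), dtype=np.int64)
    return np.concatenate(out)


def ensemble_curves(kernel: LevyKernel, config: EncounterConfig, steps: int,
                    realizations: int = 10, seed: int = 0,
                    times: np.ndarray | None = None,
                    return_final_degrees: bool = False,
                    return_per_realization: bool = False):
    """Ensemble-averaged <k(t)> and <C(t)> over independent realizations.

    Each realization draws fresh uniform starts and trajectories for
    ``config.n_walkers`` walkers; the metric (not the adjacency) is
    averaged across realizations at each requested time.  Optionally also
    returns the pooled final-time degree sequence across realizations
    (for P(k) in the stationary regime) and/or the per-realization curve
    matrices of shape (realizations, len(times)) — realizations are the
    independent replicates for any statistical statement about the curves.
    """
    if realizations < 1:
        raise ValueError("need at least one realization")
    if times is None:
        times = np.arange(steps + 1)
    times = np.asarray(times)
    ss = np.random.SeedSequence(seed)
    kk = np.empty((realizations, times.size))
    cc = np.empty((realizations, times.size))
    final_degrees = []
    for r, child in enumerate(ss.spawn(realizations)):
        sub = np.random.default_rng(child)
        traj = simulate_walkers(kernel, config.n_walkers, steps, seed=sub)
        kk[r], cc[r] = _window_metric_series(traj.states, config.memory,
                                             config.min_contacts, times)
        if return_final_degrees:
            ev = coincidence_events(traj)
            A = adjacency_at(ev, config, steps)
            final_degrees.append(A.sum(axis=1))
    out = [times, kk.mean(axis=0), cc.mean(axis=0)]
    if return_final_degrees:
        out.append(np.concatenate(final_degrees))
    if return_per_realization:
        out.extend([kk, cc])
    return tuple(out)


def ensemble_curves_random_geometry(n_sites: int, alpha: float, radius: float,
                                    config: EncounterConfig, steps: int,
                                    realizations: int = 10, seed: int = 0):
    """Like :func:`ensemble_curves`, but each realization also redraws the
    location set (uniform in the unit square).

    A "realization of the system" then includes the geometry, so
    statistics across realizations reflect both walker noise and spatial
    disorder.  Returns (times, mean_k, mean_C, per-realization k matrix,
    per-realization C matrix).
    """
    times = np.arange(steps + 1)
    kk = np.empty((realizations, times.size))
    cc = np.empty((realizations, times.size))
    ss = np.random.SeedSequence(seed)
    for r, child in enumerate(ss.spawn(realizations)):
        rng = np.random.default_rng(child)
        loc = generate_locations(n_sites, seed=rng)
        kern = LevyKernel.from_distances(pairwise_distances(loc), alpha, radius)
        traj = simulate_walkers(kern, config.n_walkers, steps, seed=rng)
        kk[r], cc[r] = _window_metric_series(traj.states, config.memory,
                                             config.min_contacts, times)
    return times, kk.mean(axis=0), cc.mean(axis=0), kk, cc
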