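"""Exact Markov-chain analysis of the long-range kernel.

Because the affinity Omega is symmetric, the walk is reversible: with
D = diag(s), s_a = sum_b Omega_ab, the operator D^{1/2} W D^{-1/2} is
symmetric, all eigenvalues are real, and the stationary distribution has
the closed form p_b = s_b / sum s.  The eigendecomposition of the
symmetrised operator yields the right eigenvector matrix Z (columns
|phi_m>) and its inverse (rows <phibar_m|) without a general matrix
inverse, and from these the mean first-passage times:

    T(b -> a) = (1/p_a) * sum_{m>=2} (1 - lambda_m)^{-1}
                * (Z_{am} Zinv_{ma} - Z_{bm} Zinv_{ma})

The per-site reach time tau_a averages T(b -> a) over a uniformly random
start b, counting 0 when b = a; the global time tau averages tau_a over
all sites and measures how fast the strategy (alpha, R) covers the
location set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kernel import LevyKernel


class NotIrreducibleError(ValueError):
    pass


def evolve_distribution(kernel: LevyKernel, p0: np.ndarray, steps: int) -> np.ndarray:
    """Apply the master equation p(t+1) = p(t) W ``steps`` times."""
    p = np.asarray(p0, dtype=float)
    if p.shape != (kernel.n,) or abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
        raise ValueError("p0 must be a length-N probability vector")
    for _ in range(steps):
        p = p @ kernel.W
    return p


def stationary_distribution(kernel: LevyKernel) -> np.ndarray:
    """Closed-form stationary distribution p_b = sum_l Omega_bl / sum_lm Omega_lm."""
    s = kernel.omega.sum(axis=1)
    total = s.sum()
    if (s <= 0).any():
        raise NotIrreducibleError("zero affinity row: chain not irreducible")
    return s / total


def mean_return_time(stationary: np.ndarray) -> np.ndarray:
    """Kac's formula: mean first-return time <T_a> = 1 / p_a."""
    p = np.asarray(stationary, dtype=float)
    if (p <= 0).any():
        raise ZeroDivisionError("stationary distribution has a zero entry (reducible chain)")
    return 1.0 / p


@dataclass(frozen=True)
class SpectralSolution:
    """Eigenstructure of W plus derived passage-time quantities."""

    eigenvalues: np.ndarray      # descending, lambda_1 = 1
    Z: np.ndarray                # right eigenvectors as columns
    Zinv: np.ndarray             # dual (left) eigenvectors as rows
    stationary: np.ndarray
    tau_per_site: np.ndarray
    tau_global: float


def _eigendecompose(kernel: LevyKernel):
    s = kernel.omega.sum(axis=1)
    if (s <= 0).any():
        raise NotIrreducibleError("zero affinity row")
    d_half = np.sqrt(s)
    # symmetrised operator S = D^{-1/2} Omega D^{-1/2} shares W's spectrum
    S = kernel.omega / np.outer(d_half, d_half)
    lam, V = np.linalg.eigh(S)           # ascending, V orthonormal
    order = np.argsort(lam)[::-1]
    lam = lam[order]
    V = V[:, order]
    Z = V / d_half[:, None]              # right eigenvectors of W
    Zinv = V.T * d_half[None, :]         # rows are left eigenvectors
    return lam, Z, Zinv


def solve(kernel: LevyKernel) -> SpectralSolution:
    """Full spectral solution: spectrum, stationary law, reach times."""
    lam, Z, Zinv = _eigendecompose(kernel)
    if lam.size > 1 and lam[1] > 1.0 - 1e-10:
        raise NotIrreducibleError("eigenvalue 1 has multiplicity > 1 (disconnected kernel)")
    p = stationary_distribution(kernel)
    tau = _reach_times(lam, Z, Zinv, p)
    return SpectralSolution(eigenvalues=lam, Z=Z, Zinv=Zinv, stationary=p,
                            tau_per_site=tau, tau_global=float(tau.mean()))


def _reach_times(lam, Z, Zinv, p) -> np.ndarray:
    n = lam.size
    inv_gap = 1.0 / (1.0 - lam[1:])                      # modes m = 2..N
    # diag part: sum_m Z_{am} Zinv_{ma} / (1 - lambda_m)
    diag_part = np.einsum("am,ma,m->a", Z[:, 1:], Zinv[1:, :], inv_gap)
    # uniform-start part: (1/N) sum_b Z_{bm}
    colmean = Z[:, 1:].mean(axis=0)
    start_part = np.einsum("m,ma,m->a", colmean, Zinv[1:, :], inv_gap)
    return (diag_part - start_part) / p


def first_passage_matrix(spec: SpectralSolution) -> np.ndarray:
    """Mean first-passage times T[b, a] from site b to site a (0 on diagonal)."""
    lam, Z, Zinv, p = spec.eigenvalues, spec.Z, spec.Zinv, spec.stationary
    inv_gap = 1.0 / (1.0 - lam[1:])
    moment = np.einsum("am,ma,m->a", Z[:, 1:], Zinv[1:, :], inv_gap)
    cross = np.einsum("bm,ma,m->ba", Z[:, 1:], Zinv[1:, :], inv_gap)
    return (moment[None, :] - cross) / p[None, :]


def reach_time_per_site(spec: SpectralSolution, site: int | None = None):
    """tau_a: mean steps to first reach ``site`` from a uniform random start.

    A start already at the target counts 0 steps.  With ``site=None`` the
    full length-N vector is returned.
    """
    if site is None:
        return spec.tau_per_site
    return float(spec.tau_per_site[site])


def global_time(spec: SpectralSolution) -> float:
    """tau = (1/N) sum_a tau_a, the strategy's global coverage time."""
    return spec.tau_global


def mc_first_passage_oracle(kernel: LevyKernel, target: int, repeats: int = 10_000,
                            seed: int | np.random.Generator = 0,
                            max_steps: int = 1_000_000) -> tuple[float, float]:
    """Monte Carlo estimate of tau_target: (mean steps, standard error).

    Starts are uniform over sites; a start equal to the target counts as
    time 0.  All repeats advance in lockstep (vectorised); chains that
    exceed ``max_steps`` raise rather than truncate the mean.
    """
    if repeats < 100:
        raise ValueError("need at least 100 repeats")
    n = kernel.n
    rng = np.random.default_rng(seed)
    cum = np.cumsum(kernel.W, axis=1)
    cum[:, -1] = 1.0
    states = rng.integers(n, size=repeats)
    times = np.zeros(repeats, dtype=np.int64)
    active = states != target
    step = 0
    while active.any():
        step += 1
        if step > max_steps:
            raise RuntimeError(f"first passage to site {target} exceeded {max_steps} steps")
        idx = np.flatnonzero(active)
        u = rng.random(idx.size)
        nxt = (cum[states[idx]] < u[:, None]).sum(axis=1)
        states[idx] = nxt
        arrived = nxt == target
        times[idx] = step  # overwritten while still active; final write is arrival time
        still = idx[~arrived]
        active[:] = False
        active[still] = True
    mean = float(times.mean())
    se = float(times.std(ddof=1) / np.sqrt(repeats))
    return mean, se
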