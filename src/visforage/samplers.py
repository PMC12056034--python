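"""Lightweight MCMC: coordinate-wise slice sampling on unconstrained parameters.

All models in this package are low-dimensional (2-45 free parameters), with
cheap, vectorizable log posteriors; Neal's (2003) slice sampler with
stepping-out and shrinkage, applied coordinate-wise (Gibbs scan) on
transformed (unconstrained) parameters, mixes well on them without needing
gradients.  Multiple chains from over-dispersed starts feed split-R-hat and
effective-sample-size diagnostics (via arviz).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import arviz as az
import numpy as np


class ConvergenceError(RuntimeError):
    """Raised when split-R-hat exceeds the acceptance threshold."""


def slice_sample_coord(
    logp: Callable[[np.ndarray], float],
    x: np.ndarray,
    i: int,
    logp_x: float,
    rng: np.random.Generator,
    w: float = 1.0,
    max_steps: int = 50,
) -> tuple[np.ndarray, float]:
    """One slice-sampling update of coordinate ``i`` of ``x``.

    Stepping-out with typical width ``w`` followed by shrinkage; returns the
    updated vector and its log density.
    """
    y = logp_x + np.log(rng.random())
    xi = x[i]
    u = rng.random()
    lo, hi = xi - w * u, xi + w * (1.0 - u)

    def f(v: float) -> float:
        x[i] = v
        return logp(x)

    j = int(rng.integers(0, max_steps + 1))
    k = max_steps - j
    while j > 0 and f(lo) > y:
        lo -= w
        j -= 1
    while k > 0 and f(hi) > y:
        hi += w
        k -= 1

    while True:
        v = rng.uniform(lo, hi)
        lv = f(v)
        if lv > y:
            return x, lv
        if v < xi:
            lo = v
        else:
            hi = v
        if hi - lo < 1e-12:  # numerical corner: degenerate slice
            x[i] = xi
            return x, logp(x)


@dataclass
class ChainResult:
    """Post-warm-up draws with shape (chains, draws, dim)."""

    draws: np.ndarray
    param_names: list[str]

    def stacked(self, name: str) -> np.ndarray:
        return self.draws[..., self.param_names.index(name)]


def run_slice_chains(
    logp: Callable[[np.ndarray], float],
    init: Callable[[np.random.Generator], np.ndarray],
    dim: int,
    param_names: list[str],
    seed,
    chains: int = 4,
    warmup: int = 1000,
    draws: int = 1000,
    widths: np.ndarray | float = 1.0,
    thin: int = 1,
) -> ChainResult:
    """Run independent slice-within-Gibbs chains on the unconstrained space.

    ``init`` draws an over-dispersed starting point per chain.  Warm-up runs
    in two phases: coordinate-wise scans with step widths adapted from the
    running spread, then a principal-axis rotation estimated from the warm-up
    covariance so that subsequent scans slice along the posterior's main
    correlation directions (essential for strongly coupled hierarchies).
    """
    master = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    streams = master.spawn(chains)
    w = np.full(dim, widths, dtype=float) if np.isscalar(widths) else np.asarray(widths, float).copy()

    all_draws = np.empty((chains, draws, dim))
    for c, stream in enumerate(streams):
        rng = np.random.default_rng(stream)
        x = np.asarray(init(rng), dtype=float).copy()
        lp = logp(x)
        if not np.isfinite(lp):
            raise ValueError("initial point has non-finite log density")

        # phase 1: axis-aligned scans with running width adaptation
        n1 = warmup // 2
        wc = w.copy()
        hist = np.empty((n1, dim))
        for t in range(n1):
            for i in range(dim):
                x, lp = slice_sample_coord(logp, x, i, lp, rng, wc[i])
            hist[t] = x
            if t + 1 in (n1 // 4, n1 // 2, 3 * n1 // 4):
                spread = hist[: t + 1].std(axis=0)
                wc = np.where(spread > 1e-8, 2.5 * spread, wc)

        # principal-axis rotation from the second half of phase-1 history
        seg = hist[n1 // 2 :] if n1 >= 8 else hist
        cov = np.cov(seg.T) if dim > 1 else np.atleast_2d(np.var(seg))
        cov = np.atleast_2d(cov) + 1e-10 * np.eye(dim)
        evals, evecs = np.linalg.eigh(cov)
        evals = np.clip(evals, 1e-12, None)
        basis = evecs * np.sqrt(evals)  # x = basis @ u, u approximately unit scale

        def logp_u(u: np.ndarray) -> float:
            return logp(basis @ u)

        u = np.linalg.solve(basis, x)
        lpu = logp_u(u)
        wu = np.full(dim, 2.5)

        # phase 2: finish warm-up in the rotated basis
        for _ in range(warmup - n1):
            for i in range(dim):
                u, lpu = slice_sample_coord(logp_u, u, i, lpu, rng, wu[i])
        for t in range(draws):
            for _ in range(thin):
                for i in range(dim):
                    u, lpu = slice_sample_coord(logp_u, u, i, lpu, rng, wu[i])
            all_draws[c, t] = basis @ u
    return ChainResult(draws=all_draws, param_names=list(param_names))


def diagnostics(draws_2d: np.ndarray) -> tuple[float, float]:
    """(split-R-hat, bulk ESS) for one parameter's (chains, draws) array."""
    data = az.convert_to_dataset(np.asarray(draws_2d))
    rhat = float(az.rhat(data)["x"].values)
    ess = float(az.ess(data)["x"].values)
    return rhat, ess


def check_convergence(draws_2d: np.ndarray, name: str, threshold: float = 1.01) -> tuple[float, float]:
    """Diagnostics for one parameter; raises ConvergenceError above threshold."""
    rhat, ess = diagnostics(draws_2d)
    if rhat >= threshold:
        raise ConvergenceError(
            f"parameter {name!r}: split-R-hat {rhat:.3f} >= {threshold}; "
            "increase draws/warmup or reparameterize"
        )
    return rhat, ess


# transforms between constrained and unconstrained spaces ---------------------


def logit(p: np.ndarray | float) -> np.ndarray | float:
    return np.log(p) - np.log1p(-p)


def expit(x: np.ndarray | float) -> np.ndarray | float:
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def log_jac_expit(x: np.ndarray | float) -> np.ndarray | float:
    """log |d expit(x) / dx| = log p + log(1-p)."""
    x = np.asarray(x, dtype=float)
    return -np.logaddexp(0.0, x) - np.logaddexp(0.0, -x)
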