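"""L1-regularized decomposition of AN responses by iterative soft-thresholding.

The solver iterates

    h_{k+1} = soft( h_k + (1/alpha) * Dᵀ(v - D h_k),  lam / (2*alpha) )

from h_0 = 0, where soft(x, t) = sign(x) * max(0, |x| - t) and alpha is (an
upper bound on) the top eigenvalue of DᵀD.  With threshold lam/(2*alpha) the
fixed point minimises

    0.5 * ||v - D h||^2  +  (lam / 2) * ||h||_1,

which is the objective all convergence checks and oracles in this package
use.  With lam = 0 the iteration is plain gradient descent to a least-squares
solution and stopping switches to a relative gradient-norm criterion.

Negative coefficients are clamped to zero on exit (atom weights are
nonnegative by construction); an optional one-sided mode applies
max(0, x - t) throughout instead.  Phase groups are collapsed by summation.

The inner loop runs on the Gram matrix G = DᵀD (precomputed once per
dictionary): the update h + (1/alpha)(c - G h) with c = Dᵀv is algebraically
identical to the direct form but costs O(M^2) instead of O(rows * M).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .dictionary import Dictionary

log = logging.getLogger(__name__)


def soft_threshold(x, t):
    """Elementwise shrinkage sign(x) * max(0, |x| - t)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be nonnegative")
    x = np.asarray(x)
    return np.sign(x) * np.maximum(0.0, np.abs(x) - t)


def estimate_step(D: np.ndarray | Dictionary, n_iter: int = 200) -> float:
    """Power-iteration estimate of max eig(DᵀD), inflated by 1.05."""
    G = D.gram if isinstance(D, Dictionary) else np.asarray(D).T @ np.asarray(D)
    if G.size == 0:
        raise ValueError("empty dictionary")
    v = np.ones(G.shape[0]) / np.sqrt(G.shape[0])
    lam_prev = 0.0
    for _ in range(n_iter):
        w = G @ v
        lam = float(v @ w)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 1.05 * 0.0
        v = w / nrm
        if abs(lam - lam_prev) <= 1e-12 * max(lam, 1.0):
            break
        lam_prev = lam
    return 1.05 * lam


@dataclass(frozen=True)
class SolverConfig:
    lam: float = 0.01
    max_iter: int = 5000
    tol: float = 1e-6
    alpha: float | str = "auto"
    one_sided: bool = False
    record_trace: bool = False

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")


@dataclass
class SparseCode:
    """Result of a solve: group-resolved and collapsed coefficients."""

    h_grouped: np.ndarray  # (g*M,) nonnegative after exit clamp
    h: np.ndarray  # (M,) group-summed
    objective: float  # 0.5||v-Dh||^2 + (lam/2)||h||_1 at the signed iterate
    n_iter: int
    converged: bool
    trace: np.ndarray | None = None


def collapse_groups(h_grouped: np.ndarray, n_groups: int) -> np.ndarray:
    """Sum the g contiguous entries of every frequency group."""
    h_grouped = np.asarray(h_grouped)
    if h_grouped.size % n_groups:
        raise ValueError("length not divisible by group count")
    return h_grouped.reshape(-1, n_groups).sum(axis=1)


def solve(
    v: np.ndarray,
    D: np.ndarray | Dictionary,
    config: SolverConfig | None = None,
) -> SparseCode:
    """ISTA solve of the L1 reconstruction of ``v`` over dictionary ``D``."""
    config = config or SolverConfig()
    if isinstance(D, Dictionary):
        G, n_groups = D.gram, D.n_groups
        c = D.project(v)
        if len(v) != D.matrix.shape[0]:
            raise ValueError("v length does not match dictionary rows")
    else:
        D = np.asarray(D)
        if len(v) != D.shape[0]:
            raise ValueError("v length does not match dictionary rows")
        G, n_groups = D.T @ D, 1
        c = D.T @ v
    vv = float(v @ v)

    alpha = estimate_step_from_gram(G) if config.alpha == "auto" else float(config.alpha)
    if alpha <= 0:
        # degenerate (all-zero) dictionary; nothing to fit
        z = np.zeros(G.shape[0])
        return SparseCode(z, collapse_groups(z, n_groups), 0.5 * vv, 0, True)
    thr = config.lam / (2.0 * alpha)

    m = G.shape[0]
    h = np.zeros(m)
    Gh = np.zeros(m)
    obj_prev = 0.5 * vv
    trace = [obj_prev] if config.record_trace else None
    converged = False
    n_done = 0
    for it in range(1, config.max_iter + 1):
        grad = c - Gh
        if config.one_sided:
            h_new = np.maximum(0.0, h + grad / alpha - thr)
        else:
            h_new = soft_threshold(h + grad / alpha, thr)
        Gh = G @ h_new
        obj = 0.5 * (vv - 2.0 * (h_new @ c) + h_new @ Gh) \
            + 0.5 * config.lam * np.abs(h_new).sum()
        if trace is not None:
            trace.append(obj)
        if it % 50 == 0 and obj > obj_prev + 1e-9 * max(abs(obj_prev), 1.0):
            log.warning("objective increased at iteration %d (%.3e -> %.3e); "
                        "step size may be too small", it, obj_prev, obj)
        h, n_done = h_new, it
        if config.lam == 0.0:
            gnorm = np.linalg.norm(c - Gh)
            if gnorm <= config.tol * max(np.linalg.norm(c), 1e-30):
                converged = True
                break
        else:
            if abs(obj_prev - obj) <= config.tol * max(abs(obj_prev), 1e-30):
                converged = True
                break
        obj_prev = obj

    if not converged:
        log.info("ISTA did not reach tol within %d iterations", config.max_iter)
    h_clamped = np.maximum(h, 0.0)
    return SparseCode(
        h_grouped=h_clamped,
        h=collapse_groups(h_clamped, n_groups),
        objective=float(obj_prev if n_done == 0 else obj),
        n_iter=n_done,
        converged=converged,
        trace=np.asarray(trace) if trace is not None else None,
    )


def estimate_step_from_gram(G: np.ndarray) -> float:
    """Power iteration directly on a precomputed Gram matrix."""
    v = np.ones(G.shape[0]) / np.sqrt(G.shape[0])
    lam_prev = 0.0
    lam = 0.0
    for _ in range(200):
        w = G @ v
        lam = float(v @ w)
        nrm = np.linalg.norm(w)
        if nrm == 0:
            return 0.0
        v = w / nrm
        if abs(lam - lam_prev) <= 1e-12 * max(lam, 1.0):
            break
        lam_prev = lam
    return 1.05 * lam


def write_trace(code: SparseCode, path) -> None:
    """Dump the per-iteration objective to CSV for diagnostics."""
    if code.trace is None:
        raise ValueError("solver was run without record_trace")
    import pandas as pd

    pd.DataFrame({"iteration": np.arange(len(code.trace)),
                  "objective": code.trace}).to_csv(path, index=False)
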