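"""Entropic (optionally unbalanced) Sinkhorn optimal transport.

Used to couple cell populations of adjacent sampling stages: the source
marginal carries each cell's growth rate (proliferating cells export more
mass), the target marginal is uniform, and after each of ``growth_iters``
solves the growth rates are re-estimated from the transported mass and the
problem re-solved.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial.distance import cdist


def sinkhorn(C: np.ndarray, p: np.ndarray, q: np.ndarray, eps: float,
             lam: float | None = None, max_iter: int = 5000,
             tol: float = 1e-9) -> np.ndarray:
    """Entropic OT coupling with exact target marginal.

    ``lam=None`` enforces the source marginal exactly (balanced transport);
    a finite ``lam`` applies a KL penalty of strength lam on the source
    marginal instead (unbalanced source), with the usual damped scaling
    exponent ``lam / (lam + eps)``.

    Raises on non-convergence, reporting the marginal residual.
    """
    from scipy.special import logsumexp

    C = np.asarray(C, dtype=float)
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if eps <= 0:
        raise ValueError("eps must be positive")
    # log-domain scaling iterations (stable for small eps)
    logp = np.log(np.maximum(p, 1e-300))
    logq = np.log(np.maximum(q, 1e-300))
    f = np.zeros(len(p))
    g = np.zeros(len(q))
    fi = 1.0 if lam is None else lam / (lam + eps)
    M = -C / eps
    for it in range(max_iter):
        f_prev = f
        f = fi * eps * (logp - logsumexp(M + g[None, :] / eps, axis=1))
        g = eps * (logq - logsumexp(M + f[:, None] / eps, axis=0))
        if it % 10 == 0:
            if lam is None:
                row = np.exp(logsumexp(M + f[:, None] / eps + g[None, :] / eps,
                                       axis=1))
                err = np.abs(row - p).sum()
            else:
                err = np.abs(f - f_prev).max() / max(1.0, np.abs(f).max())
            if err < tol:
                break
    else:
        row = np.exp(logsumexp(M + f[:, None] / eps + g[None, :] / eps, axis=1))
        res = np.abs(row - p).sum()
        raise RuntimeError(f"Sinkhorn did not converge; marginal residual {res:.3g}")
    return np.exp(M + f[:, None] / eps + g[None, :] / eps)


def ot_coupling(source_emb: np.ndarray, target_emb: np.ndarray, g: np.ndarray,
                eps: float | None = None, lam: float | None = 1.0,
                growth_iters: int = 3, dt: float = 1.0):
    """Growth-aware entropic coupling between two stages.

    Cost is squared Euclidean distance in the shared embedding; the source
    marginal is proportional to ``g**dt``, the target marginal uniform.
    After each solve the growth estimate is updated from each source cell's
    transported mass (relative to uniform) and the problem re-solved, for
    ``growth_iters`` rounds.  Returns ``(gamma, g_final)``.
    """
    S = np.atleast_2d(np.asarray(source_emb, dtype=float))
    T = np.atleast_2d(np.asarray(target_emb, dtype=float))
    if len(S) == 0 or len(T) == 0:
        raise ValueError("both stages must be non-empty")
    C = cdist(S, T, metric="sqeuclidean")
    if eps is None:
        eps = 0.05 * C.mean() if C.mean() > 0 else 0.05
    g = np.asarray(g, dtype=float).copy()
    for _ in range(max(1, int(growth_iters))):
        p = g ** dt
        p = p / p.sum()
        q = np.full(len(T), 1.0 / len(T))
        gamma = sinkhorn(C, p, q, eps=eps, lam=lam)
        mass = gamma.sum(axis=1)
        g = mass * len(S)          # relative growth: transported vs uniform mass
        g = np.maximum(g, 1e-12)
    return gamma, g
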