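"""Structured-sparsity proximal operators and the HSIC dependence estimator.

The decoder weight matrix is regularised by a column-wise group lasso
(deactivates whole programs) plus a masked L1 on non-member genes
(soft membership).  Because the penalty is separable over columns, the
joint proximal operator factorises column by column, and within a column
the masked soft-threshold composed with group-lasso shrinkage equals the
joint prox.  All operators here are closed-form and exact (they produce
bitwise zeros, which is what makes "program deactivated" a crisp event).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .gene_sets import GPMask, ROLE_HARD, ROLE_SOFT, ROLE_UNCONSTRAINED

#: column role used for query-time constrained additions (soft mask, own L1 strength)
ROLE_NEW_CONSTRAINED = "new_constrained_soft"
#: column role used for query-time free additions (plain L1, no group lasso)
ROLE_NEW_UNCONSTRAINED = "new_unconstrained"

_ROLE_ALIASES = {
    ROLE_HARD: ROLE_HARD,
    ROLE_SOFT: ROLE_SOFT,
    ROLE_UNCONSTRAINED: ROLE_SOFT,  # sparse column = soft column with all-one mask
    ROLE_NEW_UNCONSTRAINED: ROLE_NEW_UNCONSTRAINED,
    ROLE_NEW_CONSTRAINED: ROLE_NEW_CONSTRAINED,
}


@dataclass
class ProxConfig:
    """Strengths of the structured penalties.

    alpha     — group lasso on curated columns (program deactivation);
    gamma     — masked L1 on soft-membership columns;
    gamma_ext — plain L1 on new unconstrained columns added at query time;
    alpha_l1  — masked L1 on new constrained (soft) columns;
    eta       — learning rate entering every threshold (prox of eta*R).
    """

    alpha: float = 0.7
    gamma: float = 0.7
    gamma_ext: float = 0.7
    alpha_l1: float = 0.7
    eta: float = 1.0

    def __post_init__(self):
        for name in ("alpha", "gamma", "gamma_ext", "alpha_l1"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.eta <= 0:
            raise ValueError("eta must be positive")


def l1_prox(v: np.ndarray, t: float) -> np.ndarray:
    """Elementwise soft-threshold: argmin_l 0.5*||l - v||^2 + t*||l||_1."""
    if t < 0:
        raise ValueError("threshold must be non-negative")
    v = np.asarray(v, dtype=float)
    # "+ 0.0" canonicalises -0.0 so exact zeros are bitwise reproducible
    return np.sign(v) * np.maximum(np.abs(v) - t, 0.0) + 0.0


def group_lasso_prox(v: np.ndarray, t: float) -> np.ndarray:
    """Block soft-threshold: argmin_l 0.5*||l - v||^2 + t*||l||_2.

    Shrinks the whole vector toward zero and returns the exact zero vector
    when ||v||_2 <= t — the mechanism that switches programs off.
    """
    if t < 0:
        raise ValueError("threshold must be non-negative")
    v = np.asarray(v, dtype=float)
    if t == 0.0:
        return v.copy()
    norm = np.linalg.norm(v)
    if norm <= t:
        return np.zeros_like(v)
    return v * (1.0 - t / norm)


def masked_l1_prox(v: np.ndarray, m: np.ndarray, t: float) -> np.ndarray:
    """Soft-threshold only the entries with mask 1; identity on mask 0.

    Solves argmin_l 0.5*||l - v||^2 + t*||l . m||_1 for binary m.
    """
    v = np.asarray(v, dtype=float)
    m = np.asarray(m)
    if m.shape != v.shape:
        raise ValueError(f"mask shape {m.shape} != vector shape {v.shape}")
    return np.where(m == 0, v, l1_prox(v, t))


def column_prox(v: np.ndarray, m: np.ndarray, eta_alpha: float, eta_gamma: float) -> np.ndarray:
    """Joint prox of eta_alpha*||.||_2 + eta_gamma*||. . m||_1 on one column.

    Computed as group-lasso shrinkage applied after the masked
    soft-threshold; the composition equals the joint operator because
    the soft-threshold only moves entries toward zero without changing
    the subgradient set of the L1 term.
    """
    return group_lasso_prox(masked_l1_prox(v, m, eta_gamma), eta_alpha)


def soft_mask_penalty(W: np.ndarray, M: np.ndarray, gamma: float) -> float:
    """Monitoring value gamma * sum_j ||W[:, j] . M[:, j]||_1.

    Enforced through the proximal step, not by differentiating this number.
    """
    W = np.asarray(W, dtype=float)
    M = np.asarray(M)
    if W.shape != M.shape:
        raise ValueError("W and M shapes differ")
    return float(gamma * np.abs(W * M).sum())


def apply_prox(
    W: np.ndarray,
    mask: GPMask,
    cfg: ProxConfig,
    column_roles: list[str] | None = None,
    frozen_columns=None,
) -> np.ndarray:
    """Per-column proximal update of the decoder weight matrix.

    Column roles: ``hard`` — non-members zeroed, members group-lasso
    shrunk; ``soft`` / ``unconstrained-sparse`` — masked L1 then group
    lasso; ``new_unconstrained`` — plain L1 with strength eta*gamma_ext
    (no group lasso); ``new_constrained_soft`` — masked L1 with strength
    eta*alpha_l1.  Columns listed in ``frozen_columns`` are returned
    untouched.  Returns a new array; the input is not modified.
    """
    roles = column_roles if column_roles is not None else mask.membership_mode
    if len(roles) != W.shape[1]:
        raise ValueError("one role per W column required")
    frozen = set(frozen_columns) if frozen_columns is not None else set()
    out = np.array(W, dtype=float, copy=True)
    for j, role in enumerate(roles):
        if j in frozen:
            continue
        canon = _ROLE_ALIASES.get(role)
        if canon is None:
            raise ValueError(f"unknown column role {role!r}")
        v = out[:, j]
        if canon == ROLE_HARD:
            v = v * mask.B[:, j]
            out[:, j] = group_lasso_prox(v, cfg.eta * cfg.alpha)
        elif canon == ROLE_SOFT:
            out[:, j] = column_prox(v, mask.M[:, j], cfg.eta * cfg.alpha, cfg.eta * cfg.gamma)
        elif canon == ROLE_NEW_UNCONSTRAINED:
            out[:, j] = l1_prox(v, cfg.eta * cfg.gamma_ext)
        else:  # new constrained soft column
            out[:, j] = masked_l1_prox(v, mask.M[:, j], cfg.eta * cfg.alpha_l1)
    return out


# -- HSIC -------------------------------------------------------------------


def _sq_dists(A: np.ndarray) -> np.ndarray:
    sq = (A * A).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (A @ A.T)
    return np.maximum(d, 0.0)


def median_bandwidth(A: np.ndarray) -> float:
    """Median heuristic: median pairwise distance (off-diagonal), floored at tiny."""
    d = np.sqrt(_sq_dists(A))
    off = d[np.triu_indices_from(d, k=1)]
    med = np.median(off) if off.size else 0.0
    return float(med) if med > 0 else 1.0


def _rbf_gram(A: np.ndarray, bandwidth: float | None = None) -> np.ndarray:
    bw = median_bandwidth(A) if bandwidth is None else bandwidth
    return np.exp(-_sq_dists(A) / (2.0 * bw * bw))


def hsic(x: np.ndarray, Y: np.ndarray) -> float:
    """Biased V-statistic HSIC estimate between samples ``x`` and ``Y``.

    Gaussian RBF kernels with per-variable median-heuristic bandwidths;
    estimator trace(K H L H) / (n - 1)^2 with H the centering matrix.
    Non-negative up to numerical noise; 0 for a constant input.
    """
    x = np.asarray(x, dtype=float).reshape(-1, 1) if np.ndim(x) == 1 else np.asarray(x, float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y.reshape(-1, 1)
    n = x.shape[0]
    if Y.shape[0] != n:
        raise ValueError("x and Y must have the same number of samples")
    if n < 4:
        raise ValueError("HSIC needs at least 4 samples (centering degenerate)")
    K = _rbf_gram(x)
    L = _rbf_gram(Y)
    H = np.eye(n) - np.ones((n, n)) / n
    Kc = H @ K @ H
    return float(np.trace(Kc @ (H @ L @ H)) / (n - 1) ** 2)


def hsic_total(Z: np.ndarray, new_indices) -> float:
    """Sum of HSIC between each new latent node and all other latent dims."""
    Z = np.asarray(Z, dtype=float)
    new_indices = list(new_indices)
    total = 0.0
    for j in new_indices:
        rest = [k for k in range(Z.shape[1]) if k != j]
        total += hsic(Z[:, j], Z[:, rest])
    return total
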