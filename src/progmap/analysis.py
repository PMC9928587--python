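"""Interpretability layer: differential gene-program testing and diagnostics.

The differential test asks, per latent program, whether cells of group *a*
score higher than cells of group *b*: H0: Z_a > Z_b against its
complement.  With diagonal Gaussian posteriors the pairwise probability
has a closed form, 0.5 * erfc(-(mu1 - mu2) / sqrt(2 (s1 + s2))); averaging
it over random cell pairs from the two groups estimates p(H0), and the
evidence is summarised as the log-Bayes factor log K = log p / (1 - p).
|log K| >= 2.3 (posterior odds of ~10) flags a program as differentially
active.  Gene-level diagnostics come straight off the linear decoder:
importance = |weight|, direction = predominant weight sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import erfc

from .model import GPModel, PosteriorParams
from .training import deactivated_gps

__all__ = [
    "GPTestResult",
    "pairwise_h0_prob",
    "bayes_factor",
    "rank_gps",
    "gene_importance",
    "gp_direction",
    "directed_scores",
    "normalized_entropy",
]

ENRICHMENT_THRESHOLD = 2.3


@dataclass
class GPTestResult:
    program_name: str
    log_bayes_factor: float
    p_h0: float
    direction: int
    enriched: bool
    n_cells_a: int
    n_cells_b: int


def pairwise_h0_prob(mu1, s1, mu2, s2):
    """P(z1 > z2) for independent Gaussians; vectorises over inputs."""
    s1, s2 = np.asarray(s1, float), np.asarray(s2, float)
    if np.any(s1 <= 0) or np.any(s2 <= 0):
        raise ValueError("posterior variances must be positive")
    d = np.asarray(mu1, float) - np.asarray(mu2, float)
    return 0.5 * erfc(-d / np.sqrt(2.0 * (s1 + s2)))


def _posterior(model: GPModel, cells) -> PosteriorParams:
    if isinstance(cells, PosteriorParams):
        return cells
    if isinstance(cells, tuple) and len(cells) == 2:
        return model.encode(*cells)
    # CellData-like
    return model.encode(cells.X, cells.conditions)


def _pairs(n_a: int, n_b: int, n_pairs: int, rng):
    """Cell-pair index sets: the full grid when affordable, else sampled.

    The grid is a symmetric function of the two groups, which makes the
    closed-form log K exactly antisymmetric under group swapping.
    """
    if n_a * n_b <= n_pairs:
        ia, ib = np.meshgrid(np.arange(n_a), np.arange(n_b), indexing="ij")
        return ia.ravel(), ib.ravel()
    return rng.integers(0, n_a, n_pairs), rng.integers(0, n_b, n_pairs)


def bayes_factor(
    model: GPModel,
    cells_a,
    cells_b,
    program: str,
    n_pairs: int = 10_000,
    method: str = "closed_form",
    clip: float = 1e-7,
    threshold: float = ENRICHMENT_THRESHOLD,
    seed: int = 0,
    mc_draws: int = 500,
    direction_method: str = "sum",
) -> GPTestResult:
    """Log-Bayes-factor test of program activity between two cell groups.

    ``cells_a`` / ``cells_b`` may be (X, conditions) tuples, CellData, or
    precomputed :class:`PosteriorParams`.  ``method="sampling"`` replaces
    the closed form with Monte-Carlo draws from the two posteriors on the
    same pairs (mainly an internal cross-check).
    """
    if program not in model.program_names:
        raise KeyError(f"unknown program {program!r}")
    j = model.program_names.index(program)
    post_a, post_b = _posterior(model, cells_a), _posterior(model, cells_b)
    n_a, n_b = post_a.mu.shape[0], post_b.mu.shape[0]
    if n_a == 0 or n_b == 0:
        raise ValueError("both groups must be non-empty")
    rng = np.random.default_rng(seed)
    ia, ib = _pairs(n_a, n_b, n_pairs, rng)
    mu1, s1 = post_a.mu[ia, j], post_a.sigma2[ia, j]
    mu2, s2 = post_b.mu[ib, j], post_b.sigma2[ib, j]
    if method == "closed_form":
        p = float(pairwise_h0_prob(mu1, s1, mu2, s2).mean())
    elif method == "sampling":
        z1 = mu1[:, None] + np.sqrt(s1)[:, None] * rng.standard_normal((len(ia), mc_draws))
        z2 = mu2[:, None] + np.sqrt(s2)[:, None] * rng.standard_normal((len(ib), mc_draws))
        p = float((z1 > z2).mean())
    else:
        raise ValueError("method must be 'closed_form' or 'sampling'")
    p_clipped = min(max(p, clip), 1.0 - clip)
    log_k = float(np.log(p_clipped) - np.log1p(-p_clipped))
    direction = gp_direction(model.params["dec.W"][:, j], method=direction_method)
    return GPTestResult(
        program_name=program,
        log_bayes_factor=log_k,
        p_h0=p_clipped,
        direction=direction,
        enriched=abs(log_k) >= threshold,
        n_cells_a=n_a,
        n_cells_b=n_b,
    )


def rank_gps(
    model: GPModel,
    cells_a,
    cells_b,
    threshold: float = ENRICHMENT_THRESHOLD,
    n_pairs: int = 10_000,
    method: str = "closed_form",
    clip: float = 1e-7,
    seed: int = 0,
    use_directed: bool = False,
) -> list[GPTestResult]:
    """Test every non-deactivated program; sorted by |log K| descending.

    ``use_directed`` flips each program's posterior means by its direction
    heuristic first, so positive log K always means predominant
    up-regulation in group a.
    """
    post_a, post_b = _posterior(model, cells_a), _posterior(model, cells_b)
    if use_directed:
        dirs = np.array(
            [gp_direction(model.params["dec.W"][:, j]) for j in range(model.spec.n_programs)],
            dtype=float,
        )
        post_a = PosteriorParams(mu=post_a.mu * dirs, sigma2=post_a.sigma2)
        post_b = PosteriorParams(mu=post_b.mu * dirs, sigma2=post_b.sigma2)
    dead = set(deactivated_gps(model, tol=0.0))
    results = [
        bayes_factor(
            model, post_a, post_b, name,
            n_pairs=n_pairs, method=method, clip=clip, threshold=threshold, seed=seed,
        )
        for name in model.program_names
        if name not in dead
    ]
    results.sort(key=lambda r: (-abs(r.log_bayes_factor), r.program_name))
    return results


def gene_importance(model: GPModel, program: str) -> list[tuple[str, float]]:
    """Genes ranked by |decoder weight| in the program column (ties: name order)."""
    if program not in model.program_names:
        raise KeyError(f"unknown program {program!r}")
    j = model.program_names.index(program)
    scores = np.abs(model.params["dec.W"][:, j])
    order = sorted(zip(model.mask.gene_names, scores), key=lambda t: (-t[1], t[0]))
    return [(g, float(s)) for g, s in order]


def gp_direction(W_col, method: str = "sum") -> int:
    """Predominant regulation direction of a program column: +1 or -1.

    ``sum`` uses the sign of the summed weights; ``counts`` the sign of the
    positive-minus-negative entry count.  A zero aggregate maps to +1.
    """
    w = np.asarray(W_col, dtype=float)
    if w.size == 0:
        raise ValueError("empty weight column")
    if method == "sum":
        agg = w.sum()
    elif method == "counts":
        agg = np.sign(w).sum()
    else:
        raise ValueError("method must be 'sum' or 'counts'")
    return 1 if agg >= 0 else -1


def directed_scores(Z, directions) -> np.ndarray:
    """Columnwise sign-flip of latent scores so + always means up-regulation."""
    Z = np.asarray(Z, dtype=float)
    directions = np.asarray(directions, dtype=float)
    if directions.shape[0] != Z.shape[1]:
        raise ValueError("one direction per latent column required")
    return Z * directions[None, :]


def normalized_entropy(scores) -> float:
    """Shannon entropy of the normalised score vector over log(n), in [0, 1].

    1 for uniform scores (weight spread evenly), 0 for a one-hot column
    (a single dominating gene).
    """
    s = np.asarray(scores, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 scores")
    if np.any(s < 0):
        raise ValueError("scores must be non-negative")
    total = s.sum()
    if total <= 0:
        raise ValueError("all-zero score vector has no distribution")
    p = s / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum() / np.log(s.size))
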