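"""Conditional VAE with a masked linear negative-binomial decoder.

The generative model: each cell's latent vector ``Z`` (one dimension per
gene program) and one-hot condition ``C`` feed a single linear layer
``H = [Z, C] [W, L]^T``; the link ``g`` maps ``H`` to negative-binomial
means (softmax times the cell's library size by default, so reconstruction
conserves per-cell total counts), with per-(condition, gene) dispersions
``CD``.  The encoder is a small nonlinear network producing a diagonal
Gaussian posterior ``q(Z | X, C)``; the prior on ``Z`` is standard normal.

The decoder weight matrix ``W`` is wired to curated gene programs through
the binary mask ``B``: hard-membership columns have non-member entries
pinned to exactly zero at all times; soft columns leave them free but
L1-penalised through the proximal step (see :mod:`progmap.regularizers`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .gene_sets import GPMask, ROLE_HARD

__all__ = [
    "ModelSpec",
    "CellBatch",
    "CellData",
    "PosteriorParams",
    "GPModel",
    "one_hot",
    "nb_log_likelihood",
    "kl_gaussian",
    "loss_components",
]

LINKS = ("softmax", "softplus", "exp")


@dataclass
class ModelSpec:
    n_genes: int
    n_programs: int
    n_conditions: int
    hidden_sizes: tuple = (256, 256)
    link: str = "softmax"
    dispersion_mode: str = "per_gene_per_condition"

    def __post_init__(self):
        self.hidden_sizes = tuple(int(h) for h in self.hidden_sizes)
        if not self.hidden_sizes:
            raise ValueError("hidden_sizes must be non-empty")
        if self.link not in LINKS:
            raise ValueError(f"link must be one of {LINKS}")
        if self.n_programs < 1:
            raise ValueError("need at least one program (latent dim = #programs)")


@dataclass
class PosteriorParams:
    """Per-cell diagonal Gaussian posterior over latent program scores."""

    mu: np.ndarray
    sigma2: np.ndarray

    def __post_init__(self):
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        if self.mu.shape != self.sigma2.shape:
            raise ValueError("mu and sigma2 shapes differ")
        if np.any(self.sigma2 <= 0):
            raise ValueError("sigma2 must be strictly positive")


def one_hot(labels, categories) -> np.ndarray:
    categories = list(categories)
    index = {c: i for i, c in enumerate(categories)}
    out = np.zeros((len(labels), len(categories)))
    for row, lab in enumerate(labels):
        if lab not in index:
            raise KeyError(f"condition {lab!r} not among {categories}")
        out[row, index[lab]] = 1.0
    return out


@dataclass
class CellBatch:
    """A mini-batch: raw counts, one-hot conditions and library sizes."""

    X: np.ndarray
    C: np.ndarray
    library_size: np.ndarray | None = None

    def __post_init__(self):
        self.X = np.asarray(self.X, dtype=float)
        if np.any(self.X < 0) or np.any(self.X != np.round(self.X)):
            raise ValueError("X must contain non-negative integer counts")
        self.C = np.asarray(self.C, dtype=float)
        if self.C.shape[0] != self.X.shape[0]:
            raise ValueError("X and C row counts differ")
        if not np.allclose(self.C.sum(axis=1), 1.0):
            raise ValueError("C rows must be one-hot")
        if self.library_size is None:
            self.library_size = self.X.sum(axis=1)
        self.library_size = np.asarray(self.library_size, dtype=float)
        if np.any(self.library_size <= 0):
            raise ValueError("library sizes must be positive")


@dataclass
class CellData:
    """A full dataset: counts, per-cell condition labels, gene names."""

    X: np.ndarray
    conditions: np.ndarray
    condition_categories: list[str]
    gene_names: list[str] = field(default_factory=list)
    cell_ids: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.X = np.asarray(self.X)
        self.conditions = np.asarray(self.conditions)
        if len(self.conditions) != self.X.shape[0]:
            raise ValueError("one condition label per cell required")
        unknown = set(self.conditions) - set(self.condition_categories)
        if unknown:
            raise ValueError(f"labels outside declared vocabulary: {sorted(unknown)}")
        if not self.gene_names:
            self.gene_names = [f"g{i}" for i in range(self.X.shape[1])]

    @property
    def n_cells(self) -> int:
        return self.X.shape[0]

    def batch(self, rows=None) -> CellBatch:
        rows = np.arange(self.n_cells) if rows is None else np.asarray(rows)
        return CellBatch(
            X=self.X[rows],
            C=one_hot(self.conditions[rows], self.condition_categories),
        )

    @classmethod
    def from_anndata(cls, adata, condition_key: str = "condition") -> "CellData":
        import scipy.sparse as sp

        X = adata.X.toarray() if sp.issparse(adata.X) else np.asarray(adata.X)
        labels = np.asarray(adata.obs[condition_key].astype(str))
        cats = list(dict.fromkeys(labels))
        return cls(
            X=X,
            conditions=labels,
            condition_categories=cats,
            gene_names=list(adata.var_names),
            cell_ids=list(adata.obs_names),
        )


# -- parameter initialisation ----------------------------------------------


def init_params(spec: ModelSpec, mask: GPMask, rng: np.random.Generator) -> dict:
    """He-initialised encoder; decoder W small-normal on members, zero elsewhere."""
    params: dict[str, np.ndarray] = {}
    sizes = [spec.n_genes + spec.n_conditions, *spec.hidden_sizes]
    for i, (fan_in, fan_out) in enumerate(zip(sizes[:-1], sizes[1:])):
        params[f"enc.h{i}.W"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (fan_out, fan_in))
        params[f"enc.h{i}.b"] = np.zeros(fan_out)
    h_last = sizes[-1]
    for head in ("mu", "sv"):
        params[f"enc.{head}.W"] = rng.normal(0.0, np.sqrt(1.0 / h_last), (spec.n_programs, h_last))
        params[f"enc.{head}.b"] = np.zeros(spec.n_programs)
    W = rng.normal(0.0, 0.02, (spec.n_genes, spec.n_programs))
    W *= mask.B  # soft/unconstrained non-members start at exact zero
    params["dec.W"] = W
    params["dec.L"] = np.zeros((spec.n_genes, spec.n_conditions))
    params["dec.D"] = np.zeros((spec.n_conditions, spec.n_genes))  # theta = exp(D) = 1
    return params


def _as_tensors(params: dict, requires_grad: bool = True) -> dict:
    return {k: Tensor(v, requires_grad=requires_grad) for k, v in params.items()}


# -- forward passes (autodiff tensors) --------------------------------------


def encode_t(pt: dict, X: np.ndarray, C: np.ndarray, spec: ModelSpec):
    """Encoder forward on tensors; input is [log1p(counts), one-hot condition]."""
    if X.shape[1] != spec.n_genes:
        raise ValueError(f"expected {spec.n_genes} genes, got {X.shape[1]}")
    h = Tensor(np.concatenate([np.log1p(X), C], axis=1))
    for i in range(len(spec.hidden_sizes)):
        h = ad.relu(h @ pt[f"enc.h{i}.W"].T + pt[f"enc.h{i}.b"])
    mu = h @ pt["enc.mu.W"].T + pt["enc.mu.b"]
    sigma2 = ad.softplus(h @ pt["enc.sv.W"].T + pt["enc.sv.b"])
    return mu, sigma2


def decode_t(pt: dict, Z: Tensor, C: np.ndarray | Tensor, library: np.ndarray, link: str):
    """Decoder forward: H = [Z, C][W, L]^T, then the positive link times library."""
    Ct = C if isinstance(C, Tensor) else Tensor(C)
    H = Z @ pt["dec.W"].T + Ct @ pt["dec.L"].T
    lib = library.reshape(-1, 1)
    if link == "softmax":
        mean = ad.softmax(H, axis=1) * lib
    elif link == "softplus":
        mean = ad.softplus(H) * lib
    else:
        mean = ad.exp(H) * lib
    # tiny floor keeps log(mean) finite when the link underflows to 0
    return mean + 1e-10


def nb_ll_t(x: np.ndarray, mean: Tensor, theta: Tensor) -> Tensor:
    """Per-cell NB log-likelihood (mean/dispersion parameterisation), summed over genes."""
    xt = Tensor(x)
    ll = (
        ad.lgamma(xt + theta)
        - ad.lgamma(theta)
        - Tensor(gammaln_const(x))
        + theta * (ad.log(theta) - ad.log(theta + mean))
        + xt * (ad.log(mean) - ad.log(theta + mean))
    )
    return ll.sum(axis=1)


def gammaln_const(x: np.ndarray) -> np.ndarray:
    from scipy.special import gammaln

    return gammaln(np.asarray(x, dtype=float) + 1.0)


def kl_gaussian_t(mu: Tensor, sigma2: Tensor) -> Tensor:
    return ((mu * mu + sigma2 - ad.log(sigma2) - 1.0) * 0.5).sum(axis=1)


def hsic_t(zj: Tensor, Zrest: Tensor) -> Tensor:
    """Biased HSIC V-statistic between one latent node and the remaining dims.

    RBF kernels with median-heuristic bandwidths; bandwidths are treated
    as constants of the current batch (no gradient through them).
    """
    from .regularizers import median_bandwidth

    n = zj.data.shape[0]
    H = Tensor(np.eye(n) - np.ones((n, n)) / n)

    def gram(A: Tensor) -> Tensor:
        bw = median_bandwidth(A.data)
        sq = (A * A).sum(axis=1, keepdims=True)
        D = sq + sq.T - (A @ A.T) * 2.0
        return ad.exp(D * (-1.0 / (2.0 * bw * bw)))

    Kc = H @ gram(zj) @ H
    Lc = H @ gram(Zrest) @ H
    return (Kc * Lc).sum() * (1.0 / (n - 1) ** 2)


def loss_components(
    batch: CellBatch,
    pt: dict,
    spec: ModelSpec,
    beta: float,
    nu: float,
    new_node_indices=(),
    eps: np.ndarray | None = None,
    hsic_rows: np.ndarray | None = None,
) -> dict:
    """ELBO-based training loss on one mini-batch.

    total = recon + beta * KL + nu * HSIC.  The group-lasso and soft-mask
    penalties are deliberately absent: they enter through the proximal
    update, not the gradient.  ``eps`` supplies the reparameterisation
    noise (standard normal); posterior means are used when it is None.
    ``hsic_rows`` optionally restricts the (quadratic-cost) HSIC estimate
    to a subset of the batch.  Returns tensors under keys
    recon/kl/hsic/total.
    """
    if beta < 0 or nu < 0:
        raise ValueError("beta and nu must be non-negative")
    mu, sigma2 = encode_t(pt, batch.X, batch.C, spec)
    z = mu if eps is None else mu + ad.sqrt(sigma2) * Tensor(eps)
    mean = decode_t(pt, z, batch.C, batch.library_size, spec.link)
    theta = Tensor(batch.C) @ ad.exp(pt["dec.D"])
    recon = -nb_ll_t(batch.X, mean, theta).mean()
    kl = kl_gaussian_t(mu, sigma2).mean()
    new_node_indices = list(new_node_indices)
    if new_node_indices and nu > 0:
        z_h = z
        if hsic_rows is not None:
            sel = np.zeros((len(hsic_rows), z.data.shape[0]))
            sel[np.arange(len(hsic_rows)), np.asarray(hsic_rows)] = 1.0
            z_h = Tensor(sel) @ z
        hsic_sum = None
        all_idx = range(z_h.data.shape[1])
        for j in new_node_indices:
            rest = [k for k in all_idx if k != j]
            term = hsic_t(z_h.cols([j]), z_h.cols(rest))
            hsic_sum = term if hsic_sum is None else hsic_sum + term
        hsic = hsic_sum
    else:
        hsic = Tensor(0.0)
    total = recon + kl * beta + hsic * nu
    if not np.isfinite(total.data):
        raise FloatingPointError("non-finite training loss")
    return {"recon": recon, "kl": kl, "hsic": hsic, "total": total}


# -- numpy-facing wrappers ---------------------------------------------------


def nb_log_likelihood(x, mean, dispersion) -> np.ndarray:
    """Per-cell NB log-pmf summed over genes (numpy in, numpy out)."""
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if np.any(x < 0):
        raise ValueError("counts must be non-negative")
    mean = np.broadcast_to(np.asarray(mean, dtype=float), x.shape)
    theta = np.broadcast_to(np.asarray(dispersion, dtype=float), x.shape)
    if np.any(mean <= 0) or np.any(theta <= 0):
        raise ValueError("mean and dispersion must be positive")
    return nb_ll_t(x, Tensor(mean), Tensor(theta)).data


def kl_gaussian(post: PosteriorParams) -> np.ndarray:
    """Closed-form KL(q || N(0, I)) per cell, summed over latent dims."""
    return kl_gaussian_t(Tensor(post.mu), Tensor(post.sigma2)).data


# -- the model object --------------------------------------------------------


@dataclass
class GPModel:
    """A trained (or in-training) gene-program conditional VAE.

    ``trainable`` maps parameter names to binary masks (same shape); a
    missing entry means fully trainable.  ``new_unconstrained_idx`` lists
    latent columns added at query time that carry the HSIC penalty.
    """

    spec: ModelSpec
    mask: GPMask
    params: dict
    condition_labels: list[str]
    trainable: dict = field(default_factory=dict)
    new_unconstrained_idx: list[int] = field(default_factory=list)

    @property
    def program_names(self) -> list[str]:
        return self.mask.program_names

    @property
    def column_roles(self) -> list[str]:
        return self.mask.membership_mode

    @classmethod
    def initialise(
        cls, spec: ModelSpec, mask: GPMask, condition_labels, seed: int = 0
    ) -> "GPModel":
        if spec.n_programs != mask.n_programs:
            raise ValueError("latent size must equal the number of mask columns")
        if spec.n_genes != len(mask.gene_names):
            raise ValueError("spec.n_genes must match the mask gene axis")
        rng = np.random.default_rng(seed)
        return cls(
            spec=spec,
            mask=mask,
            params=init_params(spec, mask, rng),
            condition_labels=list(condition_labels),
        )

    def enforce_hard_mask(self) -> None:
        """Zero decoder entries outside hard-membership programs, in place."""
        for j, role in enumerate(self.column_roles):
            if role == ROLE_HARD:
                self.params["dec.W"][:, j] *= self.mask.B[:, j]

    def encode(self, X, conditions) -> PosteriorParams:
        batch = CellBatch(X=X, C=one_hot(conditions, self.condition_labels))
        pt = _as_tensors(self.params, requires_grad=False)
        mu, sigma2 = encode_t(pt, batch.X, batch.C, self.spec)
        return PosteriorParams(mu=mu.data, sigma2=sigma2.data)

    def decode(self, Z, conditions, library_size) -> np.ndarray:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[1] != self.spec.n_programs:
            raise ValueError(f"expected {self.spec.n_programs} latent columns")
        pt = _as_tensors(self.params, requires_grad=False)
        C = one_hot(conditions, self.condition_labels)
        mean = decode_t(pt, Tensor(Z), C, np.asarray(library_size, float), self.spec.link).data
        bad = np.flatnonzero(~np.isfinite(mean).all(axis=1))
        if bad.size:
            raise FloatingPointError(f"non-finite decoder mean for cell index {bad[0]}")
        return mean

    def copy(self) -> "GPModel":
        from copy import deepcopy

        return deepcopy(self)
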