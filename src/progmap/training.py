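"""Proximal stochastic gradient training.

Each mini-batch takes a gradient step on the encoder, the condition
weights ``L`` and the dispersions ``D`` (Adam by default), and a plain SGD
step on the decoder program matrix ``W`` followed by the closed-form
proximal update that enforces group-lasso program selection and the
soft-membership L1 (prox semantics require a plain step for ``W``; the
threshold uses W's own learning rate).  Deactivated programs therefore
have bitwise-zero columns — no tolerance needed.

Training runs in two phases: a stochastic mini-batch phase (optionally
early-stopped on a validation ELBO), then a short full-batch proximal
refinement phase.  The refinement phase plays the role a decaying
learning-rate schedule plays elsewhere: with the gradient noise gone, the
proximal operator identifies the active set exactly, so program columns
below the group-lasso threshold settle at bitwise zero instead of
hovering near it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .gene_sets import GPMask, ROLE_HARD
from .model import CellData, GPModel, ModelSpec, _as_tensors, loss_components
from .regularizers import ProxConfig, apply_prox

logger = logging.getLogger("progmap")

#: the monitoring metric printed at the end of training
DEACTIVATION_SHARE_LOG = "Share of de-activated inactive genes in extension terms"


@dataclass
class TrainConfig:
    beta: float = 0.5  # KL weight (a.k.a. alpha_kl)
    prox: ProxConfig = field(default_factory=ProxConfig)
    nu: float = 1.0  # HSIC weight, active only when new unconstrained nodes exist
    epochs: int = 100
    refine_epochs: int = 150  # trailing large-batch proximal steps
    batch_size: int = 256
    learning_rate: float = 1e-3  # Adam, encoder / L / D
    w_learning_rate: float = 0.01  # plain SGD on W; also the prox eta
    seed: int = 0
    early_stopping: bool = False
    patience: int = 25
    refine_batch_size: int = 512
    val_fraction: float = 0.1
    deactivation_tol: float = 0.0
    prox_warmup_epochs: int = 30  # linear ramp of the prox strengths from 0
    hsic_max_cells: int = 256  # HSIC is O(n^2); estimate it on a subsample

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2")
        if self.learning_rate <= 0 or self.w_learning_rate < 0:
            raise ValueError("learning rates must be positive")


@dataclass
class TrainReport:
    recon: list = field(default_factory=list)
    kl: list = field(default_factory=list)
    hsic: list = field(default_factory=list)
    total: list = field(default_factory=list)
    val_elbo: list = field(default_factory=list)
    deactivated_program_names: list = field(default_factory=list)
    inactive_gene_deactivation_share: float = float("nan")
    epochs_run: int = 0


def _stratified_split(conditions, val_fraction, rng):
    """Per-condition random split; returns (train_idx, val_idx)."""
    train, val = [], []
    conditions = np.asarray(conditions)
    for lab in np.unique(conditions):
        idx = np.flatnonzero(conditions == lab)
        idx = rng.permutation(idx)
        n_val = int(round(len(idx) * val_fraction))
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    return np.sort(np.array(train, int)), np.sort(np.array(val, int))


class _Adam:
    def __init__(self, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for name, g in grads.items():
            m = self.m.setdefault(name, np.zeros_like(g))
            v = self.v.setdefault(name, np.zeros_like(g))
            m += (1 - self.b1) * (g - m)
            v += (1 - self.b2) * (g * g - v)
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            params[name] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _frozen_w_columns(model: GPModel) -> set[int]:
    tmask = model.trainable.get("dec.W")
    if tmask is None:
        return set()
    return {j for j in range(tmask.shape[1]) if not tmask[:, j].any()}


def fit(model: GPModel, data: CellData, cfg: TrainConfig) -> TrainReport:
    """Train ``model`` in place on ``data``; respects per-parameter
    trainability masks (used by query mapping) and returns the report."""
    rng = np.random.default_rng(cfg.seed)
    report = TrainReport()

    def prox_at(epoch):
        # warm-up lets the encoder couple to every program before the
        # group lasso starts the selection race
        if cfg.w_learning_rate <= 0:
            return None
        s = min(1.0, (epoch + 1) / max(cfg.prox_warmup_epochs, 1))
        return ProxConfig(
            alpha=s * cfg.prox.alpha,
            gamma=s * cfg.prox.gamma,
            gamma_ext=s * cfg.prox.gamma_ext,
            alpha_l1=s * cfg.prox.alpha_l1,
            eta=cfg.w_learning_rate,
        )
    frozen_cols = _frozen_w_columns(model)
    new_nodes = list(model.new_unconstrained_idx)

    train_idx, val_idx = _stratified_split(data.conditions, cfg.val_fraction, rng)
    if len(val_idx) == 0:
        val_idx = train_idx[: max(2, len(train_idx) // 10)]
    adam = _Adam(cfg.learning_rate)

    model.enforce_hard_mask()
    best_val, stale = np.inf, 0

    def one_step(rows, epoch, start, prox_cfg):
        batch = data.batch(rows)
        eps = rng.standard_normal((len(rows), model.spec.n_programs))
        hsic_rows = None
        if new_nodes and len(rows) > cfg.hsic_max_cells:
            hsic_rows = rng.choice(len(rows), cfg.hsic_max_cells, replace=False)
        pt = _as_tensors(model.params, requires_grad=True)
        try:
            parts = loss_components(
                batch, pt, model.spec, cfg.beta, cfg.nu, new_nodes,
                eps=eps, hsic_rows=hsic_rows,
            )
        except FloatingPointError as err:
            raise FloatingPointError(
                f"{err} (epoch {epoch}, batch starting at {start})"
            ) from err
        parts["total"].backward()
        grads = {}
        for name, t in pt.items():
            if t.grad is None:
                continue
            g = t.grad
            tmask = model.trainable.get(name)
            if tmask is not None:
                # "+ 0.0" turns masked -0.0 into +0.0 so frozen entries
                # (including exact zeros) stay bitwise identical
                g = g * tmask + 0.0
            grads[name] = g
        w_grad = grads.pop("dec.W", None)
        adam.step(model.params, grads)
        if w_grad is not None and cfg.w_learning_rate > 0:
            model.params["dec.W"] -= cfg.w_learning_rate * w_grad
            model.params["dec.W"] = apply_prox(
                model.params["dec.W"],
                model.mask,
                prox_cfg,
                model.column_roles,
                frozen_columns=frozen_cols,
            )
        return parts

    def run_epoch(epoch, batch_size):
        prox_cfg = prox_at(epoch)
        order = rng.permutation(train_idx)
        sums = {"recon": 0.0, "kl": 0.0, "hsic": 0.0, "total": 0.0}
        n_seen = 0
        for start in range(0, len(order), batch_size):
            rows = order[start : start + batch_size]
            if len(rows) < 2:
                continue
            parts = one_step(rows, epoch, start, prox_cfg)
            for key in sums:
                sums[key] += float(parts[key].data) * len(rows)
            n_seen += len(rows)
        _assert_hard_mask(model)
        for key in sums:
            getattr(report, key).append(sums[key] / max(n_seen, 1))
        report.epochs_run = epoch + 1
        val_loss = _validation_loss(model, data, val_idx, cfg)
        report.val_elbo.append(val_loss)
        logger.info(
            "epoch %d: recon=%.3f kl=%.3f hsic=%.5f total=%.3f val=%.3f",
            epoch, report.recon[-1], report.kl[-1], report.hsic[-1],
            report.total[-1], val_loss,
        )
        return val_loss

    for epoch in range(cfg.epochs):
        val_loss = run_epoch(epoch, cfg.batch_size)
        if cfg.early_stopping:
            # halt without rollback: the prox active set keeps improving
            # past the validation optimum, so we stop but do not restore
            if val_loss < best_val - 1e-6:
                best_val = val_loss
                stale = 0
            else:
                stale += 1
                if stale > cfg.patience:
                    logger.info("early stopping at epoch %d", epoch)
                    break

    # large-batch proximal refinement: with most gradient noise gone the
    # prox identifies the active set exactly (columns settle at bit zero)
    for _ in range(cfg.refine_epochs):
        run_epoch(report.epochs_run, min(cfg.refine_batch_size, len(train_idx)))

    report.deactivated_program_names = deactivated_gps(model, cfg.deactivation_tol)
    report.inactive_gene_deactivation_share = inactive_gene_deactivation_share(model)
    logger.info("%s: %.4f", DEACTIVATION_SHARE_LOG, report.inactive_gene_deactivation_share)
    return report


def _validation_loss(model: GPModel, data: CellData, val_idx, cfg: TrainConfig) -> float:
    """Deterministic ELBO proxy (posterior-mean latent) on the validation cells."""
    batch = data.batch(val_idx)
    pt = _as_tensors(model.params, requires_grad=False)
    parts = loss_components(batch, pt, model.spec, cfg.beta, 0.0, (), eps=None)
    return float(parts["recon"].data + cfg.beta * parts["kl"].data)


def _assert_hard_mask(model: GPModel) -> None:
    W, B = model.params["dec.W"], model.mask.B
    for j, role in enumerate(model.column_roles):
        if role == ROLE_HARD and np.any(W[:, j][B[:, j] == 0] != 0.0):
            raise AssertionError(f"hard-mask invariant violated in column {j}")


def train_reference(
    data: CellData,
    mask: GPMask,
    spec: ModelSpec | None = None,
    cfg: TrainConfig | None = None,
) -> tuple[GPModel, TrainReport]:
    """Build and train a reference model from scratch.

    The latent dimension equals the number of mask columns; conditions are
    the dataset's declared condition vocabulary.
    """
    cfg = cfg or TrainConfig()
    if spec is None:
        spec = ModelSpec(
            n_genes=len(mask.gene_names),
            n_programs=mask.n_programs,
            n_conditions=len(data.condition_categories),
        )
    if set(data.condition_categories) - set(data.condition_categories):
        raise ValueError("data conditions must be within the declared vocabulary")
    model = GPModel.initialise(spec, mask, data.condition_categories, seed=cfg.seed)
    report = fit(model, data, cfg)
    return model, report


def deactivated_gps(model: GPModel, tol: float = 0.0) -> list[str]:
    """Programs whose decoder column L2 norm is <= tol (prox yields exact zeros)."""
    W = model.params["dec.W"]
    norms = np.linalg.norm(W, axis=0)
    return [name for name, nrm in zip(model.program_names, norms) if nrm <= tol]


def inactive_gene_deactivation_share(model: GPModel, mask: GPMask | None = None) -> float:
    """Fraction of L1-penalised (M = 1) decoder entries that are exactly zero.

    Computed over soft-membership and sparse columns; hard columns have no
    penalised entries by construction.  Returns 1.0 (with a warning) when
    the model has no such columns.
    """
    mask = mask or model.mask
    W = model.params["dec.W"]
    sel = np.zeros_like(W, dtype=bool)
    for j, role in enumerate(model.column_roles):
        if role != ROLE_HARD:
            sel[:, j] = mask.M[:, j] == 1
    if not sel.any():
        logger.warning("model has no soft-masked columns; share reported as 1.0")
        return 1.0
    return float((W[sel] == 0.0).mean())
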