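"""Gradient-based fitting of a soft rule set.

The loss is the mean squared prediction error plus the three
interpretability penalties (length, crispness, semantic).  Everything is
differentiable in the unconstrained parameterisation (selection logits,
rule weights, intercept), so training is plain first-order optimisation:
analytic gradients with Adam-style adaptive per-parameter step sizes.

Protocol: the table is split at study level into an internal training and
validation part; the model trains for at least ``min_epochs`` full-batch
epochs and stops once the validation loss (MSE + penalties) has not
improved for ``patience`` consecutive epochs, returning the parameters of
the best validation epoch.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

from .arm_table import ArmTable
from .ontology import OntologyGraph
from .rule_model import (
    DEFAULT_CRISP_THRESHOLD,
    DEFAULT_LAMBDA_CRISP,
    DEFAULT_LAMBDA_LEN,
    DEFAULT_LAMBDA_SEM,
    SoftRuleSet,
    semantic_pair_matrix,
)

__all__ = ["TrainConfig", "TrainResult", "initialize", "train"]

log = logging.getLogger(__name__)


@dataclass
class TrainConfig:
    """Knobs of the training procedure.

    Defaults follow the deployed protocol: 200 rules, at least 400 epochs
    with validation early stopping.  ``patience`` = 1 replicates stopping at
    the first non-improving epoch but is noise-fragile; the default of 20 is
    configurable down to 1.
    """

    n_rules: int = 200
    min_epochs: int = 400
    max_epochs: int = 4000
    patience: int = 20
    learning_rate: float = 1e-2
    validation_fraction: float = 0.1
    lambda_len: float = DEFAULT_LAMBDA_LEN
    lambda_crisp: float = DEFAULT_LAMBDA_CRISP
    lambda_sem: float = DEFAULT_LAMBDA_SEM
    crisp_threshold: float = DEFAULT_CRISP_THRESHOLD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_epochs < 1:
            raise ValueError("min_epochs must be ≥ 1")
        if not (0 < self.validation_fraction < 1):
            raise ValueError("validation_fraction must lie in (0, 1)")
        if self.patience < 1:
            raise ValueError("patience must be ≥ 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class TrainResult:
    """A fitted model plus its training log."""

    model: SoftRuleSet
    history: list[dict]  # per epoch: train_loss, val_loss, penalties
    best_epoch: int
    best_val_loss: float


# ----------------------------------------------------------------------


def _nonnegated_columns(table: ArmTable) -> list[str]:
    return [c for c in table.feature_columns if table.kind(c) != "negated"]


def initialize(table: ArmTable, config: TrainConfig) -> SoftRuleSet:
    """Regression-seeded singletons plus random remainder rules.

    One singleton rule per non-negated literal, with the selection pinned
    to that literal and the weight taken from an ordinary least-squares fit
    of the outcome on the non-negated literals; the intercept comes from the
    same regression.  The remaining rules start with selections near zero
    and small random weights.  A singular regression falls back to a ridge
    solution (logged).
    """
    data = table.with_outcomes_only()
    if data.n_arms < 2:
        raise ValueError("need at least 2 arms with outcomes")
    schema = table.schema
    non_neg = _nonnegated_columns(table)
    if config.n_rules < len(non_neg):
        raise ValueError(
            f"n_rules={config.n_rules} < {len(non_neg)} non-negated literals; "
            "singleton coverage requires at least one rule per literal"
        )
    rng = np.random.default_rng(config.seed)

    X = data.memberships(non_neg)
    y = data.outcomes()
    A = np.column_stack([np.ones(len(y)), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < A.shape[1]:
        log.info("singular init regression (rank %d < %d); using ridge", rank, A.shape[1])
        lam = 1.0
        reg = lam * np.eye(A.shape[1])
        reg[0, 0] = 0.0
        coef = np.linalg.solve(A.T @ A + reg, A.T @ y)
    intercept, betas = float(coef[0]), coef[1:]

    L, R = len(schema), config.n_rules
    col_index = {c: i for i, c in enumerate(schema)}
    # Remainder rules: selections near zero, tiny random weights.  A rule
    # with all-zero selection fits every arm, so its weight acts as an
    # intercept shift; keeping initial weights tiny leaves the regression
    # intercept calibrated.
    theta = rng.normal(-2.5, 1.0, size=(R, L))
    weights = rng.normal(0.0, 0.01, size=R)
    for k, (col, beta) in enumerate(zip(non_neg, betas)):
        theta[k] = -6.0
        theta[k, col_index[col]] = 4.0  # s ≈ 0.982 on the singleton literal
        weights[k] = beta

    return SoftRuleSet(
        schema=list(schema),
        theta=theta,
        weights=weights,
        intercept=intercept,
        lambda_len=config.lambda_len,
        lambda_crisp=config.lambda_crisp,
        lambda_sem=config.lambda_sem,
        crisp_threshold=config.crisp_threshold,
        penalty_scale=max(float(np.var(y)), 1.0),
    )


# ----------------------------------------------------------------------
# Forward + backward pass, fully vectorised.


def _forward(theta, w, b, X):
    s = 1.0 / (1.0 + np.exp(-np.clip(theta, -500, 500)))
    g = 1.0 - s[None, :, :] * (1.0 - X[:, None, :])  # (N, R, L)
    fit = g.prod(axis=2)
    pred = b + fit @ w
    return s, g, fit, pred


def _loss_terms(s, pred, y, lambdas, scale, M):
    lam_len, lam_crisp, lam_sem = lambdas
    mse = float(np.mean((pred - y) ** 2))
    p_len = lam_len * scale * float(s.sum())
    p_crisp = lam_crisp * scale * float((s * (1.0 - s)).sum())
    p_sem = lam_sem * scale * 0.5 * float(np.einsum("rl,lk,rk->", s, M, s))
    return mse, p_len, p_crisp, p_sem


def _gradients(theta, w, b, X, y, lambdas, scale, M):
    N = len(y)
    lam_len, lam_crisp, lam_sem = lambdas
    s, g, fit, pred = _forward(theta, w, b, X)
    resid = pred - y

    grad_b = 2.0 * resid.mean()
    grad_w = (2.0 / N) * (resid @ fit)

    # product over literals excluding each position, via two cumprods
    left = np.cumprod(g, axis=2)
    right = np.cumprod(g[:, :, ::-1], axis=2)[:, :, ::-1]
    E = np.ones_like(g)
    E[:, :, 1:] *= left[:, :, :-1]
    E[:, :, :-1] *= right[:, :, 1:]

    # d fit / d s_rl = −(1 − x_l) · E;  chain through the residuals
    up = (2.0 / N) * resid[:, None] * w[None, :]          # (N, R)
    grad_s = -np.einsum("nr,nrl->rl", up, (1.0 - X)[:, None, :] * E)

    grad_s += lam_len * scale
    grad_s += lam_crisp * scale * (1.0 - 2.0 * s)
    grad_s += lam_sem * scale * (s @ M)

    grad_theta = grad_s * s * (1.0 - s)
    loss = _loss_terms(s, pred, y, lambdas, scale, M)
    return grad_theta, grad_w, grad_b, loss


def _split_validation(table: ArmTable, fraction: float, seed: int):
    studies = np.array(sorted(map(str, set(table.df["study_id"].astype(str)))))
    rng = np.random.default_rng(seed)
    rng.shuffle(studies)
    n_val = max(1, int(round(fraction * len(studies))))
    if n_val >= len(studies):
        raise ValueError("too few studies for a validation split")
    val = set(studies[:n_val])
    mask = table.df["study_id"].astype(str).isin(val).to_numpy()
    return ~mask, mask


def train(table: ArmTable, graph: OntologyGraph, config: TrainConfig) -> TrainResult:
    """Fit a soft rule set with early stopping on a held-out study split.

    Returns the parameters from the best validation-loss epoch; the
    per-epoch loss log is kept in the result.  Raises on non-finite loss
    (usually a too-large learning rate).
    """
    data = table.with_outcomes_only()
    model = initialize(data, config)
    schema = model.schema
    M = semantic_pair_matrix(graph, schema)
    lambdas = (config.lambda_len, config.lambda_crisp, config.lambda_sem)
    scale = model.penalty_scale

    train_mask, val_mask = _split_validation(data, config.validation_fraction, config.seed)
    X = data.memberships()
    y = data.outcomes()
    Xt, yt = X[train_mask], y[train_mask]
    Xv, yv = X[val_mask], y[val_mask]

    theta, w, b = model.theta, model.weights, float(model.intercept)
    lr = config.learning_rate
    beta1, beta2, eps = 0.9, 0.999, 1e-8
    m_t = [np.zeros_like(theta), np.zeros_like(w), 0.0]
    v_t = [np.zeros_like(theta), np.zeros_like(w), 0.0]

    def val_loss(theta, w, b):
        s, _, _, pred = _forward(theta, w, b, Xv)
        mse, p_len, p_crisp, p_sem = _loss_terms(s, pred, yv, lambdas, scale, M)
        return mse + p_len + p_crisp + p_sem

    history: list[dict] = []
    best = (val_loss(theta, w, b), 0, theta.copy(), w.copy(), b)
    since_best = 0
    for epoch in range(1, config.max_epochs + 1):
        g_theta, g_w, g_b, losses = _gradients(theta, w, b, Xt, yt, lambdas, scale, M)
        train_loss = sum(losses)
        if not np.isfinite(train_loss):
            raise RuntimeError(
                "non-finite training loss; try a smaller learning_rate "
                f"(current {lr})"
            )
        for i, (param, grad) in enumerate(((theta, g_theta), (w, g_w), (b, g_b))):
            m_t[i] = beta1 * m_t[i] + (1 - beta1) * grad
            v_t[i] = beta2 * v_t[i] + (1 - beta2) * np.square(grad)
            mhat = m_t[i] / (1 - beta1**epoch)
            vhat = v_t[i] / (1 - beta2**epoch)
            step = lr * mhat / (np.sqrt(vhat) + eps)
            if i == 0:
                theta = theta - step
            elif i == 1:
                w = w - step
            else:
                b = b - step
        vl = val_loss(theta, w, b)
        history.append(
            {"epoch": epoch, "train_loss": train_loss, "val_loss": vl,
             "mse": losses[0], "penalty_length": losses[1],
             "penalty_crispness": losses[2], "penalty_semantic": losses[3]}
        )
        if vl < best[0] - 1e-12:
            best = (vl, epoch, theta.copy(), w.copy(), b)
            since_best = 0
        else:
            since_best += 1
        if epoch >= config.min_epochs and since_best >= config.patience:
            break

    best_val, best_epoch, theta, w, b = best
    out = model.copy()
    out.theta, out.weights, out.intercept = theta, w, float(b)
    return TrainResult(model=out, history=history, best_epoch=best_epoch,
                       best_val_loss=float(best_val))
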