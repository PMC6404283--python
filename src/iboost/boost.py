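"""Block-wise boosting of offset elastic-net Cox fits.

Starting from a zero offset, each iteration picks one predictor block,
fits an elastic-net Cox model to it with the accumulated prediction as an
offset, and adds ``v`` times the fitted block contribution to the offset.
Two tuning variants are provided: per-iteration cross-validation over
(block, alpha, lambda), and a permutation rule that fixes alpha = 1 and
chooses each block's lambda as the median over permuted datasets of the
smallest lambda selecting nothing.

The final coefficient vector is exactly ``v`` times the sum of the
per-iteration updates.  The algorithm stops once the offset has remained
constant (null updates) for ``patience`` consecutive iterations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .core_survival import SurvivalOutcome, log_partial_likelihood
from .penalized_cox import (
    DEFAULT_ALPHA_GRID,
    BlockedCoefficients,
    BlockedDesign,
    ElasticNetConfig,
    cv_deviance,
    fit_enet_cox,
    lambda_max,
    make_lambda_path,
    stratified_event_folds,
)

__all__ = ["BoostConfig", "BoostState", "fit_iboost", "step_cv", "step_permutation", "permutation_lambda"]


@dataclass(frozen=True)
class BoostConfig:
    """Configuration for a boosting run.

    ``variant`` selects the tuning rule; ``v`` is the step length damping
    each accepted update; ``patience`` the number of consecutive constant-
    offset iterations required to stop; ``B`` the permutation count.
    """

    variant: Literal["cv", "permutation"] = "permutation"
    v: float = 0.1
    patience: int = 5
    max_iter: int = 2000
    B: int = 20
    alpha_grid: tuple = DEFAULT_ALPHA_GRID
    n_lambda: int = 20
    lambda_min_ratio: float = 0.01
    cv_folds: int = 5
    cv_repeats: int = 1
    seed: int | None = None

    def __post_init__(self):
        if self.variant not in ("cv", "permutation"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if not 0 < self.v <= 1:
            raise ValueError(f"step length v must lie in (0, 1], got {self.v}")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.B < 1:
            raise ValueError("B must be >= 1")


@dataclass
class IterationRecord:
    m: int
    block: int | None  # None for a null update
    alpha: float | None
    lam: float | None
    update_norm: float
    log_pl: float


@dataclass
class BoostState:
    """Mutable state of a boosting run plus its full history."""

    iteration: int
    offset: np.ndarray
    coefficients: BlockedCoefficients
    history: list[IterationRecord] = field(default_factory=list)
    stopped_by: str | None = None  # "patience" or "cap"

    @classmethod
    def initial(cls, design: BlockedDesign) -> "BoostState":
        return cls(0, np.zeros(design.n), BlockedCoefficients.zeros_like(design))


def permutation_lambda(
    X: np.ndarray,
    outcome: SurvivalOutcome,
    offset: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> float:
    """Permutation-calibrated LASSO penalty for one block.

    For each of B permutations, the rows of (time, event, offset) are
    jointly shuffled against X, breaking any predictor-outcome association;
    the smallest lambda selecting no variable (lambda_max at alpha = 1) is
    recorded, and the median over permutations is returned.  Fitting at the
    returned lambda selects nothing in at least half of the permuted sets.
    """
    n = X.shape[0]
    vals = np.empty(B)
    for b in range(B):
        perm = rng.permutation(n)
        vals[b] = lambda_max(X, outcome.subset(perm), offset[perm], alpha=1.0)
    return float(np.median(vals))


def step_permutation(
    state: BoostState,
    design: BlockedDesign,
    outcome: SurvivalOutcome,
    cfg: BoostConfig,
    rng: np.random.Generator,
):
    """One permutation-variant iteration: per-block LASSO at the permutation
    lambda, block chosen by offset partial likelihood, ties to the lowest
    block index.

    Returns (block index or None, ElasticNetConfig or None, update vector).
    """
    f = state.offset
    best = None  # (-logPL, k) — argmax logPL, ties to low k
    for k, X in enumerate(design.blocks):
        lam_k = permutation_lambda(X, outcome, f, cfg.B, rng)
        enet = ElasticNetConfig(alpha=1.0, lam=lam_k)
        beta_k = fit_enet_cox(X, outcome, f, enet)
        if not np.any(beta_k):
            continue
        ll = log_partial_likelihood(f + X @ beta_k, outcome)
        cand = (-ll, k)
        if best is None or cand < best[0]:
            best = (cand, enet, beta_k)
    if best is None:
        return None, None, None
    (_, k), enet, beta_k = best[0], best[1], best[2]
    return k, enet, beta_k


def step_cv(
    state: BoostState,
    design: BlockedDesign,
    outcome: SurvivalOutcome,
    cfg: BoostConfig,
    rng: np.random.Generator,
):
    """One CV-variant iteration: k-fold CV deviance over the full
    (block, alpha, lambda) grid with the current offset, then a full-data
    refit at the winning triple.
    """
    f = state.offset
    n = design.n
    fold_plans = [
        stratified_event_folds(outcome, cfg.cv_folds, rng) for _ in range(cfg.cv_repeats)
    ]
    best = None  # ((deviance, k, -alpha, -lam), k, enet)
    for k, X in enumerate(design.blocks):
        for alpha in cfg.alpha_grid:
            lmax = lambda_max(X, outcome, f, alpha)
            if lmax <= 0:
                continue
            path = make_lambda_path(lmax, cfg.n_lambda, cfg.lambda_min_ratio)
            dev = np.zeros(path.size)
            for labels in fold_plans:
                for fold in range(cfg.cv_folds):
                    train = np.flatnonzero(labels != fold)
                    beta = None
                    sub_outcome = outcome.subset(train)
                    for i, lam in enumerate(path):
                        beta = fit_enet_cox(
                            X[train], sub_outcome, f[train],
                            ElasticNetConfig(alpha, lam), beta0=beta, tol=1e-7,
                        )
                        dev[i] += cv_deviance(X, outcome, f, beta, train)
            dev /= cfg.cv_folds * cfg.cv_repeats
            i_best = int(np.argmin(dev))
            cand = (dev[i_best], k, -alpha, -path[i_best])
            if best is None or cand < best[0]:
                best = (cand, k, ElasticNetConfig(alpha, float(path[i_best])))
    if best is None:
        return None, None, None
    _, k, enet = best
    beta_k = fit_enet_cox(design.blocks[k], outcome, f, enet)
    if not np.any(beta_k):
        return None, None, None
    return k, enet, beta_k


def fit_iboost(
    design: BlockedDesign,
    outcome: SurvivalOutcome,
    cfg: BoostConfig,
) -> BoostState:
    """Run the boosting loop to completion.

    The design must already be standardized (unit-SD columns).  Returns the
    final state; ``state.stopped_by`` is ``"patience"`` when the offset was
    constant for ``cfg.patience`` consecutive iterations and ``"cap"`` when
    ``cfg.max_iter`` was reached.
    """
    if design.n != len(outcome):
        raise ValueError("design and outcome sample sizes differ")
    if outcome.n_events == 0:
        raise ValueError("at least one event is required")
    rng = np.random.default_rng(cfg.seed)
    step = step_cv if cfg.variant == "cv" else step_permutation

    state = BoostState.initial(design)
    quiet = 0
    while state.iteration < cfg.max_iter:
        m = state.iteration + 1
        k, enet, beta_k = step(state, design, outcome, cfg, rng)
        if k is None:
            quiet += 1
            state.history.append(
                IterationRecord(m, None, None, None, 0.0,
                                log_partial_likelihood(state.offset, outcome))
            )
        else:
            quiet = 0
            update = design.blocks[k] @ beta_k
            state.offset = state.offset + cfg.v * update
            state.coefficients.parts[k] = state.coefficients.parts[k] + cfg.v * beta_k
            state.history.append(
                IterationRecord(
                    m, k, enet.alpha, enet.lam,
                    float(np.linalg.norm(beta_k)),
                    log_partial_likelihood(state.offset, outcome),
                )
            )
        state.iteration = m
        if quiet >= cfg.patience:
            state.stopped_by = "patience"
            return state
    state.stopped_by = "cap"
    return state
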