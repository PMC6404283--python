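"""Prediction-assessment stack: C-index, NRI, risk correlation, MSE,
and the repeated stratified train/test split harness.

The C-index follows the usable-pair convention of Pencina-style
concordance for censored data; the NRI compares survival probabilities at
a fixed horizon (3 years by convention) and handles censoring before the
horizon with inverse-probability-of-censoring weights built from a
Kaplan–Meier estimate of the censoring distribution.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .core_survival import SurvivalOutcome, breslow_baseline, pl_gradient
from .penalized_cox import BlockedCoefficients, BlockedDesign

__all__ = [
    "c_index",
    "estimate_survival_prob",
    "nri",
    "risk_correlation",
    "mse_by_block",
    "stratified_splits",
    "SplitPlan",
]

DEFAULT_T0 = 3.0


class UndefinedResultError(ValueError):
    """The requested metric is undefined on this input."""


def c_index(risk_scores, outcome: SurvivalOutcome) -> float:
    """Concordance index over usable pairs.

    A pair is usable when the subject with the smaller observed time had an
    event (for tied observed times, when exactly one of the two had an
    event, the event subject counts as the shorter survivor; tied times
    with two events are excluded).  Concordant pairs score 1, tied risk
    scores 0.5.  A constant risk score — the empty-model case — therefore
    yields exactly 0.5.
    """
    r = np.asarray(risk_scores, dtype=float)
    if r.shape[0] != len(outcome):
        raise ValueError("risk score / outcome length mismatch")
    t, e = outcome.time, outcome.event
    ev = np.flatnonzero(e == 1)
    # usable[i, j]: event subject i vs any j observed longer (or censored at
    # the same time); ordered pairs, so each usable pair is counted once
    longer = (t[None, :] > t[ev, None]) | (
        (t[None, :] == t[ev, None]) & (e[None, :] == 0)
    )
    den = int(longer.sum())
    if den == 0:
        raise UndefinedResultError("no usable pairs for the C-index")
    conc = (r[ev, None] > r[None, :]) & longer
    tied = (r[ev, None] == r[None, :]) & longer
    return float((conc.sum() + 0.5 * tied.sum()) / den)


def _fit_univariate_cox(risk: np.ndarray, outcome: SurvivalOutcome) -> float:
    """Unpenalized one-covariate Cox fit by Newton's method on gamma."""
    x = risk - risk.mean()
    gamma = 0.0
    for _ in range(100):
        eta = gamma * x
        g = float(x @ pl_gradient(eta, outcome))
        # numerical second derivative via small symmetric difference of the
        # gradient (cheap and robust at d=1)
        h = 1e-5 * max(1.0, abs(gamma))
        g_hi = float(x @ pl_gradient((gamma + h) * x, outcome))
        g_lo = float(x @ pl_gradient((gamma - h) * x, outcome))
        hess = (g_hi - g_lo) / (2 * h)
        if hess >= -1e-12:
            break
        step = -g / hess
        step = float(np.clip(step, -2.0, 2.0))
        gamma += step
        if abs(step) < 1e-10:
            break
    return gamma


def estimate_survival_prob(
    train_risk,
    train_outcome: SurvivalOutcome,
    test_risk,
    t0: float = DEFAULT_T0,
) -> np.ndarray:
    """Survival probability at ``t0`` given a univariate risk score.

    Fits an unpenalized Cox model of the training outcome on the training
    risk score, estimates the Breslow cumulative baseline hazard, and
    returns ``exp(-H0(t0) * exp(gamma * (r - mean)))`` for the test risks.
    A constant training risk degrades gracefully to the marginal baseline
    survival at ``t0`` for every subject.
    """
    train_risk = np.asarray(train_risk, dtype=float)
    test_risk = np.asarray(test_risk, dtype=float)
    center = train_risk.mean()
    if np.ptp(train_risk) == 0:
        gamma = 0.0
    else:
        gamma = _fit_univariate_cox(train_risk, train_outcome)
    eta_train = gamma * (train_risk - center)
    H0 = breslow_baseline(eta_train, train_outcome)(t0)
    return np.exp(-H0 * np.exp(gamma * (test_risk - center)))


def _km_censoring_survival(outcome: SurvivalOutcome):
    """Kaplan–Meier estimate of the censoring survival function G(t).

    Censorings are the 'events' here; deaths are treated as censored
    observations of the censoring time.
    """
    order = np.argsort(outcome.time, kind="stable")
    t = outcome.time[order]
    cens = 1 - outcome.event[order]
    uniq = np.unique(t[cens == 1])
    n = t.shape[0]
    surv = []
    G = 1.0
    for u in uniq:
        at_risk = np.sum(t >= u)
        d = np.sum((t == u) & (cens == 1))
        if at_risk > 0:
            G *= 1.0 - d / at_risk
        surv.append(G)
    times = np.asarray(uniq)
    values = np.asarray(surv)

    def G_of(s):
        # left-continuous evaluation G(s-): probability of remaining
        # uncensored strictly before s
        idx = np.searchsorted(times, np.asarray(s, dtype=float), side="left")
        padded = np.concatenate([[1.0], values])
        return padded[idx]

    return G_of


def nri(
    q_base,
    q_new,
    outcome: SurvivalOutcome,
    t0: float = DEFAULT_T0,
    n_boot: int = 500,
    rng: np.random.Generator | None = None,
) -> tuple[float, tuple[float, float]]:
    """Censoring-weighted net reclassification improvement at horizon t0.

    Estimates ``P(q_new < q_base | T < t0) - P(q_new < q_base | T > t0)``
    where q are survival probabilities at t0 under the two models: positive
    when the candidate model moves short survivors toward higher predicted
    risk and long survivors toward lower.  Short survivors (event before
    t0) are weighted by 1/G(Y-), with G the Kaplan–Meier censoring
    survival; long survivors are subjects observed beyond t0.  On
    uncensored data this reduces to the plug-in difference of proportions.
    Returns (estimate, 95% bootstrap CI).
    """
    q_base = np.asarray(q_base, dtype=float)
    q_new = np.asarray(q_new, dtype=float)
    if q_base.shape != q_new.shape or q_base.shape[0] != len(outcome):
        raise ValueError("probability vectors / outcome length mismatch")
    if rng is None:
        rng = np.random.default_rng()

    def point_estimate(o: SurvivalOutcome, qb, qn) -> float:
        G = _km_censoring_survival(o)
        short = (o.time < t0) & (o.event == 1)
        long_ = o.time > t0
        if not short.any():
            raise UndefinedResultError(f"no events before t0={t0}")
        if not long_.any():
            raise UndefinedResultError(f"no subjects observed beyond t0={t0}")
        w = 1.0 / np.maximum(G(o.time[short]), 1e-10)
        improved_short = (qn[short] < qb[short]).astype(float)
        p_short = float(w @ improved_short / w.sum())
        p_long = float(np.mean(qn[long_] < qb[long_]))
        return p_short - p_long

    est = point_estimate(outcome, q_base, q_new)
    boots = []
    n = len(outcome)
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        try:
            boots.append(point_estimate(outcome.subset(idx), q_base[idx], q_new[idx]))
        except (UndefinedResultError, ValueError):
            continue
    if boots:
        lo, hi = np.percentile(boots, [2.5, 97.5])
    else:
        lo = hi = float("nan")
    return est, (float(lo), float(hi))


def risk_correlation(
    beta_hat: BlockedCoefficients,
    beta_true: BlockedCoefficients,
    design: BlockedDesign,
) -> float:
    """Pearson correlation of estimated and true risk scores on ``design``."""
    r_hat = beta_hat.linear_predictor(design)
    r_true = beta_true.linear_predictor(design)
    if np.ptp(r_hat) == 0 or np.ptp(r_true) == 0:
        raise UndefinedResultError("constant risk score: correlation undefined")
    return float(np.corrcoef(r_hat, r_true)[0, 1])


def mse_by_block(
    beta_hat: BlockedCoefficients, beta_true: BlockedCoefficients
) -> tuple[dict[str, float], float]:
    """Per-block squared L2 distance between coefficient vectors, plus total."""
    if beta_hat.block_names != beta_true.block_names:
        raise ValueError("block name mismatch")
    per_block = {}
    for name, p_hat, p_true in zip(beta_hat.block_names, beta_hat.parts, beta_true.parts):
        if p_hat.shape != p_true.shape:
            raise ValueError(f"dimension mismatch in block {name!r}")
        per_block[name] = float(np.sum((p_hat - p_true) ** 2))
    return per_block, float(sum(per_block.values()))


@dataclass
class SplitPlan:
    """A list of (train_ids, test_ids) index pairs sharing one stratification."""

    splits: list[tuple[np.ndarray, np.ndarray]]
    strata: np.ndarray

    def __iter__(self):
        return iter(self.splits)

    def __len__(self):
        return len(self.splits)


def stratified_splits(
    strata_labels,
    n_splits: int = 30,
    train_fraction: float = 0.6,
    rng: np.random.Generator | None = None,
) -> SplitPlan:
    """Repeated stratified train/test splits at a 3:2 ratio by default.

    Within each stratum, round(train_fraction * size) subjects go to
    training; singleton strata are assigned to training with a warning.
    """
    labels = np.asarray(strata_labels)
    if rng is None:
        rng = np.random.default_rng()
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie in (0, 1)")
    uniq = np.unique(labels)
    for u in uniq:
        if np.sum(labels == u) == 1:
            warnings.warn(
                f"stratum {u!r} has a single member; assigned to training",
                stacklevel=2,
            )
    splits = []
    for _ in range(n_splits):
        train_idx, test_idx = [], []
        for u in uniq:
            members = np.flatnonzero(labels == u)
            if members.size == 1:
                train_idx.append(members)
                continue
            perm = rng.permutation(members)
            n_train = int(np.floor(train_fraction * members.size + 0.5))
            n_train = min(max(n_train, 1), members.size - 1)
            train_idx.append(perm[:n_train])
            test_idx.append(perm[n_train:])
        splits.append(
            (np.sort(np.concatenate(train_idx)), np.sort(np.concatenate(test_idx)))
        )
    return SplitPlan(splits, labels)
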