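"""Cox partial-likelihood machinery with offset support.

All quantities are parameterized through the linear predictor
``eta_i = f_i + x_i' beta`` so that offsets (fixed contributions from
earlier boosting iterations) come for free.  Tied event times are handled
with the Breslow convention throughout, and risk sets are closed on the
left: a subject censored exactly at an event time is at risk for that
event.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SurvivalOutcome",
    "BaselineHazard",
    "log_partial_likelihood",
    "pl_gradient",
    "pl_weights",
    "breslow_baseline",
]


class DimensionError(ValueError):
    """Input arrays have incompatible lengths."""


class DegenerateInputError(ValueError):
    """Input lacks the structure needed for estimation (e.g. no events)."""


@dataclass(frozen=True)
class SurvivalOutcome:
    """Right-censored follow-up: observed time and event indicator.

    Parameters
    ----------
    time : array-like of float
        Observed follow-up, min(survival, censoring); strictly positive.
    event : array-like of {0, 1}
        1 if death observed, 0 if censored.
    """

    time: np.ndarray
    event: np.ndarray

    def __init__(self, time, event):
        time = np.asarray(time, dtype=float)
        event = np.asarray(event)
        if time.ndim != 1 or event.ndim != 1:
            raise DimensionError("time and event must be 1-dimensional")
        if time.shape != event.shape:
            raise DimensionError(
                f"time has length {time.shape[0]} but event has length {event.shape[0]}"
            )
        if not np.all(np.isfinite(time)) or np.any(time <= 0):
            raise ValueError("all follow-up times must be finite and > 0")
        uniq = np.unique(event)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError(f"event indicator must be 0/1, got values {uniq}")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "event", event.astype(np.int8))

    def __len__(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def subset(self, idx) -> "SurvivalOutcome":
        return SurvivalOutcome(self.time[idx], self.event[idx])


@dataclass(frozen=True)
class BaselineHazard:
    """Right-continuous step estimate of the cumulative baseline hazard."""

    times: np.ndarray
    cumulative_hazard: np.ndarray

    def __call__(self, t) -> np.ndarray:
        """Evaluate H0 at times ``t`` (0 before the first event time)."""
        idx = np.searchsorted(self.times, np.asarray(t, dtype=float), side="right")
        padded = np.concatenate([[0.0], self.cumulative_hazard])
        return padded[idx]


def _check(eta: np.ndarray, outcome: SurvivalOutcome) -> np.ndarray:
    eta = np.asarray(eta, dtype=float)
    if eta.ndim != 1 or eta.shape[0] != len(outcome):
        raise DimensionError(
            f"linear predictor has length {eta.shape[0] if eta.ndim == 1 else eta.shape},"
            f" expected {len(outcome)}"
        )
    if not np.all(np.isfinite(eta)):
        raise ValueError("linear predictor contains non-finite entries")
    if outcome.n_events == 0:
        raise DegenerateInputError("at least one observed event is required")
    return eta


def _risk_quantities(eta: np.ndarray, outcome: SurvivalOutcome):
    """Sorted-order helper quantities shared by all operations.

    Returns (order, S, first_of_tie) where ``order`` sorts times ascending,
    ``S[i]`` is the at-risk sum of exp(eta - max eta) for the tie group of
    the i-th sorted subject, and everything is in sorted order.
    """
    order = np.argsort(outcome.time, kind="stable")
    t = outcome.time[order]
    e = eta[order]
    m = e.max()
    w = np.exp(e - m)
    # reverse cumulative sum: total weight of {j : Y_j >= Y_i}
    rcs = np.cumsum(w[::-1])[::-1]
    # tie groups share the risk set of their first (lowest-index) member
    first = np.zeros(t.shape[0], dtype=np.intp)
    new_group = np.empty(t.shape[0], dtype=bool)
    new_group[0] = True
    new_group[1:] = t[1:] != t[:-1]
    first = np.maximum.accumulate(np.where(new_group, np.arange(t.shape[0]), 0))
    S = rcs[first]
    return order, t, w, S, m


def log_partial_likelihood(eta, outcome: SurvivalOutcome) -> float:
    """Log Cox partial likelihood at linear predictor ``eta``.

    Sum over events of ``eta_i - log sum_{j: Y_j >= Y_i} exp(eta_j)``,
    stabilized by subtracting max(eta) before exponentiation.  Invariant
    under adding a constant to ``eta``.
    """
    eta = _check(eta, outcome)
    order, _, _, S, m = _risk_quantities(eta, outcome)
    d = outcome.event[order].astype(bool)
    return float(np.sum(eta[order][d] - (np.log(S[d]) + m)))


def pl_gradient(eta, outcome: SurvivalOutcome) -> np.ndarray:
    """Gradient of the log partial likelihood with respect to ``eta``.

    ``g_i = event_i - exp(eta_i) * H0(Y_i)`` with H0 the Breslow
    cumulative hazard at the current eta; components sum to zero.
    """
    eta = _check(eta, outcome)
    order, t, w, S, _ = _risk_quantities(eta, outcome)
    d = outcome.event[order].astype(float)
    # cumulative sum over event times <= Y_i of d_t / S(t), in sorted order
    inc = d / S
    H = np.cumsum(inc)
    # within a tie group every member gets the full group's hazard mass
    # (risk sets are closed: Y_j >= Y_i), so use the last index of the group
    n = t.shape[0]
    last = np.empty(n, dtype=np.intp)
    new_group = np.empty(n, dtype=bool)
    new_group[:-1] = t[:-1] != t[1:]
    new_group[-1] = True
    idx = np.where(new_group, np.arange(n), n - 1)
    last = np.minimum.accumulate(idx[::-1])[::-1]
    # w = exp(eta - m) and S uses the same scale, so w * H cancels the
    # max-shift exactly: w_i * d_t / S(t) = exp(eta_i) * d_t / S_true(t)
    g_sorted = d - w * H[last]
    g = np.empty_like(g_sorted)
    g[order] = g_sorted
    return g


def pl_weights(eta, outcome: SurvivalOutcome) -> np.ndarray:
    """Diagonal of the negative Hessian of the log partial likelihood.

    ``w_i = exp(eta_i) H0(Y_i) - exp(2 eta_i) sum_{t <= Y_i} d_t / S(t)^2``,
    the standard diagonal used as IRLS weights by coordinate-descent Cox
    solvers.  Non-negative.
    """
    eta = _check(eta, outcome)
    order, t, w, S, _ = _risk_quantities(eta, outcome)
    d = outcome.event[order].astype(float)
    n = t.shape[0]
    new_group = np.empty(n, dtype=bool)
    new_group[:-1] = t[:-1] != t[1:]
    new_group[-1] = True
    idx = np.where(new_group, np.arange(n), n - 1)
    last = np.minimum.accumulate(idx[::-1])[::-1]
    H1 = np.cumsum(d / S)[last]
    H2 = np.cumsum(d / S**2)[last]
    w_sorted = w * H1 - w**2 * H2
    out = np.empty_like(w_sorted)
    out[order] = np.maximum(w_sorted, 0.0)
    return out


def breslow_baseline(eta, outcome: SurvivalOutcome) -> BaselineHazard:
    """Breslow estimate of the cumulative baseline hazard.

    Increment ``d_t / sum_{j: Y_j >= t} exp(eta_j)`` at each distinct
    event time ``t`` (``d_t`` = number of events at ``t``).
    """
    eta = _check(eta, outcome)
    order, t, w, S, _ = _risk_quantities(eta, outcome)
    d = outcome.event[order].astype(float)
    # scale: S was computed on exp(eta - m); divide increments by exp(m)
    # implicitly by using the same scaled weights in numerator count d.
    event_mask = d > 0
    times_e = t[event_mask]
    uniq_times, inverse = np.unique(times_e, return_inverse=True)
    d_t = np.bincount(inverse)
    # risk-set sum at each unique event time, on the true scale
    m = eta.max()
    S_true = S * np.exp(m)
    # S is constant within a tie group; take it at the first event of each group
    first_event_idx = np.searchsorted(t, uniq_times, side="left")
    S_at = S_true[first_event_idx]
    increments = d_t / S_at
    return BaselineHazard(uniq_times, np.cumsum(increments))
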