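import numpy as np
import pytest

from iboost import SurvivalOutcome
from iboost.penalized_cox import standardize


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_survival(rng, n, censor_frac=0.3, beta=None, X=None):
    """Small random censored dataset for oracle comparisons."""
    if X is not None and beta is not None:
        eta = X @ beta
    else:
        eta = np.zeros(n)
    T = np.sqrt(2.0 * rng.exponential(size=n) * np.exp(-eta))
    C = np.quantile(T, 1 - censor_frac) * rng.uniform(0.2, 1.5, size=n)
    time = np.minimum(T, C) + 1e-9
    event = (T <= C).astype(int)
    if event.sum() == 0:
        event[np.argmin(time)] = 1
    return SurvivalOutcome(time, event)


@pytest.fixture
def small_cox_problem(rng):
    """n=30, d=5 standardized design with real signal, ~30% censoring."""
    n, d = 30, 5
    X = rng.standard_normal((n, d))
    X, _ = standardize(X)
    beta = np.array([1.0, -0.5, 0.0, 0.0, 0.3])
    outcome = random_survival(rng, n, beta=beta, X=X)
    return X, outcome, beta


def naive_log_partial_likelihood(eta, time, event):
    """Double-loop risk-set oracle for the Breslow log partial likelihood."""
    total = 0.0
    n = len(time)
    for i in range(n):
        if not event[i]:
            continue
        denom = sum(np.exp(eta[j]) for j in range(n) if time[j] >= time[i])
        total += eta[i] - np.log(denom)
    return total


def naive_breslow(eta, time, event):
    """Direct-summation oracle for the Breslow cumulative hazard."""
    uniq = np.unique(time[event == 1])
    cum, out = 0.0, []
    for t in uniq:
        d_t = int(np.sum((time == t) & (event == 1)))
        denom = np.sum(np.exp(eta[time >= t]))
        cum += d_t / denom
        out.append(cum)
    return uniq, np.asarray(out)


def naive_c_index(risk, time, event):
    """Brute-force pairwise concordance oracle."""
    num, den = 0.0, 0
    n = len(time)
    for i in range(n):
        for j in range(n):
            if i == j or not event[i]:
                continue
            if time[j] > time[i] or (time[j] == time[i] and not event[j]):
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
    return num / den
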