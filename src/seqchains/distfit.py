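"""Maximum-likelihood comparison of rank–frequency distribution families.

A unit inventory induces counts over ranks r = 1..S (S = number of unit
types).  Three families of rank-indexed category probabilities are fitted
by maximum likelihood and compared by AIC:

* uniform       p_r = 1/S                  (0 parameters)
* power law     p_r ∝ r^(-a), a >= 0       (1 parameter)
* exponential   p_r ∝ exp(-λ r), λ >= 0    (1 parameter)

The log-likelihood is the multinomial log-likelihood of the observed counts
with the constant multinomial coefficient omitted (identical across
families, so AIC differences are unaffected).  AIC values are converted to
Akaike relative probabilities: Δi = AICi − min AIC, Li = exp(−Δi/2),
w_i = Li / Σ L.  The power law nests the uniform at a = 0, so its maximized
log-likelihood is never below the uniform's; AIC charges it one parameter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

__all__ = ["FAMILIES", "DistributionFit", "fit_family", "akaike_weights", "compare_families"]

FAMILIES = ("uniform", "power_law", "exponential")

_BOUNDS = {"power_law": (0.0, 10.0), "exponential": (0.0, 10.0)}
_XATOL = 1e-8


@dataclass(frozen=True)
class DistributionFit:
    """One family fitted to one rank–frequency table."""

    family: str
    params: dict[str, float]
    loglik: float
    k: int
    aic: float
    rel_prob: float | None = None


def _counts(table) -> np.ndarray:
    if isinstance(table, pd.DataFrame):
        counts = np.asarray(table["frequency"], dtype=float)
    else:
        counts = np.asarray(table, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need counts for at least two ranks")
    if np.any(counts < 1):
        raise ValueError("all counts must be >= 1")
    return counts


def _loglik(counts: np.ndarray, log_p: np.ndarray) -> float:
    return float(np.sum(counts * log_p))


def _log_probs(family: str, s: int, theta: float) -> np.ndarray:
    r = np.arange(1, s + 1, dtype=float)
    if family == "uniform":
        logw = np.zeros(s)
    elif family == "power_law":
        logw = -theta * np.log(r)
    elif family == "exponential":
        logw = -theta * r
    else:
        raise ValueError(f"unknown family {family!r}")
    logw -= logw.max()  # stabilize the normalizer
    return logw - np.log(np.sum(np.exp(logw)))


def fit_family(table, family: str) -> DistributionFit:
    """Fit one family to a rank–frequency table by maximum likelihood.

    *table* is a rank table (:func:`seqchains.metrics.rank_table` output,
    frequencies in rank order) or a plain descending count array.  The
    1-parameter families are maximized by bounded scalar optimization on
    [0, 10] with tolerance 1e-8.
    """
    counts = _counts(table)
    s = len(counts)
    if family == "uniform":
        ll = _loglik(counts, _log_probs("uniform", s, 0.0))
        params: dict[str, float] = {}
        k = 0
    elif family in ("power_law", "exponential"):
        def neg_ll(theta: float) -> float:
            return -_loglik(counts, _log_probs(family, s, theta))

        res = minimize_scalar(
            neg_ll, bounds=_BOUNDS[family], method="bounded",
            options={"xatol": _XATOL},
        )
        if not res.success:
            raise RuntimeError(f"MLE for {family} did not converge: {res.message}")
        theta = float(res.x)
        ll = -float(res.fun)
        # the bounded optimizer stays epsilon inside the bracket; when the
        # optimum sits at theta = 0 (uniform limit) take the endpoint exactly
        ll0 = _loglik(counts, _log_probs(family, s, 0.0))
        if ll0 >= ll:
            theta, ll = 0.0, ll0
        params = {"exponent" if family == "power_law" else "rate": theta}
        k = 1
    else:
        raise ValueError(f"unknown family {family!r}; choose one of {FAMILIES}")
    return DistributionFit(family=family, params=params, loglik=ll, k=k, aic=2 * k - 2 * ll)


def akaike_weights(aics) -> np.ndarray:
    """Akaike relative probabilities from a vector of AIC values."""
    aics = np.asarray(aics, dtype=float)
    rel = np.exp(-(aics - aics.min()) / 2.0)
    return rel / rel.sum()


def compare_families(table) -> list[DistributionFit]:
    """Fit all three families and fill in Akaike relative probabilities.

    Returns fits in :data:`FAMILIES` order; their ``rel_prob`` values sum
    to one.
    """
    fits = [fit_family(table, fam) for fam in FAMILIES]
    weights = akaike_weights([f.aic for f in fits])
    return [replace(f, rel_prob=float(w)) for f, w in zip(fits, weights)]
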