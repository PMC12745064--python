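"""Zipf's law of abbreviation and the reaction-time/TP association.

Zipf's law of abbreviation — frequent units tend to be short — is tested at
the unit-type level: one observation per unit type, outcome the unit's
token frequency, fitted with a log-link Poisson regression on unit length
(optionally interacted with generation, or with a produced-vs-random
flag).  A type-level Pearson correlation between log frequency and length
complements the regression.

The reaction-time analysis asks whether learners are sensitive to the
trigram statistics of their input: after standard RT filtering (absolute
floor, then per-participant 2-SD trimming), log reaction time is regressed
on the transitional probability of the produced transition, sequence
position, and generation.  Negative TP slopes mean faster keypresses for
more predictable transitions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .metrics import UnitInventory
from .seqdata import ReproductionEvent
from .segmentation import TrigramModel, UnseenContextError

__all__ = [
    "GlmFit",
    "poisson_freq_length",
    "freq_length_correlation",
    "filter_rts",
    "build_rt_table",
    "rt_tp_association",
]

logger = logging.getLogger(__name__)

POISSON_TOL = 1e-8
RT_FLOOR_MS = 100.0
RT_SD_RANGE = 2.0


@dataclass(frozen=True)
class GlmFit:
    """A fitted regression: named coefficients, standard errors, and z/t
    statistics, with the family and the observation count."""

    params: dict[str, float]
    bse: dict[str, float]
    tvalues: dict[str, float]
    family: str
    n: int

    @classmethod
    def from_statsmodels(cls, res, family: str) -> "GlmFit":
        return cls(
            params={k: float(v) for k, v in res.params.items()},
            bse={k: float(v) for k, v in res.bse.items()},
            tvalues={k: float(v) for k, v in res.tvalues.items()},
            family=family,
            n=int(res.nobs),
        )


_FORMULAS = ("length", "length_x_generation", "length_x_produced")


def _design(units: pd.DataFrame, formula: str) -> pd.DataFrame:
    X = pd.DataFrame({"const": 1.0, "length": units["length"].astype(float)})
    if formula == "length":
        pass
    elif formula == "length_x_generation":
        X["generation"] = units["generation"].astype(float)
        X["length:generation"] = X["length"] * X["generation"]
    elif formula == "length_x_produced":
        X["is_produced"] = units["is_produced"].astype(float)
        X["length:is_produced"] = X["length"] * X["is_produced"]
    else:
        raise ValueError(f"unknown formula {formula!r}; choose one of {_FORMULAS}")
    return X


def poisson_freq_length(units: pd.DataFrame, formula: str = "length") -> GlmFit:
    """Log-link Poisson regression of unit frequency on unit length.

    *units* holds one row per unit type (per set) with columns
    ``frequency`` and ``length``, plus ``generation`` or ``is_produced``
    for the interaction variants.  Fitted by IRLS to tolerance 1e-8.
    """
    freq = units["frequency"].to_numpy()
    if np.any(freq < 1) or not np.allclose(freq, np.round(freq)):
        raise ValueError("frequencies must be positive integers")
    if units["length"].nunique() < 2:
        raise ValueError("need at least two distinct unit lengths")
    X = _design(units, formula)
    model = sm.GLM(freq.astype(float), X, family=sm.families.Poisson())
    res = model.fit(tol=POISSON_TOL, maxiter=200)
    if not res.converged:
        raise RuntimeError(
            f"Poisson IRLS did not converge in {res.fit_history['iteration']} iterations"
        )
    return GlmFit.from_statsmodels(res, family="poisson-log")


def freq_length_correlation(inv: UnitInventory | pd.DataFrame) -> float:
    """Pearson correlation between log token frequency and unit length,
    one point per unit type."""
    if isinstance(inv, UnitInventory):
        freqs = np.array(list(inv.freq.values()), dtype=float)
        lengths = np.array([len(u) for u in inv.freq], dtype=float)
    else:
        freqs = inv["frequency"].to_numpy(dtype=float)
        lengths = inv["length"].to_numpy(dtype=float)
    if len(freqs) < 3:
        raise ValueError("need at least 3 unit types")
    logf = np.log(freqs)
    if np.isclose(logf.var(), 0.0) or np.isclose(lengths.var(), 0.0):
        raise ValueError("zero variance in log frequency or length; correlation undefined")
    r, _ = stats.pearsonr(logf, lengths)
    return float(r)


def filter_rts(events: Iterable[ReproductionEvent] | pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Standard reaction-time filtering for keypress data.

    Step 1 drops keypresses faster than 100 ms; step 2 drops, per
    participant (one agent per chain × generation), rows outside the
    participant's mean ± 2 SD computed on the step-1 survivors.  Rows
    exactly on a bound are retained, and a participant with fewer than two
    surviving keypresses keeps all of them (SD undefined; a warning is
    logged).  Returns the filtered keypress table and a report of the row
    counts dropped at each step.
    """
    if isinstance(events, pd.DataFrame):
        df = events.copy()
    else:
        rows = []
        for ev in events:
            for pos, rt in enumerate(ev.rts, start=1):
                rows.append(
                    {"chain_id": ev.chain_id, "generation": ev.generation,
                     "trial_index": ev.trial_index, "position": pos,
                     "symbol": ev.produced[pos - 1], "rt_ms": float(rt)}
                )
        df = pd.DataFrame(rows)
    n0 = len(df)
    df = df[df["rt_ms"] >= RT_FLOOR_MS]
    n_floor = n0 - len(df)

    keep = pd.Series(True, index=df.index)
    for (cid, gen), grp in df.groupby(["chain_id", "generation"], dropna=False):
        if len(grp) < 2:
            logger.warning(
                "participant (%s, %s) has %d keypress(es); SD undefined, rows retained",
                cid, gen, len(grp),
            )
            continue
        m = grp["rt_ms"].mean()
        sd = grp["rt_ms"].std(ddof=1)
        lo, hi = m - RT_SD_RANGE * sd, m + RT_SD_RANGE * sd
        keep.loc[grp.index] = (grp["rt_ms"] >= lo) & (grp["rt_ms"] <= hi)
    n_sd = int((~keep).sum())
    out = df[keep].reset_index(drop=True)
    report = {"n_input": n0, "dropped_floor": n_floor, "dropped_sd": n_sd, "n_kept": len(out)}
    return out, report


def build_rt_table(
    events: Iterable[ReproductionEvent],
    models_by_generation: Mapping[int, TrigramModel],
) -> pd.DataFrame:
    """Attach transitional probabilities to filtered keypress rows.

    ``models_by_generation[g]`` must be the trigram model of the set the
    generation-*g* participant experienced (their input set).  TPs are
    evaluated on the produced sequence, so only positions 3..L carry a TP;
    earlier positions and transitions through unseen contexts are dropped.
    Filtering (:func:`filter_rts`) is applied first.
    """
    events = list(events)
    filtered, _ = filter_rts(events)
    key = filtered.set_index(["chain_id", "generation", "trial_index", "position"]).index
    kept = set(key)
    rows = []
    for ev in events:
        model = models_by_generation[ev.generation]
        toks = ev.produced.tokens
        for pos in range(3, len(toks) + 1):
            if (ev.chain_id, ev.generation, ev.trial_index, pos) not in kept:
                continue
            try:
                tp = model.tp(toks[pos - 3], toks[pos - 2], toks[pos - 1])
            except UnseenContextError:
                continue
            rows.append(
                {"chain_id": ev.chain_id, "generation": ev.generation,
                 "trial_index": ev.trial_index, "position": pos,
                 "symbol": toks[pos - 1], "tp": tp,
                 "rt_ms": ev.rts[pos - 1], "log_rt": math.log(ev.rts[pos - 1])}
            )
    return pd.DataFrame(rows)


def rt_tp_association(rt_table: pd.DataFrame) -> GlmFit:
    """OLS of log reaction time on transitional probability, sequence
    position, and generation (fixed effects only).

    A nuisance term (position or generation) that is constant in the data —
    e.g. a single-generation table — is dropped with a log message rather
    than left to break the design; a genuinely collinear design still
    raises.
    """
    if len(rt_table) < 10:
        raise ValueError("need at least 10 keypress rows")
    if "log_rt" in rt_table.columns:
        y = rt_table["log_rt"].astype(float)
    else:
        y = np.log(rt_table["rt_ms"].astype(float))
    X = pd.DataFrame({"const": 1.0, "tp": rt_table["tp"].astype(float)})
    for term in ("position", "generation"):
        col = rt_table[term].astype(float)
        if col.nunique() > 1:
            X[term] = col
        else:
            logger.info("dropping constant predictor %r from the RT model", term)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank-deficient (collinear predictors)")
    res = sm.OLS(y, X).fit()
    return GlmFit.from_statsmodels(res, family="gaussian-identity")
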