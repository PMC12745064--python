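"""Compression-based complexity of sequence sets and its relation to
structure and learnability.

Kolmogorov complexity is uncomputable; a standard proxy is the compressed
size of a canonical serialization under a dictionary compressor.  Here the
set is serialized as one character per token with newline-separated
sequences and compressed with DEFLATE (zlib) at maximum level; the
compressed byte count is the complexity estimate.  Repetitive, structured
sets compress to fewer bytes than random ones of the same shape.

Cultural transmission generally simplifies its material, so a falling
complexity curve alone cannot show that *statistical* structure (coherent
units, Zipfian frequencies) is doing the work.  The regression utilities
here ask whether the log–log rank–frequency R² predicts transmission error
over and above raw compressibility.
"""

from __future__ import annotations

import zlib

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .seqdata import SequenceSet

__all__ = ["COMPRESSOR", "kolmogorov_estimate", "structure_vs_complexity"]

#: compressor identity, recorded in pipeline manifests
COMPRESSOR = "zlib (DEFLATE), level 9"


def serialize_set(sset: SequenceSet) -> bytes:
    """Canonical byte serialization: one char per token, one sequence per
    line, trailing newline, UTF-8."""
    return "".join(f"{s}\n" for s in sset.sequences).encode("utf-8")


def kolmogorov_estimate(sset: SequenceSet) -> int:
    """Byte length of the set's canonical serialization after DEFLATE at
    maximum compression.  Deterministic; *not* invariant to sequence order
    in general (the compressor window sees order)."""
    return len(zlib.compress(serialize_set(sset), 9))


def structure_vs_complexity(chain_metrics: pd.DataFrame) -> dict:
    """Relate per-set complexity, Zipfian fit, and transmission error.

    *chain_metrics* holds one row per set with columns ``complexity``,
    ``r2``, ``mean_error`` and optionally ``entropy``; seed sets of
    generation zero should already be excluded (they have no reproduction
    error and are random by construction).  Requires at least 3 rows.

    Returns Pearson correlations (with p-values) between complexity and R²,
    entropy and mean error, R² and mean error, plus the coefficient table
    of the OLS fit ``mean_error ~ r2 + complexity``.
    """
    df = chain_metrics.dropna(subset=["complexity", "r2", "mean_error"])
    if len(df) < 3:
        raise ValueError("need at least 3 sets for correlation analysis")
    for col in ("complexity", "r2", "mean_error"):
        if np.isclose(np.var(df[col].to_numpy(dtype=float)), 0.0):
            raise ValueError(f"column {col!r} is constant; correlation undefined")
    out: dict = {"n": len(df)}
    r, p = stats.pearsonr(df["complexity"], df["r2"])
    out["r_complexity_r2"] = (float(r), float(p))
    r, p = stats.pearsonr(df["r2"], df["mean_error"])
    out["r_r2_error"] = (float(r), float(p))
    if "entropy" in df.columns and not df["entropy"].isna().any():
        r, p = stats.pearsonr(df["entropy"], df["mean_error"])
        out["r_entropy_error"] = (float(r), float(p))
    X = sm.add_constant(df[["r2", "complexity"]].astype(float))
    fit = sm.OLS(df["mean_error"].astype(float), X).fit()
    out["ols_params"] = dict(fit.params)
    out["ols_bse"] = dict(fit.bse)
    out["ols_rsquared"] = float(fit.rsquared)
    return out
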