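"""Transmission-error and unit-inventory statistics.

Covers the per-set measurements of the transmission-chain analysis:
normalized Levenshtein transmission error, unit frequency inventories and
their Shannon entropy, rank–frequency tables with the log–log R² measure of
Zipfian shape, and the within- vs between-unit transitional-probability
contrast that quantifies the statistical coherence of segmented units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

from .seqdata import ColorSequence
from .segmentation import SegmentationResult, TrigramModel

__all__ = [
    "levenshtein",
    "normalized_levenshtein",
    "transmission_error",
    "transmission_success",
    "UnitInventory",
    "unit_inventory",
    "shannon_entropy",
    "normalized_entropy",
    "rank_table",
    "loglog_r2",
    "Coherence",
    "coherence",
    "set_summary",
]


def _tokens(seq: ColorSequence | str | Iterable[str]) -> tuple[str, ...]:
    if isinstance(seq, ColorSequence):
        return seq.tokens
    return tuple(seq)


def levenshtein(a, b) -> int:
    """Plain edit distance (insertions, deletions, substitutions), by the
    standard two-row dynamic program."""
    s, t = _tokens(a), _tokens(b)
    if len(s) < len(t):
        s, t = t, s
    prev = list(range(len(t) + 1))
    for i, ca in enumerate(s, start=1):
        cur = [i]
        for j, cb in enumerate(t, start=1):
            cur.append(min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb)))
        prev = cur
    return prev[-1]


def normalized_levenshtein(a, b) -> float:
    """Edit distance divided by the length of the longer sequence; in [0, 1]."""
    s, t = _tokens(a), _tokens(b)
    if not s or not t:
        raise ValueError("sequences must be non-empty")
    return levenshtein(s, t) / max(len(s), len(t))


def transmission_error(seen, produced) -> float:
    """Normalized Levenshtein distance between the seen and produced sequence."""
    return normalized_levenshtein(seen, produced)


def transmission_success(seen, produced) -> int:
    """1 if the sequence was reproduced exactly (error 0), else 0."""
    return int(transmission_error(seen, produced) == 0.0)


@dataclass(frozen=True)
class UnitInventory:
    """Unit-type → token-frequency table of one segmented set.

    ``n_types`` is the number of distinct units ("set size"); ``n_tokens``
    the total number of unit tokens.
    """

    freq: dict[str, int]

    def __post_init__(self) -> None:
        if not self.freq:
            raise ValueError("inventory must contain at least one unit")
        if any(c < 1 for c in self.freq.values()):
            raise ValueError("all unit frequencies must be >= 1")

    @property
    def n_types(self) -> int:
        return len(self.freq)

    @property
    def n_tokens(self) -> int:
        return sum(self.freq.values())

    @classmethod
    def from_units(cls, units: Iterable[Iterable[str]]) -> "UnitInventory":
        freq: dict[str, int] = {}
        for seq_units in units:
            for u in seq_units:
                freq[u] = freq.get(u, 0) + 1
        return cls(freq)


def unit_inventory(segresult: SegmentationResult) -> UnitInventory:
    """Count every unit token across the whole segmented set."""
    return UnitInventory.from_units(segresult.units())


def shannon_entropy(inv: UnitInventory) -> float:
    """Shannon entropy H = -sum p log2 p (bits) of the unit frequencies."""
    n = inv.n_tokens
    return -sum((c / n) * math.log2(c / n) for c in inv.freq.values())


def normalized_entropy(inv: UnitInventory) -> float:
    """Entropy efficiency H / log2(n_types), in [0, 1].

    A single-type inventory has H = 0 and an undefined 0/0 ratio; by
    convention 0 is returned for it.
    """
    if inv.n_types == 1:
        return 0.0
    return shannon_entropy(inv) / math.log2(inv.n_types)


def rank_table(inv: UnitInventory) -> pd.DataFrame:
    """Rank–frequency table: columns ``rank`` (1..n_types), ``unit``,
    ``frequency``, ``length``, ranked by descending frequency with ties
    broken by unit string ascending (so the table is deterministic)."""
    items = sorted(inv.freq.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "rank": np.arange(1, len(items) + 1),
            "unit": [u for u, _ in items],
            "frequency": [c for _, c in items],
            "length": [len(u) for u, _ in items],
        }
    )


def loglog_r2(table: pd.DataFrame) -> float:
    """R² of the OLS fit of log frequency on log rank.

    High values indicate a rank–frequency relation close to a power law
    (log-log linear).  Requires at least two unit types; when all
    frequencies are equal (zero variance in log frequency) the convention
    R² = 0 is returned.
    """
    freq = np.asarray(table["frequency"], dtype=float)
    rank = np.asarray(table["rank"], dtype=float)
    if len(freq) < 2:
        raise ValueError("log-log R^2 needs at least two unit types")
    y = np.log(freq)
    x = np.log(rank)
    sst = float(np.sum((y - y.mean()) ** 2))
    if sst == 0.0:
        return 0.0
    sxx = float(np.sum((x - x.mean()) ** 2))
    sxy = float(np.sum((x - x.mean()) * (y - y.mean())))
    return (sxy * sxy) / (sxx * sst)


class Coherence(NamedTuple):
    """Mean TP within units vs at unit boundaries (NaN for an empty class)."""

    within_tp: float
    between_tp: float
    n_within: int
    n_between: int


def coherence(segresult: SegmentationResult, model: TrigramModel | None = None) -> Coherence:
    """Mean transitional probability within vs between units, pooled over
    every TP-bearing position (3..L) of every sequence of the set.

    Position ``i`` is between-unit when a boundary separates tokens ``i-1``
    and ``i`` (boundary position ``i-1``), else within-unit.  Positions 1–2
    carry no TP and are excluded.  A class with no members yields NaN.
    """
    if model is None:
        model = segresult.model
    within, between = [], []
    for seq, tps, bnds in zip(segresult.sset, segresult.tps, segresult.boundaries):
        bset = set(bnds)
        for j, tp in enumerate(tps):
            i = j + 3  # sequence position of this TP
            (between if (i - 1) in bset else within).append(tp)
    return Coherence(
        float(np.mean(within)) if within else float("nan"),
        float(np.mean(between)) if between else float("nan"),
        len(within),
        len(between),
    )


def set_summary(segresult: SegmentationResult) -> dict:
    """One row of per-set statistics used by the pipeline report."""
    inv = unit_inventory(segresult)
    table = rank_table(inv)
    coh = coherence(segresult)
    sset = segresult.sset
    return {
        "chain_id": sset.chain_id,
        "generation": sset.generation,
        "n_seq": sset.n_sequences,
        "mean_len": float(np.mean(sset.lengths)),
        "n_types": inv.n_types,
        "n_tokens": inv.n_tokens,
        "entropy": shannon_entropy(inv),
        "norm_entropy": normalized_entropy(inv),
        "r2": loglog_r2(table) if inv.n_types >= 2 else float("nan"),
        "within_tp": coh.within_tp,
        "between_tp": coh.between_tp,
    }
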