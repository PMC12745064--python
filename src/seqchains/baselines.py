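"""Null baselines for the segmentation analysis.

Two nulls isolate what the Zipfian structure of segmented units reflects:

* the **shuffled** baseline permutes the pooled color tokens of a set and
  refills the original sequence lengths, preserving the unigram histogram
  and the length multiset while destroying all sequential order;
* the **rotated** baseline keeps the sequences and the number of unit
  boundaries but shifts every boundary forward by one random offset in the
  global (concatenated-set) coordinate system, so boundaries no longer
  align with transitional-probability drops.

If Zipfian unit distributions emerge from sequential structure, the
original sets should outscore both nulls on the log–log rank–frequency R².
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .metrics import loglog_r2, rank_table, unit_inventory
from .seqdata import ColorSequence, SequenceSet, TransmissionChain
from .segmentation import SegmentationResult, segment_set

__all__ = ["shuffle_set", "rotate_boundaries", "baseline_comparison"]


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def shuffle_set(sset: SequenceSet, seed) -> SequenceSet:
    """Permute the pooled tokens of *sset* uniformly and refill sequences of
    the original lengths in the original order.

    Conserves per-symbol counts and per-sequence lengths exactly;
    deterministic given *seed* (an int or a ``numpy.random.Generator``).
    """
    rng = _rng(seed)
    pool = [tok for seq in sset for tok in seq]
    perm = rng.permutation(len(pool))
    shuffled = [pool[i] for i in perm]
    out, start = [], 0
    for L in sset.lengths:
        out.append(ColorSequence(shuffled[start:start + L]))
        start += L
    return sset.replace_sequences(out)


def rotate_boundaries(
    segresult: SegmentationResult, seed=None, k: int | None = None
) -> SegmentationResult:
    """Shift all unit boundaries forward by one global offset *k*.

    Boundaries are mapped to coordinates over the concatenation of the
    set's sequences, shifted by ``k`` (drawn uniformly from 1..total−1 when
    not given), wrapped modulo the total token count, and mapped back to
    per-sequence positions — so a boundary pushed past the end of a
    sequence lands in the next one, and past the last sequence re-enters
    the first.  The boundary count is conserved; the sequences, TPs and
    ratios are unchanged.  A segmentation with no boundaries is returned
    unchanged.
    """
    total = segresult.sset.total_tokens
    if segresult.n_boundaries == 0:
        return segresult
    if k is None:
        k = int(_rng(seed).integers(1, total))
    k = int(k) % total
    lengths = segresult.sset.lengths
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    global_cuts = [
        offsets[s] + b
        for s, bnds in enumerate(segresult.boundaries)
        for b in bnds
    ]
    new_bounds: list[list[int]] = [[] for _ in lengths]
    for g in global_cuts:
        g2 = (g - 1 + k) % total + 1
        s = int(np.searchsorted(offsets, g2, side="left")) - 1
        new_bounds[s].append(int(g2 - offsets[s]))
    return segresult.replace_boundaries(new_bounds)


def baseline_comparison(
    chain: TransmissionChain, threshold: float, n_reps: int = 50, seed: int = 0
) -> pd.DataFrame:
    """Per-set log–log R² of the original segmentation and its two nulls.

    For every set of *chain*: the original R²; *n_reps* shuffled replicates,
    each re-segmented from scratch (fresh trigram model on the shuffled set,
    same threshold); and *n_reps* rotated replicates, which keep the original
    sequences and model and rotate the boundaries.  Returns a long table
    with columns ``generation, dataset, rep, r2`` (``rep`` is NA for the
    original rows; sets whose inventory has fewer than two unit types yield
    NaN R²).  Deterministic given *seed*.
    """
    rows = []

    def r2_of(segresult: SegmentationResult) -> float:
        inv = unit_inventory(segresult)
        if inv.n_types < 2:
            return float("nan")
        return loglog_r2(rank_table(inv))

    for g, sset in enumerate(chain):
        seg = segment_set(sset, threshold)
        rows.append({"generation": g, "dataset": "original", "rep": pd.NA, "r2": r2_of(seg)})
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 0xBA5E, g, 0, rep])
            )
            shuf = shuffle_set(sset, rng)
            rows.append(
                {"generation": g, "dataset": "shuffled", "rep": rep,
                 "r2": r2_of(segment_set(shuf, threshold))}
            )
        for rep in range(n_reps):
            rng = np.random.default_rng(
                np.random.SeedSequence([int(seed), 0xBA5E, g, 1, rep])
            )
            rot = rotate_boundaries(seg, rng)
            rows.append({"generation": g, "dataset": "rotated", "rep": rep, "r2": r2_of(rot)})
    return pd.DataFrame(rows, columns=["generation", "dataset", "rep", "r2"])
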