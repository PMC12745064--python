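"""Transitional-probability segmentation of categorical sequences.

Sequences are segmented into units at drops in trigram transitional
probability (TP), the cue infants are thought to exploit when segmenting
continuous speech.  The TP of the token at position ``i`` (1-based) is its
conditional probability given the two preceding tokens, estimated from
counts pooled over every sequence of one set (contexts never span two
sequences).  TPs therefore exist for positions 3..L of each sequence.

A *drop* is measured by the ratio of two consecutive TPs,
``ratio(i) = TP(i) / TP(i-1)`` for positions 4..L.  When the ratio at
position ``i`` falls strictly below a calibrated threshold, a unit boundary
is placed between positions ``i-1`` and ``i`` — recorded as boundary
position ``i-1``, meaning "cut after token ``i-1``".  The earliest possible
cut is therefore after position 3, so the first unit of a sequence is never
shorter than 3 tokens.

The threshold is calibrated on unstructured data: pool the TP ratios of
many uniformly random sets of the study's shape and take a low percentile
of the aggregated distribution, so that only drops rare under randomness
count as boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .seqdata import DEFAULT_ALPHABET, ColorSequence, SequenceSet

__all__ = [
    "UnseenContextError",
    "TrigramModel",
    "SegmentationResult",
    "fit_trigram_model",
    "transition_probabilities",
    "tp_ratios",
    "calibrate_threshold",
    "segment_set",
    "units_of",
]


class UnseenContextError(KeyError):
    """TP queried for a two-symbol context with zero observations."""


@dataclass(frozen=True)
class TrigramModel:
    """Pooled trigram counts of one sequence set.

    ``context_counts[(a, b)]`` is the number of trigram slots whose first two
    symbols are ``(a, b)``; ``continuation_counts[(a, b, c)]`` the number of
    those continuing with ``c``.  TP(c | a, b) is their ratio.
    """

    context_counts: dict[tuple[str, str], int]
    continuation_counts: dict[tuple[str, str, str], int]
    alphabet: tuple[str, ...]

    @classmethod
    def fit(cls, sset: SequenceSet) -> "TrigramModel":
        ctx: dict[tuple[str, str], int] = {}
        cont: dict[tuple[str, str, str], int] = {}
        for seq in sset:
            toks = seq.tokens
            for i in range(2, len(toks)):
                a, b, c = toks[i - 2], toks[i - 1], toks[i]
                ctx[(a, b)] = ctx.get((a, b), 0) + 1
                cont[(a, b, c)] = cont.get((a, b, c), 0) + 1
        return cls(ctx, cont, sset.alphabet)

    def tp(self, a: str, b: str, c: str) -> float:
        """TP(c | a, b); raises :class:`UnseenContextError` for unseen (a, b)."""
        n = self.context_counts.get((a, b), 0)
        if n == 0:
            raise UnseenContextError((a, b))
        return self.continuation_counts.get((a, b, c), 0) / n

    def transition_probabilities(self, seq: ColorSequence | str) -> list[float]:
        """TPs of *seq* at positions 3..L (empty for sequences shorter than 3)."""
        toks = tuple(seq.tokens) if isinstance(seq, ColorSequence) else tuple(seq)
        return [self.tp(toks[i - 2], toks[i - 1], toks[i]) for i in range(2, len(toks))]


def fit_trigram_model(sset: SequenceSet) -> TrigramModel:
    """Pool trigram counts over all sequences of *sset* (contexts never cross
    sequence boundaries) and return the resulting TP model."""
    return TrigramModel.fit(sset)


def transition_probabilities(seq: ColorSequence | str, model: TrigramModel) -> list[float]:
    """TPs of *seq* under *model*, one per position 3..L."""
    return model.transition_probabilities(seq)


def tp_ratios(tps: Sequence[float]) -> list[float]:
    """Consecutive-TP ratios: ``ratio(i) = TP(i) / TP(i-1)`` for positions 4..L.

    The result has ``len(tps) - 1`` entries (empty for fewer than 2 TPs).
    """
    return [tps[j] / tps[j - 1] for j in range(1, len(tps))]


@dataclass(frozen=True)
class SegmentationResult:
    """Per-sequence boundaries of one set under one threshold.

    ``boundaries[s]`` is the sorted tuple of boundary positions of sequence
    ``s``; boundary ``p`` cuts between tokens ``p`` and ``p + 1`` (1-based).
    ``tps[s]`` holds TPs for positions 3..L and ``ratios[s]`` ratios for
    positions 4..L of that sequence.
    """

    sset: SequenceSet
    threshold: float
    boundaries: tuple[tuple[int, ...], ...]
    tps: tuple[tuple[float, ...], ...]
    ratios: tuple[tuple[float, ...], ...]
    model: TrigramModel

    def units(self) -> list[list[str]]:
        """Units of every sequence, cutting at the boundaries.

        Boundary positions equal to a sequence's length (possible only for
        rotated null segmentations, where the cut sits at the sequence end)
        are vacuous and produce no split.  Unit order is preserved and the
        units of a sequence concatenate back to it exactly.
        """
        out: list[list[str]] = []
        for seq, bnds in zip(self.sset, self.boundaries):
            s = str(seq)
            cuts = [b for b in bnds if 1 <= b < len(s)]
            pieces = []
            prev = 0
            for b in cuts:
                pieces.append(s[prev:b])
                prev = b
            pieces.append(s[prev:])
            out.append(pieces)
        return out

    @property
    def n_boundaries(self) -> int:
        return sum(len(b) for b in self.boundaries)

    def replace_boundaries(
        self, boundaries: Iterable[Iterable[int]]
    ) -> "SegmentationResult":
        new = tuple(tuple(sorted(b)) for b in boundaries)
        if len(new) != len(self.sset):
            raise ValueError("boundary list count must match sequence count")
        return SegmentationResult(
            self.sset, self.threshold, new, self.tps, self.ratios, self.model
        )


def segment_set(
    sset: SequenceSet, threshold: float, model: TrigramModel | None = None
) -> SegmentationResult:
    """Segment every sequence of *sset* at TP-ratio drops below *threshold*.

    A boundary is placed between positions ``i-1`` and ``i`` exactly when the
    ratio at position ``i`` is strictly below *threshold* (a tie does not
    cut).  The model defaults to the set's own trigram model.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    if model is None:
        model = TrigramModel.fit(sset)
    all_tps, all_ratios, all_bounds = [], [], []
    for seq in sset:
        tps = model.transition_probabilities(seq)
        ratios = tp_ratios(tps)
        # ratio index j corresponds to sequence position i = j + 4
        bounds = [j + 3 for j, r in enumerate(ratios) if r < threshold]
        all_tps.append(tuple(tps))
        all_ratios.append(tuple(ratios))
        all_bounds.append(tuple(bounds))
    return SegmentationResult(
        sset, float(threshold), tuple(all_bounds), tuple(all_tps), tuple(all_ratios), model
    )


def units_of(segresult: SegmentationResult) -> list[list[str]]:
    """Unit strings of every sequence of a segmentation (see
    :meth:`SegmentationResult.units`)."""
    return segresult.units()


def calibrate_threshold(
    n_sets: int = 500,
    n_seq: int = 30,
    seq_len: int = 12,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    percentile: float = 5.0,
    seed: int = 0,
    return_ratios: bool = False,
):
    """Calibrate the segmentation threshold on uniformly random sets.

    Generates *n_sets* random sets (*n_seq* sequences of length *seq_len*,
    tokens i.i.d. uniform over *alphabet*), fits a trigram model per set,
    pools the TP ratios of all sequences of all sets into one aggregated
    distribution, and returns its *percentile*-th percentile (linear
    interpolation between order statistics).  Deterministic given *seed*.

    With the study defaults (500 sets of 30x12 over 4 symbols, 5th
    percentile) the threshold lands near 0.41.

    Returns the threshold, or ``(threshold, ratios)`` with the pooled ratio
    array when *return_ratios* is true.
    """
    from .synthetic import random_set  # local import to avoid a module cycle

    if n_sets < 1:
        raise ValueError("n_sets must be >= 1")
    if not 0 < percentile < 100:
        raise ValueError("percentile must be in (0, 100)")
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x5E6]))
    pooled: list[float] = []
    for _ in range(n_sets):
        sset = random_set(n_seq, seq_len, alphabet, rng=rng)
        model = TrigramModel.fit(sset)
        for seq in sset:
            pooled.extend(tp_ratios(model.transition_probabilities(seq)))
    ratios = np.asarray(pooled, dtype=float)
    threshold = float(np.percentile(ratios, percentile))
    if return_ratios:
        return threshold, ratios
    return threshold
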