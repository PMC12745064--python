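"""Core containers and plain-text I/O for transmission-chain sequence data.

A transmission chain is a lineage of sequence sets: generation 0 is a
randomly generated seed set, and each later generation is a learner's
reproduction of the previous one.  The containers here are deliberately
thin — ordered tuples of symbols with a declared alphabet — so that every
downstream statistic (transitional probabilities, unit inventories,
entropies) is computed from explicit, validated data.

The alphabet is always declared, never inferred from the data.  The default
is the four colors of the reproduction task (``R``, ``Y``, ``G``, ``B``),
but any inventory of distinct single-character symbols works (e.g. a
bioacoustic unit inventory).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Sequence

__all__ = [
    "DEFAULT_ALPHABET",
    "ValidationError",
    "ColorSequence",
    "SequenceSet",
    "TransmissionChain",
    "ReproductionEvent",
    "read_set",
    "write_set",
    "read_chain",
    "write_chain",
    "read_events",
    "write_events",
    "write_trials",
]

DEFAULT_ALPHABET: tuple[str, ...] = ("R", "Y", "G", "B")

_GEN_FILE_RE = re.compile(r"^gen(\d+)\.txt$")


class ValidationError(ValueError):
    """Raised when input data violate a container invariant."""


@dataclass(frozen=True)
class ColorSequence:
    """An ordered sequence of categorical symbols (one keypress per token)."""

    tokens: tuple[str, ...]

    def __init__(self, tokens: Iterable[str]) -> None:
        object.__setattr__(self, "tokens", tuple(tokens))
        if len(self.tokens) < 1:
            raise ValidationError("a sequence must contain at least one token")

    @property
    def length(self) -> int:
        return len(self.tokens)

    def __len__(self) -> int:
        return len(self.tokens)

    def __iter__(self) -> Iterator[str]:
        return iter(self.tokens)

    def __getitem__(self, i):
        return self.tokens[i]

    def __str__(self) -> str:
        return "".join(self.tokens)


def _as_sequence(seq: ColorSequence | str | Iterable[str]) -> ColorSequence:
    if isinstance(seq, ColorSequence):
        return seq
    return ColorSequence(seq)


@dataclass(frozen=True)
class SequenceSet:
    """An ordered set of sequences — the unit of transmission.

    Parameters
    ----------
    sequences
        Ordered sequences; order is meaningful (trial order).
    alphabet
        Declared symbol inventory.  Every token of every sequence must be a
        member; violations raise :class:`ValidationError`.
    chain_id, generation
        Optional provenance labels (chain label and 0-based generation).
    """

    sequences: tuple[ColorSequence, ...]
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    chain_id: str | None = None
    generation: int | None = None

    def __init__(
        self,
        sequences: Iterable[ColorSequence | str],
        alphabet: Sequence[str] = DEFAULT_ALPHABET,
        chain_id: str | None = None,
        generation: int | None = None,
    ) -> None:
        seqs = tuple(_as_sequence(s) for s in sequences)
        alpha = tuple(alphabet)
        if len(seqs) < 1:
            raise ValidationError("a sequence set must contain at least one sequence")
        if len(set(alpha)) != len(alpha) or len(alpha) < 1:
            raise ValidationError("alphabet symbols must be distinct and non-empty")
        allowed = set(alpha)
        for i, s in enumerate(seqs):
            for j, tok in enumerate(s):
                if tok not in allowed:
                    raise ValidationError(
                        f"sequence {i + 1}, position {j + 1}: symbol {tok!r} "
                        f"not in alphabet {''.join(alpha)}"
                    )
        if generation is not None and generation < 0:
            raise ValidationError("generation must be >= 0")
        object.__setattr__(self, "sequences", seqs)
        object.__setattr__(self, "alphabet", alpha)
        object.__setattr__(self, "chain_id", chain_id)
        object.__setattr__(self, "generation", generation)

    @property
    def n_sequences(self) -> int:
        return len(self.sequences)

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(s.length for s in self.sequences)

    @property
    def total_tokens(self) -> int:
        return sum(self.lengths)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[ColorSequence]:
        return iter(self.sequences)

    def __getitem__(self, i: int) -> ColorSequence:
        return self.sequences[i]

    def replace_sequences(self, sequences: Iterable[ColorSequence | str]) -> "SequenceSet":
        """A copy of this set with new sequences and identical metadata."""
        return SequenceSet(sequences, self.alphabet, self.chain_id, self.generation)


@dataclass(frozen=True)
class TransmissionChain:
    """Sequence sets of one chain, ordered by consecutive generation 0..G."""

    sets: tuple[SequenceSet, ...]
    chain_id: str | None = None

    def __init__(self, sets: Iterable[SequenceSet], chain_id: str | None = None) -> None:
        ordered = tuple(sets)
        if not ordered:
            raise ValidationError("a chain must contain at least one set")
        for g, sset in enumerate(ordered):
            if sset.generation is not None and sset.generation != g:
                raise ValidationError(
                    f"generations must be consecutive from 0; found {sset.generation} at index {g}"
                )
        alphabets = {s.alphabet for s in ordered}
        if len(alphabets) != 1:
            raise ValidationError("all sets of a chain must share one alphabet")
        ids = {s.chain_id for s in ordered if s.chain_id is not None}
        if chain_id is None and len(ids) == 1:
            chain_id = next(iter(ids))
        if len(ids) > 1:
            raise ValidationError(f"sets carry conflicting chain ids: {sorted(ids)}")
        object.__setattr__(self, "sets", ordered)
        object.__setattr__(self, "chain_id", chain_id)

    @property
    def n_generations(self) -> int:
        return len(self.sets)

    @property
    def alphabet(self) -> tuple[str, ...]:
        return self.sets[0].alphabet

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self) -> Iterator[SequenceSet]:
        return iter(self.sets)

    def __getitem__(self, g: int) -> SequenceSet:
        return self.sets[g]


@dataclass(frozen=True)
class ReproductionEvent:
    """One reproduction trial: the sequence seen, the sequence produced,
    and one reaction time (ms) per produced keypress.

    The first token's reaction time is measured from reproduction onset;
    later tokens' from the preceding keypress.
    """

    chain_id: str | None
    generation: int
    trial_index: int
    seen: ColorSequence
    produced: ColorSequence
    rts: tuple[float, ...]

    def __init__(
        self,
        chain_id: str | None,
        generation: int,
        trial_index: int,
        seen: ColorSequence | str,
        produced: ColorSequence | str,
        rts: Iterable[float],
    ) -> None:
        seen = _as_sequence(seen)
        produced = _as_sequence(produced)
        rts = tuple(float(r) for r in rts)
        if len(rts) != produced.length:
            raise ValidationError(
                f"expected {produced.length} reaction times, got {len(rts)}"
            )
        if any(r <= 0 for r in rts):
            raise ValidationError("reaction times must be positive")
        object.__setattr__(self, "chain_id", chain_id)
        object.__setattr__(self, "generation", int(generation))
        object.__setattr__(self, "trial_index", int(trial_index))
        object.__setattr__(self, "seen", seen)
        object.__setattr__(self, "produced", produced)
        object.__setattr__(self, "rts", rts)


# ---------------------------------------------------------------------------
# plain-text readers / writers
# ---------------------------------------------------------------------------

def read_set(
    path: str | Path,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    chain_id: str | None = None,
    generation: int | None = None,
) -> SequenceSet:
    """Read a sequence set from a plain-text file (one sequence per line,
    one character per symbol, no separators, blank lines forbidden)."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    lines = text.splitlines()
    if not lines:
        raise ValidationError(f"{path}: empty set file")
    allowed = set(alphabet)
    seqs = []
    for lineno, line in enumerate(lines, start=1):
        if line == "":
            raise ValidationError(f"{path}: blank line at line {lineno}")
        for col, ch in enumerate(line, start=1):
            if ch not in allowed:
                raise ValidationError(
                    f"{path}: line {lineno}, character {col}: symbol {ch!r} "
                    f"not in alphabet {''.join(alphabet)}"
                )
        seqs.append(ColorSequence(line))
    return SequenceSet(seqs, alphabet, chain_id=chain_id, generation=generation)


def write_set(sset: SequenceSet, path: str | Path) -> None:
    """Write a set in the canonical one-sequence-per-line text format.

    Byte output is deterministic for a given set (trailing newline, UTF-8).
    """
    path = Path(path)
    path.write_text("".join(f"{s}\n" for s in sset.sequences), encoding="utf-8")


def write_chain(chain: TransmissionChain, directory: str | Path) -> None:
    """Write one ``genNN.txt`` file per generation into *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for g, sset in enumerate(chain.sets):
        write_set(sset, directory / f"gen{g:02d}.txt")


def read_chain(
    path: str | Path,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
    chain_id: str | None = None,
) -> TransmissionChain:
    """Read a chain from a directory of ``genNN.txt`` files or a chain CSV.

    The CSV layout has the header ``chain_id,generation,seq_index,sequence``;
    if it holds more than one chain, ``chain_id`` must be given to select one.
    Generations must be consecutive starting at 0; a gap is an error naming
    the missing index.
    """
    path = Path(path)
    if path.is_dir():
        found: dict[int, Path] = {}
        for f in path.iterdir():
            m = _GEN_FILE_RE.match(f.name)
            if m:
                found[int(m.group(1))] = f
        if not found:
            raise ValidationError(f"{path}: no genNN.txt files found")
        n_gen = max(found) + 1
        for g in range(n_gen):
            if g not in found:
                raise ValidationError(f"{path}: missing generation file gen{g:02d}.txt")
        sets = [
            read_set(found[g], alphabet, chain_id=chain_id, generation=g)
            for g in range(n_gen)
        ]
        return TransmissionChain(sets, chain_id=chain_id)

    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"chain_id", "generation", "seq_index", "sequence"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValidationError(f"{path}: chain CSV must have columns {sorted(required)}")
        rows = list(reader)
    if not rows:
        raise ValidationError(f"{path}: empty chain CSV")
    ids = sorted({r["chain_id"] for r in rows})
    if chain_id is None:
        if len(ids) > 1:
            raise ValidationError(
                f"{path}: CSV contains chains {ids}; pass chain_id to select one"
            )
        chain_id = ids[0]
    rows = [r for r in rows if r["chain_id"] == chain_id]
    if not rows:
        raise ValidationError(f"{path}: no rows for chain {chain_id!r}")
    by_gen: dict[int, list[tuple[int, str]]] = {}
    for r in rows:
        by_gen.setdefault(int(r["generation"]), []).append(
            (int(r["seq_index"]), r["sequence"])
        )
    n_gen = max(by_gen) + 1
    sets = []
    for g in range(n_gen):
        if g not in by_gen:
            raise ValidationError(f"{path}: missing generation {g} for chain {chain_id!r}")
        seqs = [s for _, s in sorted(by_gen[g])]
        sets.append(SequenceSet(seqs, alphabet, chain_id=chain_id, generation=g))
    return TransmissionChain(sets, chain_id=chain_id)


def write_events(events: Iterable[ReproductionEvent], path: str | Path) -> None:
    """Write per-keypress rows: chain_id,generation,trial_index,position,seen,produced,rt_ms.

    ``seen`` and ``produced`` repeat the whole-trial sequences on every row;
    ``position`` is the 1-based index of the produced keypress.
    """
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["chain_id", "generation", "trial_index", "position", "seen", "produced", "rt_ms"])
        for ev in events:
            for pos, rt in enumerate(ev.rts, start=1):
                w.writerow(
                    [ev.chain_id or "", ev.generation, ev.trial_index, pos,
                     str(ev.seen), str(ev.produced), repr(rt)]
                )


def write_trials(events: Iterable[ReproductionEvent], path: str | Path) -> None:
    """Write whole-trial rows: chain_id,generation,trial_index,seen_seq,produced_seq."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["chain_id", "generation", "trial_index", "seen_seq", "produced_seq"])
        for ev in events:
            w.writerow([ev.chain_id or "", ev.generation, ev.trial_index, str(ev.seen), str(ev.produced)])


def read_events(
    path: str | Path,
    alphabet: Sequence[str] = DEFAULT_ALPHABET,
) -> list[ReproductionEvent]:
    """Read the per-keypress events CSV back into :class:`ReproductionEvent` rows."""
    path = Path(path)
    by_trial: dict[tuple[str, int, int], dict] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        for r in reader:
            key = (r["chain_id"], int(r["generation"]), int(r["trial_index"]))
            rec = by_trial.setdefault(
                key, {"seen": r["seen"], "produced": r["produced"], "rts": {}}
            )
            rec["rts"][int(r["position"])] = float(r["rt_ms"])
    events = []
    for (cid, gen, trial), rec in sorted(by_trial.items()):
        rts = [rec["rts"][p] for p in sorted(rec["rts"])]
        events.append(
            ReproductionEvent(cid or None, gen, trial, rec["seen"], rec["produced"], rts)
        )
    return events
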