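"""Synthetic data: random seed sets and a chunk-recall reproduction agent.

Every analysis stage of this package can run without human data because
this module supplies both ends of the experiment:

* :func:`random_set` builds generation-zero material — uniformly random
  sequences (defaults: 30 sequences of length 12 over the four colors);
* :func:`reproduce_set` is a minimal chunk-based learner.  It parses the
  set it sees into units via transitional-probability segmentation, builds
  a chunk inventory, and reproduces each sequence chunk by chunk: a chunk
  is recalled veridically with probability 1−ε and otherwise replaced by a
  chunk sampled with probability proportional to freq^β.  Occasional
  boundary noise drops or duplicates a chunk, and productions are forced
  into the valid length band (8–16) by removing or appending chunks.  The
  agent also emits per-keypress reaction times that are faster for more
  probable transitions and later positions, mirroring sequence-learning
  reaction-time signatures.
* :func:`simulate_chain` iterates the agent: each generation's output set
  is the next generation's input, which is the transmission-chain design.

The agent is a deliberately minimal model of chunk learning and recall —
enough for the statistical signatures (coherent units, skewing frequency
distributions) to emerge over generations — and makes no claim of fidelity
to human learners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .seqdata import (
    DEFAULT_ALPHABET,
    ColorSequence,
    ReproductionEvent,
    SequenceSet,
    TransmissionChain,
)
from .segmentation import UnseenContextError, segment_set

__all__ = ["AgentConfig", "ChainSimConfig", "random_set", "reproduce_set", "simulate_chain"]


@dataclass(frozen=True)
class AgentConfig:
    """Parameters of the chunk-recall agent.

    recall_noise
        ε, probability that a recalled chunk is replaced by a sampled one.
    reuse_bias
        β, exponent of the frequency-weighted chunk sampling (freq^β).
    boundary_noise
        Probability of dropping or duplicating one chunk of a production.
    min_len, max_len
        Valid produced lengths (the task rejects productions outside 8–16).
    rt_base, rt_tp_slope, rt_pos_slope, rt_sigma
        Reaction-time generator: log rt = log(rt_base) + rt_tp_slope·TP +
        rt_pos_slope·position + Normal(0, rt_sigma); rt_base in ms.
    """

    recall_noise: float = 0.1
    reuse_bias: float = 1.0
    boundary_noise: float = 0.1
    min_len: int = 8
    max_len: int = 16
    rt_base: float = 450.0
    rt_tp_slope: float = -0.16
    rt_pos_slope: float = -0.01
    rt_sigma: float = 0.2

    def __post_init__(self) -> None:
        for name in ("recall_noise", "boundary_noise"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.reuse_bias < 0:
            raise ValueError("reuse_bias must be >= 0")
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if self.rt_sigma <= 0:
            raise ValueError("rt_sigma must be > 0")


@dataclass(frozen=True)
class ChainSimConfig:
    """Parameters of a simulated transmission chain (defaults mirror the
    reproduction task: 10 generations of 30 sequences, seed length 12,
    four colors, the agent parsing at the calibrated threshold 0.41)."""

    n_generations: int = 10
    n_seq: int = 30
    init_len: int = 12
    alphabet: tuple[str, ...] = DEFAULT_ALPHABET
    agent: AgentConfig = field(default_factory=AgentConfig)
    threshold: float = 0.41
    chain_id: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_generations < 1 or self.n_seq < 1 or self.init_len < 1:
            raise ValueError("n_generations, n_seq and init_len must be >= 1")


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def random_set(
    n_seq: int = 30,
    seq_len: int = 12,
    alphabet=DEFAULT_ALPHABET,
    seed=None,
    rng: np.random.Generator | None = None,
    chain_id: str | None = None,
    generation: int | None = 0,
) -> SequenceSet:
    """A set of *n_seq* sequences of length *seq_len* with tokens i.i.d.
    uniform over *alphabet*.  Deterministic given *seed* (or pass an
    existing generator as *rng* to draw from a shared stream)."""
    if rng is None:
        rng = _rng(seed)
    alphabet = tuple(alphabet)
    draws = rng.integers(0, len(alphabet), size=(n_seq, seq_len))
    seqs = ["".join(alphabet[i] for i in row) for row in draws]
    return SequenceSet(seqs, alphabet, chain_id=chain_id, generation=generation)


def _sample_chunk(types: list[str], weights: np.ndarray, rng: np.random.Generator) -> str:
    return types[int(rng.choice(len(types), p=weights))]


def _mean_tp(seg) -> float:
    tps = [tp for seq_tps in seg.tps for tp in seq_tps]
    return float(np.mean(tps)) if tps else 0.5


def reproduce_set(
    seen: SequenceSet,
    cfg: AgentConfig,
    threshold: float,
    seed=None,
    generation: int | None = None,
) -> tuple[SequenceSet, list[ReproductionEvent]]:
    """One agent's reproduction of *seen*, with per-keypress reaction times.

    The agent segments *seen* at *threshold* with the set's own trigram
    model, then rebuilds each sequence from its chunks: each chunk is kept
    with probability 1−ε or replaced by an inventory chunk sampled with
    probability ∝ freq^β; with probability ``boundary_noise`` one chunk is
    dropped or duplicated; productions outside [min_len, max_len] are
    repaired by removing/appending chunks (with a final token-level
    truncation at max_len).  Reaction times follow the log-linear generator
    in :class:`AgentConfig`; transitions without a defined TP (positions
    1–2, unseen contexts) use the seen set's mean TP as a neutral value.

    Returns the produced set and the reproduction events, deterministic
    given *seed*.
    """
    rng = _rng(seed)
    seg = segment_set(seen, threshold)
    units = seg.units()
    freq: dict[str, int] = {}
    for seq_units in units:
        for u in seq_units:
            freq[u] = freq.get(u, 0) + 1
    types = sorted(freq)
    if types:
        w = np.array([freq[t] ** cfg.reuse_bias for t in types], dtype=float)
        weights = w / w.sum()
    model = seg.model
    mean_tp = _mean_tp(seg)
    gen = generation if generation is not None else (
        seen.generation + 1 if seen.generation is not None else None
    )

    produced_seqs: list[str] = []
    events: list[ReproductionEvent] = []
    for trial, (seq, seq_units) in enumerate(zip(seen, units)):
        if not types:  # degenerate: no inventory, copy verbatim
            chunks = [str(seq)]
        else:
            chunks = []
            for u in seq_units:
                if rng.random() < cfg.recall_noise:
                    chunks.append(_sample_chunk(types, weights, rng))
                else:
                    chunks.append(u)
            if rng.random() < cfg.boundary_noise:
                if len(chunks) > 1 and rng.random() < 0.5:
                    del chunks[int(rng.integers(len(chunks)))]
                else:
                    i = int(rng.integers(len(chunks)))
                    chunks.insert(i, chunks[i])
            # repair the production into the valid length band
            while sum(map(len, chunks)) > cfg.max_len and len(chunks) > 1:
                del chunks[int(rng.integers(len(chunks)))]
            while sum(map(len, chunks)) < cfg.min_len:
                chunks.append(_sample_chunk(types, weights, rng))
        toks = "".join(chunks)[: cfg.max_len]
        produced_seqs.append(toks)

        rts = []
        for pos in range(1, len(toks) + 1):
            if pos >= 3:
                try:
                    tp = model.tp(toks[pos - 3], toks[pos - 2], toks[pos - 1])
                except UnseenContextError:
                    tp = mean_tp
            else:
                tp = mean_tp
            log_rt = (
                math.log(cfg.rt_base)
                + cfg.rt_tp_slope * tp
                + cfg.rt_pos_slope * pos
                + rng.normal(0.0, cfg.rt_sigma)
            )
            rts.append(math.exp(log_rt))
        events.append(
            ReproductionEvent(seen.chain_id, gen if gen is not None else -1,
                              trial, seq, ColorSequence(toks), rts)
        )
    produced = SequenceSet(produced_seqs, seen.alphabet, seen.chain_id, gen)
    return produced, events


def simulate_chain(
    cfg: ChainSimConfig,
) -> tuple[TransmissionChain, dict[int, list[ReproductionEvent]]]:
    """Simulate a transmission chain of ``cfg.n_generations`` sets.

    Generation 0 is a uniformly random set; each later generation is the
    chunk-recall agent's reproduction of the previous one, with a fresh
    agent stream seeded from ``(cfg.seed, g)`` so any generation is
    reproducible in isolation.  Returns the chain and the reproduction
    events keyed by the generation they produced (1..G−1).
    """
    seed0 = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    sets = [
        random_set(cfg.n_seq, cfg.init_len, cfg.alphabet, rng=seed0,
                   chain_id=cfg.chain_id, generation=0)
    ]
    events: dict[int, list[ReproductionEvent]] = {}
    for g in range(1, cfg.n_generations):
        rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), g]))
        produced, ev = reproduce_set(
            sets[-1], cfg.agent, cfg.threshold, seed=rng, generation=g
        )
        sets.append(produced)
        events[g] = ev
    return TransmissionChain(sets, chain_id=cfg.chain_id), events
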