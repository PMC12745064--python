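# Methods

This note documents the models and procedures implemented in `seqchains`,
the defaults and numerical conventions they use, and what the synthetic
data generator does and does not emulate.

## Data model

A *sequence set* is an ordered list of sequences over a declared alphabet
(default `R, Y, G, B`); a *transmission chain* is a list of sets with
consecutive generations starting at 0. Generation 0 is a random seed set
(default 30 sequences of length 12, tokens i.i.d. uniform); each later set
is a learner's reproduction of the previous one. Reproduction events
optionally carry one reaction time per produced keypress (the first
measured from reproduction onset). The alphabet is always declared, never
inferred: silent inference would hide data errors. All positions in
reports are 1-based.

## Segmentation

Transitional probabilities are trigram-conditional: TP(c | a, b) =
n(abc) / n(ab·), with counts pooled over every sequence of exactly one set
and contexts never spanning two sequences. TPs therefore exist at
positions 3..L of a sequence, and consecutive-TP ratios
r(i) = TP(i) / TP(i−1) at positions 4..L. A ratio strictly below the
threshold θ is a drop, and it cuts **before the later token**: boundary
position i−1 (cut between tokens i−1 and i). Consequences: the earliest
cut is after position 3, so a sequence's first unit is never shorter than
3 tokens; boundary positions satisfy 3 ≤ p ≤ L−1; ties at θ do not cut
(θ is a percentile of a continuous empirical distribution, so ties are
measure-zero, but the rule must be defined). Cutting before the later
token makes the low-TP transition the *boundary* transition, which is what
produces the low between-unit TPs in the coherence analysis; the
alternative reading (cut after) would decouple boundary transitions from
the drop and is rejected on those grounds.

θ is calibrated on unstructured data: 500 uniformly random sets of the
study shape are generated, each gets its own trigram model, and all ratios
of all sets are pooled into one aggregated distribution whose 5th
percentile (linear interpolation between order statistics) is θ. Under
these conventions θ ≈ 0.42 and is stable to < 0.02 across seeds (the
pooled sample has ~1.35 × 10⁵ ratios). The percentile convention matters
at the ~0.01 level and is fixed to numpy's linear rule. A one-symbol
alphabet degenerates to all TPs = 1, all ratios = 1, θ = 1.

## Per-set statistics

* Transmission error = Levenshtein distance (insertions, deletions,
  substitutions; standard two-row DP) divided by the longer length;
  success = exact reproduction. Per-generation error compares trial i of
  generation g against trial i of generation g−1.
* The unit inventory counts every unit token of a segmented set. Set size
  S = number of types. Shannon entropy H = −Σ p log₂ p (bits); entropy
  efficiency H / log₂ S, defined as 0 for S = 1.
* The rank table orders types by descending frequency with ties broken by
  unit string ascending, so outputs are bit-for-bit reproducible. The
  Zipfian-shape measure is the R² of OLS of log frequency on log rank
  (natural logs; the base cancels). All-equal frequencies have zero
  variance in log frequency; R² is 0 by convention. R² is invariant to
  scaling all frequencies by a positive constant.
* Coherence classifies every TP-bearing position (3..L) as between-unit
  when a boundary separates it from its predecessor, else within-unit, and
  averages TPs per class over the pooled positions of the set; an empty
  class yields NaN.

## Distribution comparison

Rank-indexed category models over ranks 1..S: uniform (k = 0 parameters),
power-law pᵣ ∝ r^−a (k = 1), exponential pᵣ ∝ e^−λr (k = 1). The
log-likelihood is multinomial in the observed counts with the constant
coefficient omitted (identical across families, so AIC differences are
exact). One-dimensional MLE is bounded scalar minimization on [0, 10] with
tolerance 1e-8; the θ = 0 endpoint is evaluated explicitly so the
power law's maximized likelihood is never below the nested uniform's.
Rank support is fixed at the observed S — whole inventories are fitted, no
tail cutoff. AIC = 2k − 2ℓ (not AICc); Akaike weights
wᵢ = e^(−Δᵢ/2) / Σ e^(−Δⱼ/2) sum to one and are invariant to shifting all
AICs by a constant.

## Null baselines

The **shuffled** baseline permutes the pooled tokens of a set uniformly
and refills the original sequence lengths in order, conserving the unigram
histogram and length multiset exactly; each replicate is re-segmented from
scratch (fresh trigram model, same θ). The **rotated** baseline maps the
original boundaries to coordinates over the concatenated set, shifts all
of them by one offset k ~ Uniform{1..T−1} (T = total tokens), and wraps
modulo T — a boundary pushed past a sequence's end lands in the next
sequence, and past the last sequence re-enters the first. One k per
replicate (per-sequence shifts would destroy the cross-sequence unit
structure the null is meant to preserve). Boundary count and the circular
multiset of global gaps are conserved; a boundary landing exactly on a
sequence-final slot is kept in the count but is a vacuous cut when units
are extracted (a rare seam case of the wrap). Both baselines are
deterministic given (input, seed, replicate index).

## Complexity

Kolmogorov complexity is proxied by the byte length of the set's canonical
serialization (one character per token, newline-separated, trailing
newline, UTF-8) after zlib/DEFLATE at level 9. The estimate is
deterministic but *not* order-invariant (the compressor window sees
sequence order), and is sub-additive up to header overhead. Regression
utilities relate per-set complexity, R², entropy and mean error
(generation 0 excluded: seed sets have no reproduction error and are
random by construction), with Pearson correlations and an OLS of error on
R² + complexity.

## Abbreviation and reaction times

The law-of-abbreviation model is a log-link Poisson GLM with one
observation per unit **type** (outcome: token frequency; predictor: unit
length, optionally interacted with generation or a produced-vs-random
flag), fitted by IRLS to 1e-8. Type-level observation is the reading under
which random generation-zero sets show a flat slope. The complementary
descriptive statistic is the Pearson correlation of log frequency with
length over types.

RT filtering drops keypresses under 100 ms, then rows outside the
participant's mean ± 2 SD (sample SD on the survivors, computed per
chain × generation; rows on a bound are retained; participants with fewer
than two rows keep them, logged). The association model is OLS of log RT
on TP + position + generation; TPs attached to keypresses come from the
trigram model of the set the participant experienced (their input set),
evaluated on the produced sequence, so positions 1–2 and transitions
through unseen contexts carry no TP and are dropped. A constant
position/generation column (e.g. a single-generation table) is dropped
from the design with a log message; genuine collinearity raises.

## Synthetic data generator

`random_set` emulates generation-zero material: tokens i.i.d. uniform, 30
sequences of length 12 by default. `reproduce_set` is a deliberately
minimal chunk-recall agent:

1. parse the seen set with the set's own trigram model at θ;
2. build the chunk inventory with token frequencies;
3. reproduce each sequence chunk by chunk — keep each chunk with
   probability 1 − ε (default ε = 0.1), else replace it with an inventory
   chunk sampled ∝ freq^β (default β = 1);
4. with probability 0.1 (boundary noise) drop or duplicate one chunk;
5. repair productions into the valid 8–16 band by deleting/appending
   chunks, with a final token-level truncation at 16 (the human protocol
   instead repeats invalid trials, which has no analogue for a
   deterministic agent);
6. emit per-keypress RTs: log rt = log(450) − 0.16·TP − 0.01·position +
   N(0, 0.2), in ms; positions without a defined TP use the seen set's
   mean TP as a neutral value.

ε and β defaults are the moderate-noise regime in which the transmission
signatures emerge; the RT coefficients mirror the magnitudes reported for
human sequence reproduction (base ≈ 450 ms, TP slope −0.16, position slope
−0.01). One master seed drives the chain; per-generation streams are
derived by counter so any generation is reproducible in isolation. In the
noiseless limit (ε = boundary noise = 0) reproduction is the identity.

Under the defaults, simulated chains reproduce the qualitative transmission
pattern in a majority of seeds: the within−between TP gap widens, entropy
falls, log-log R² rises, and the power-law family overtakes the uniform by
the final generation, with produced lengths always in 8–16.

**What the agent does not emulate.** It is not a cognitive model: recall
noise is constant per chunk, so transmission error stays roughly flat
(~0.06–0.10) across generations instead of falling as it does for human
learners, and consequently the negative entropy–error correlation observed
in humans does not materialize in simulation (pooled r ≈ −0.09, n.s.). The
robust complexity-side signature — compressed size anticorrelated with R²
(r ≈ −0.77 pooled over chains) — does hold and is what the tests assert.
Passing tests therefore demonstrate the pipeline's correctness and the
emergence of distributional structure under chunk reuse, not fidelity to
human error trajectories.

## Problem sizes and determinism

Default analysis sizes: 500 calibration sets, 200 replicate sets for
generation-zero statistics, 50 null replicates per set, 20 seeds × 10
generations for emergence checks — sizes at which every pooled statistic
above is stable to well within its reported tolerance. All stochastic
operations take explicit seeds (numpy `SeedSequence` streams); no global
RNG state is used, and pipeline manifests record every seed, the threshold
and the compressor so a run can be reproduced byte-for-byte.
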