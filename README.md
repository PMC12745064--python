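# seqchains

Statistical analysis of **iterated sequence-learning transmission chains**:
sets of categorical sequences (by default color sequences over `R`, `Y`,
`G`, `B`) that are passed from learner to learner, each generation
reproducing the previous generation's output. The package is aimed at
researchers in cultural evolution and statistical sequence learning; the
same machinery applies to any corpus of categorical sequences over a small
alphabet (e.g. bioacoustic unit sequences).

The question the pipeline answers: do initially random sequence sets evolve
the statistical signatures that make natural language learnable —
statistically coherent "words" and a Zipfian frequency distribution — and
does a frequency–length relation (Zipf's law of abbreviation) appear?

## What it computes

* **Segmentation.** Transitional probabilities (TPs) are trigram-conditional,
  TP(cᵢ | cᵢ₋₂, cᵢ₋₁), estimated from counts pooled over one set. Drops in
  TP mark unit boundaries: with rᵢ = TPᵢ / TPᵢ₋₁, a boundary is placed
  between positions i−1 and i whenever rᵢ < θ. The threshold θ is the 5th
  percentile of the pooled ratio distribution of 500 uniformly random
  30×12 sets (≈ 0.41–0.43), so only drops rare under randomness cut.
* **Per-set statistics.** Normalized Levenshtein transmission error;
  unit-inventory set size, Shannon entropy H = −Σ p log₂ p and entropy
  efficiency H / log₂ S; within- vs between-unit mean TP; the R² of the
  OLS fit of log frequency on log rank (Zipfian shape).
* **Distribution comparison.** Maximum-likelihood fits of rank-indexed
  uniform (pᵣ = 1/S), power-law (pᵣ ∝ r^−a) and exponential (pᵣ ∝ e^−λr)
  families, compared by AIC = 2k − 2ℓ and Akaike weights
  wᵢ = e^(−Δᵢ/2) / Σⱼ e^(−Δⱼ/2).
* **Null baselines.** Token-shuffled sets (unigram histogram and sequence
  lengths preserved, order destroyed) and boundary-rotated segmentations
  (boundary count preserved, cuts decoupled from TP drops), 50 replicates
  each.
* **Complexity.** Compressed size (DEFLATE, level 9) of the serialized set
  as a Kolmogorov-complexity proxy, and its relation to R² and error.
* **Abbreviation & reaction times.** Type-level Poisson regression of unit
  frequency on unit length (log link), Pearson correlation of log frequency
  with length, and an OLS of log reaction time on TP + position +
  generation after standard RT filtering (100 ms floor, per-participant
  2 SD trim).
* **Synthetic data.** A uniform generation-zero generator and a chunk-recall
  agent (parse → frequency-weighted noisy recall, productions clamped to
  8–16 tokens) so every stage runs without human data.

## Worked example

Simulate a 10-generation chain with the default agent (recall noise 0.1,
reuse bias 1.0) and run the full pipeline at threshold 0.41:

```python
from seqchains import ChainSimConfig, run_pipeline
run_pipeline(ChainSimConfig(seed=4), "report", threshold=0.41, reps=10, seed=4)
```

`report/metrics.csv` then holds one row per generation:

```
 generation  mean_error  n_types  entropy    r2  within_tp  between_tp  complexity
          0         NaN       37    5.195 0.273      0.289       0.107         173
          1       0.038       38    5.222 0.421      0.292       0.115         173
          4       0.076       46    5.492 0.480      0.343       0.111         172
          9       0.130       45    5.394 0.752      0.456       0.145         152
```

Reading the rows: over transmission the within-unit TP rises (0.29 → 0.46)
while the between-unit TP stays low — units become statistically coherent —
and the log-log R² rises (0.27 → 0.75) as the unit frequency distribution
becomes Zipfian; the compressed size falls as structure accumulates.
`report/distfits.csv` shows the model comparison flipping from uniform to
power law between generation 0 and generation 9:

```
 generation      family  param   loglik     aic  rel_prob
          0     uniform    NaN -137.215 274.430     0.556
          0   power_law  0.092 -137.090 276.179     0.232
          9     uniform    NaN -228.400 456.799     0.066
          9   power_law  0.324 -225.337 452.674     0.517
```

The same stages are available from the shell:

```bash
seqchains calibrate --n-sets 500 --seed 1          # prints the threshold
seqchains simulate --out chain --generations 10 --seed 4
seqchains run --chain chain --out report --threshold 0.41 --seed 4
```

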