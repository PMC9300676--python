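# Methods

## The kinetic model

Each attP-L variant is treated as the substrate of an independent,
irreversible first-order inversion: after reaction time *t* a fraction
`F = 1 − exp(−k_flip · t)` of its molecules is flipped. Rate constants are
reported relative to wild type (`k_flip,WT ≡ 1`); absolute per-minute rates
are attached to a rate table's provenance only when the pool's overall
flipped fraction (from qPCR) is available.

The sequence model assumes independent multiplicative contributions of the
base at each randomized position:

    k_flip(s) = ∏_i W[i, b(s,i)],     W[i, WT base] = 1.

Taking log10 makes the model linear in the log-weights, with the one-hot
sequence encoding as the design matrix. The WT gauge is imposed
*structurally* — WT columns are dropped and no intercept is fitted — so the
WT prediction is exactly 1 rather than approximately 1 from a constrained
optimization. Base-10 logarithms are used throughout; the base only rescales
coefficients uniformly.

The model deliberately excludes epistasis between positions. Position-base
combinations never observed in training are *unidentified*: their weights
are NaN, they are excluded from the least-squares system, and predicting a
variant that carries one raises an error instead of silently using 1.
Rank deficiency beyond unidentified columns (possible at very small training
sizes) yields the minimum-norm solution with a warning and is flagged on the
estimator; an optional ridge penalty (`alpha`) exists solely for the
deliberately under-determined sizes of the sensitivity sweep and is off by
default everywhere else.

Unweighted ordinary least squares is the default; count-weighted OLS
(weighting each sequence by its read count) is available as a config option
but is not used by the shipped pipeline, since restricting the analysis to
the top-3000 variants already removes the lowest-precision frequencies.

## Frequency → rate conversion

Under selection conditions where total flipping is far below 1 (the shipped
default produces ≈0.002% in 5 min, mirroring a low-enzyme selection), the
flipped pool composition is proportional to `naive_s · k_s`, so

    linear mode:  k_s = (f_s / naive_s) / (f_WT / naive_WT),

with naïve ratios 1 when no naïve table is supplied (uniform library). The
*exact* mode inverts the first-order map without the linearization: it
reconstructs each variant's own flipped fraction from the pool composition,
the qPCR-measured overall flipped fraction, and the naïve abundances
(default uniform `4^-P` over the design's library), then computes
`k_s = log(1−F_s)/log(1−F_WT)`. The two agree to first order as the pool's
flipped fraction goes to zero; linear is the default because the selection
regime of interest sits deep in the initial-rate limit. Both conversions are
scale-invariant in the read counts and record their mode, reaction time, and
naïve correction in the rate table's provenance.

WT must be present in the frequency table because it anchors the relative
scale. When the analysis is restricted to the top-3000 variants and WT falls
outside that cut (which can happen under synthetic ground truths in which
many variants out-enrich WT), the pipeline appends the WT row from the full
table rather than failing; its frequency is still estimated from the same
refined read set.

## Read refinement

A read is kept iff its length equals the reference half-site, every base is
A/C/G/T, and all constant (non-variable) positions match the reference
exactly; kept reads are projected to the bases at the variable positions.
Matching is exact by construction — no quality-aware or fuzzy matching — and
every rejection is tallied by reason so alternative tolerances can be
compared. Reads are assumed pre-oriented (amplicon protocol); a
reverse-complement retry is available behind a flag. Frequencies are always
computed over kept ("refined") reads, never raw reads.

## The synthetic-data generator

The generator emulates the selection experiment the analysis was built for:

* ground-truth weights: WT-gauge weight matrix with non-WT weights drawn
  log-uniformly on [0.01, 4] — the span the fitted weights occupy in
  practice, covering disrupting (W ≤ 0.1), moderate-loss (0.1 < W < 1) and
  enhancing (W > 1) substitutions;
* naïve library: uniform by default (a Dirichlet option exists for
  robustness studies, since real synthesis deviates from perfect
  equimolarity by an amount that is not precisely characterized);
* selection: deterministic first-order flipping per variant,
  `rate_scale = 5e-5` and 5 min by default so total flipping is ≈0.002%
  (the deep initial-rate regime); an optional saturation transform
  `k → k/(1+b·k)` qualitatively reproduces the compression of weight
  magnitudes at high enzyme concentration, and is off by default;
* sequencing: one multinomial draw of 5×10⁵ reads from the flipped pool
  (and optionally the naïve pool), substitution-only uniform per-base errors
  (default 0.1%, amplicon-like; no indels — the filter rejects
  length/constant-position violations regardless), constant Q40 quality
  strings (qualities are unused downstream). Every stochastic step takes an
  explicit seed.

What passing the synthetic benchmark shows: the entire pipeline — FASTQ
round trip, refinement, counting, top-3000 restriction, WT-anchored rate
conversion, gauge-fixed fitting — recovers known ground truth within the
sampling noise of the stated read depth (validation MAE in log10 k below
0.1; fitted-vs-true log-weight r² above 0.95). What it does not show:
robustness to PCR amplification bias, indels, quality-correlated errors,
paired-end artifacts, or naïve-library skew, none of which the generator
models.

## Train/validation protocol and sensitivity sweep

`train_val_split` samples `n_total` variants uniformly without replacement
and splits with `n_train = ⌊0.7·n + 0.5⌋` (200 → 140/60). WT, when present,
is always placed in the training set because it anchors the gauge. The
sensitivity sweep repeats sample→split→fit across training-set sizes with
independent seeded draws per replicate, recording train/validation MAE and
the dispersion of each identifiable log-weight across replicates; sizes
below the parameter count are flagged under-determined and retained — that
is the overfitting regime the sweep exists to expose. Validation variants
carrying unidentified weights are dropped (and tallied) rather than scored,
matching the policy of predicting only inside observed support; a replicate
whose validation set becomes empty contributes a missing value, not a zero.

## qPCR quantification

The standard curve is an OLS fit of Cq on log10(copies), requiring ≥3 points
spanning ≥2 decades. The shipped reference calibration is
slope −3.378, intercept 40.169, r² 0.998, with a linear-range floor of
~10³ copies; at the fixed 10⁹-copy reaction size this corresponds to a
detection limit of 0.0001% flipping. Inversion of the curve flags (but does
not refuse) quantifications below the linear range.

## Circuit model

The dual-attP co-expression circuit is reconstructed from the published
reaction scheme at the level of plasmid states: S (unflipped) converts
irreversibly to P1 (GFP-committed, via attP1) or P2 (mCherry-committed, via
attP2); reporters accumulate from their committed states with optional
first-order dilution. Three reconstruction choices, each switchable in
config:

1. **Rapid-equilibrium sequestration** instead of explicit bound-species
   ODEs — enzyme binding/unbinding is fast relative to catalysis, avoiding
   unknown on/off constants:
   `E_free = E_total / (1 + Kd_scale·(k1·(S+P2) + k2·(S+P1)))`.
2. **Decoy strength proportional to the site's own k** — the minimal
   assumption under which a slow attP2 sequesters little enzyme, so
   lowering k2 at fixed high k1 simultaneously lowers the mCherry:GFP ratio
   and *raises* total output (the product-inhibition trade-off).
3. **Flux first order in free enzyme**, consistent with the in vitro
   first-order treatment: `r_m = rate_calibration · k_m · E_free`.

Because the channels share `E_free`, `r1/r2 = k1/k2` at all times and the
endpoint split P1:P2 equals k1:k2 exactly — a strong internal check.
Defaults (`Kd_scale = 5`, `rate_calibration = 0.02 min⁻¹`, `E_total =
P_total = 1`, 12-h horizon, presets k ∈ {0.02, 1, 10} for low/medium/high
variants) place the system in the partial-conversion, sequestration-limited
regime where that trade-off is visible; absolute magnitudes are
configuration, not claims. Integration uses LSODA with rtol 1e-8 / atol
1e-10; plasmid conservation `S+P1+P2 = P_total` is asserted to 1e-6
relative on the reporting grid, never enforced by substitution.

## Numerical details and problem sizes

* `expm1`/`log1p` are used for flipped fractions and their inversion so the
  initial-rate regime (F ~ 1e-9) keeps full precision.
* Top-N selection breaks count ties by lexicographic variant order;
  subset frequency tables retain full-table frequencies, with a
  renormalized view available explicitly.
* Enrichment scores with a zero naïve percentage are NaN plus an explicit
  undefined flag, never silently 0.
* Degenerate IUPAC codes are rejected everywhere: library synthesis uses
  only N, and reads must be concrete.
* The shipped benchmark and acceptance script use the full library-2 problem
  size (262,144 variants, 5×10⁵ reads); unit and property tests use 2–3
  position designs (16–64 variants) where oracles are exhaustively
  checkable. One benchmark run completes in a few seconds.

## Known limitations

* The weight model is strictly position-independent; cooperative base
  interactions would be absorbed into residual error.
* The mapping of published 23-nt engineered sequences onto the half-site
  numbering is orientation-ambiguous from text alone, so mutation notation
  (`G5T,G12A,G17A`) is the primary variant interface and no full-length
  reference strings are hard-coded beyond the design's half-site.
* The circuit model is a reconstruction: explicit enzyme-binding ODEs and
  variant-specific decoy affinities are plausible alternatives behind the
  same interface, and its outputs are qualitative regimes, not fitted
  fluorescence values.
* Enrichment heat-map rendering and graphics are out of scope; the matrices
  are emitted as TSV.
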