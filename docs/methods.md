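# Methods

## Problem setting

Given a protein sequence and a candidate lysine, decide whether the lysine
is an acetylation site. Supervision is species-specific: a *target* species
with few verified sites, and *source* species with many. The package
implements a multi-source domain-adaptation scheme in which one shared
feature extractor serves all species and each source's influence on the
target model is weighted by the similarity of its feature distribution to
the target's.

## Data model

* **Windows.** Each candidate site is represented by the residue window at
  offsets −15…+15 around the lysine (length 31, odd by construction).
  Positions outside the protein are padded with the placeholder `X`;
  non-standard residues are normalized to `X` at parse time. Site
  coordinates are 1-based throughout.
* **Alphabet.** One-hot columns follow the fixed ordering
  `ACDEFGHIKLMNPQRSTVWY` + `X` (21 categories). The learning method is
  invariant to any column permutation, so the ordering is purely a
  serialization convention, recorded in every dataset manifest.
* **Labels.** Positives are annotated sites; negatives are *all other*
  lysines of the same proteins. Annotations at non-lysine residues are
  counted and dropped; out-of-range positions are errors.
* **Splits.** Per class (stratified), 10% of samples go to the test split,
  then 10% of the remainder to validation. Each split is balanced
  independently by seeded down-sampling of its majority class. Splitting
  before balancing keeps test membership independent of the balancing
  draw; balancing within each split keeps prevalence at exactly 0.5
  everywhere. Split membership is keyed by (protein id, position), so no
  site can appear in two splits.
* **Redundancy.** Homology filtering is expected to happen upstream (an
  external clustering tool; the package accepts its keep-list). A built-in
  greedy k-mer-Jaccard filter (k = 5) is provided as a labelled
  approximation for pipelines without one; it is *not* equivalent to
  percent-identity clustering.

## Network

`one-hot (B, 31, 21) → conv1d(21→128, k=3, pad 1) → ReLU → avgpool(k=2,
s=2) → LSTM(hidden 128) → final hidden state (B, 128) → affine → softmax`.

Design points that the architecture description leaves open, and the
choices made:

* Pooling position: applied to the convolution output (31 → 15 time steps,
  floor division), before the LSTM; the alternative (pooling the LSTM
  output sequence) is selectable via `pool_position="after_lstm"`.
* Nonlinearity after the convolution: ReLU.
* LSTM: single layer, unidirectional; the final hidden state is the
  embedding, so the embedding dimensionality *M* always equals the hidden
  size (128), which is exactly what the KL alignment loss consumes.
* Classifier: one affine map + softmax; no dropout by default.
* Initialization: uniform fan-in scaling per parameter family, from a
  seeded generator; two inits with the same seed are bit-identical.

The network is implemented in float64 NumPy with hand-written
backpropagation (conv, pooling, LSTM, affine, softmax-CE, and the KL term's
gradient through the softmax of the batch-mean embedding). The test suite
validates every path against central finite differences. Everything is
single-threaded deterministic: same seed, same data ⇒ bit-identical
checkpoints, with no "deterministic flag" needed.

## Losses and weighting

* **Classification**: mean binary cross-entropy over the batch, with
  probabilities clamped at ε = 1e−7. The gradient is taken through the
  fused softmax-CE form (p − y)/B; the clamp's dead zone only matters at
  saturation where the true gradient vanishes.
* **Domain difference**: embeddings of one batch are averaged, passed
  through a softmax over the M feature dimensions, smoothed by ε = 1e−8
  and renormalized; the loss is KL(p_target ‖ p_source). The expectation
  in the definition is realized as this batch-mean comparison (per-sample
  pairing across domains is undefined).
* **Weights**: the same KL values serve as the per-source divergences
  D_j.  They are smoothed across steps by an exponential moving average
  (momentum 0.9) because per-batch divergences are noisy, and mapped to
  the simplex by `α = softmax(−D)` so that *similar* sources are
  up-weighted — the stated intent of the weighting scheme.  The printed
  form of the weighting formula has the opposite sign (it would up-weight
  dissimilar sources); it is preserved verbatim under `mode="literal"` for
  comparison.  `mode="uniform"` fixes α = 1/N.  α is a schedule, not a
  parameter: no gradient flows through it.
* **Total**: `L_total = L_C^T + Σ_j α_j (L_C^{S_j} + L_KL^{S_j})`, with the
  summation over sources explicit. Every training step draws one batch per
  domain (equal batch sizes, 64 by default), recomputes D/α, and applies
  one joint Adam update (lr 1e−3) to θ and W.
* **Early stopping**: patience 10 on target-validation AUC; the returned
  model is the best-validation-AUC checkpoint. `patience=0` disables both
  early stopping and best-checkpoint selection (fixed epochs, final
  model) — used where a noisy tiny validation split would otherwise pick
  an arbitrary epoch.

Training modes: `mdda` (all sources, adaptive α), `uniform` (all sources,
α = 1/N), `ssda` (exactly one source), `ssdt` (no sources; the loss
reduces exactly to the target cross-entropy).

## Evaluation

Confusion counts use the rule *predict positive iff score ≥ threshold*.
Acc/Sn/Sp/Pre/F1 follow the standard formulas; zero-denominator ratios are
reported as 0 with an explicit flag. AUC is the trapezoidal ROC integral
(ties credited ½). The fixed-specificity operating point maximizes
sensitivity subject to achieved Sp ≥ target (default 0.900) over observed
score thresholds, breaking sensitivity ties toward higher specificity and
then the smaller threshold; no interpolation between ROC points. If no
observed threshold reaches the target the error names the best achievable
specificity. By default thresholds are chosen on the evaluated scores
themselves, matching the comparison protocol the operating point emulates.

## Synthetic world

The simulator emulates the structure of per-species acetylation data
without reproducing any real corpus:

* A species motif is a PWM over the 20 standard residues at each window
  position, centre fixed to K. Six informative positions mix a modal
  residue into a shared mildly skewed background composition (a fixed
  Dirichlet(50) draw, max/min ratio < 3) with weight `strength`; all other
  positions are pure background. Default `strength = 0.35`: weak
  positional enrichment, in line with the modest per-position biases real
  PTM motifs show, and deliberately hard enough that ~180 training windows
  do not saturate a target-only model — the data-poor regime that
  motivates domain adaptation in the first place.
* Positives of source *j* are drawn per-window from the target's motif
  with probability λ_j, else from a source-specific independent decoy
  motif. Negatives are pure background with a centre K, so the motif is
  the *only* class signal — precisely the signal the method claims to
  transfer.
* Defaults: `n_target = 200` (data-poor target), `n_source = 2000` per
  source (data-rich), three sources at λ = (1.0, 0.5, 0.0).

What the simulator does **not** model: homology/redundancy structure
between windows, proteome-scale class imbalance, compositional differences
between species backgrounds, and correlations between window positions. A
green adaptation test therefore establishes that the machinery transfers a
positional motif signal across domains and ranks sources by distributional
similarity — not that real cross-species acetylation prediction reaches
any particular accuracy.

Because the test and validation splits of a 200-sample target contain only
~20 windows each, generalization in the simulation studies is measured on
a 1,000-window i.i.d. draw from the target's generative model
(`simulate_evaluation_set`, disjoint seed stream); split-level AUC at that
size cannot resolve the effects of interest.

## Numerical choices

* Probability clamp 1e−7 (cross-entropy); distribution smoothing 1e−8
  (KL); both configurable.
* Odd sequence length under pooling stride 2: floor division (31 → 15).
* Checkpoints serialize parameters as JSON decimal strings, which
  round-trip float64 exactly; reloading reproduces predictions
  bit-identically.
* Divergence EMA momentum 0.9; α recomputed every step from the EMA.

## Known limitations

* NumPy training is CPU-bound and single-threaded; the defaults are sized
  for desk-scale studies (minutes), not proteome-scale corpora.
* The adaptive-weight and uniform-weight modes differ only through the
  divergence softmax; early in training, embedding distributions across
  domains are close, so α stays near-uniform and the two modes behave very
  similarly at small scale. The ordering (adaptive ≥ uniform > target-only)
  is directional, with the decisive gap being adaptation vs no adaptation.
* The built-in redundancy filter is a rough stand-in; use a real
  clustering tool for publication-grade datasets.
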