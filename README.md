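# mdace

Species-specific prediction of lysine acetylation sites by **multi-source
domain adaptation**.

Lysine acetylation is a reversible post-translational modification central
to chromatin regulation and metabolism. Supervised site predictors need
thousands of experimentally verified sites, which exist for only a handful
of well-studied species; for most organisms the labelled data are far too
sparse to train a deep model directly. `mdace` addresses this by training a
single CNN-LSTM feature extractor jointly on a data-poor *target* species
and several data-rich *source* species, aligning their feature
distributions and dynamically re-weighting each source by its similarity to
the target.

## Model

The prediction unit is a 31-residue peptide window centred on a candidate
lysine (offsets −15…+15, out-of-range positions padded with `X`), one-hot
encoded over the 21-letter alphabet `ACDEFGHIKLMNPQRSTVWY` + `X` into a
31 × 21 matrix. A hybrid network maps the window to a prediction

    p(y | x) = h(g(x; θ); W)

where the shared extractor *g* is: 1-D convolution (21→128 channels, kernel
3, padding 1) → ReLU → average pooling (kernel 2, stride 2) → LSTM (hidden
size *M* = 128), and the classifier *h* is an affine map with softmax.

Training minimizes, for target *T* and source domains *S₁…S_N*,

    L_total = L_C^T + Σ_j α_j ( L_C^{S_j} + L_KL^{S_j} )

where `L_C` is mean binary cross-entropy, `L_KL^{S_j}` is the KL divergence
between the softmax-normalized batch-mean embedding distributions of the
target and source *j*, and the simplex weights `α = softmax(−D)` are
recomputed each step from exponentially smoothed per-source divergences
`D_j`, so sources whose feature distribution sits closer to the target
contribute more. Four training modes reproduce the ablation arms:
`mdda` (adaptive weights), `uniform` (equal weights), `ssda` (single
source), `ssdt` (target-only).

Evaluation reports AUC plus accuracy, sensitivity, specificity, precision
and F1, including the operating point with maximum sensitivity subject to
specificity ≥ 0.900.

Because real acetylation corpora require an external database download, the
package ships a seeded simulator: per-species position-weight-matrix motifs
around a central K, with a per-source mixing coefficient λ ∈ [0, 1]
controlling how much of the target's motif each source shares (λ = 1 same
motif, λ = 0 independent). All adaptation behaviour is testable against the
known ground truth λ.

The implementation is pure NumPy (forward and backward passes are written
out and checked against finite differences in the test suite); no GPU or
deep-learning framework is required.

## Worked example

```sh
mdace simulate --seed 1 --out study/
mdace train --mode mdda --target study/target \
    --source study/source1 --source study/source2 --source study/source3 \
    --epochs 30 --seed 1 --out run/
mdace evaluate --model run/model.json --test study/target \
    --specificity 0.9 --out report.json
```

The `evaluate` step prints the metric report, e.g.:

```json
{
  "AUC": 0.6799999999999999,
  "Acc": 0.7,
  "Sn": 0.5,
  "Sp": 0.9,
  "Pre": 0.8333333333333334,
  "F1": 0.625,
  "threshold": 0.6793013955450737,
  "n_pos": 10,
  "n_neg": 10,
  "zero_denominator_flags": [],
  "tie_handling": "trapezoid (ties credited 1/2)"
}
```

i.e. on this (small, 20-window) simulated test split the model ranks a
random true site above a random non-site 68% of the time, and at the
threshold whose specificity reaches 0.900 it recovers 50% of true sites
with precision 0.83. `run/trace.csv` records per-epoch losses, the per-source α
trajectory and validation AUC; every command writes a `run_manifest.yaml`
with seeds and input checksums so runs are reproducible.

The same workflow applies to real data via
`mdace prepare --fasta proteins.fasta --sites sites.csv --species NAME --out DIR`
(annotations are 1-based lysine positions) followed by `train`/`evaluate`/
`predict`.

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
re-runs the full pipeline from scratch: it simulates the standard
three-source study (λ = 1.0, 0.5, 0.0), trains the adaptive multi-domain
model and the target-only baseline, evaluates both on a held-out draw from
the target distribution, and prints the AUCs, the sensitivity at
specificity 0.900, and the final source weights.
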