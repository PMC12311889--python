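# Methods

## The problem

A mass spectrometry image (MSI) records a full mass spectrum at every pixel
of a tissue section.  After binning to a 0.1-Da grid a single image is a
matrix of tens of thousands of pixels by thousands of m/z bins — routinely
gigabytes — which makes routine analyses (k-means segmentation, t-SNE,
archival storage) slow or infeasible.  `msicodec` compresses each pixel's
spectrum into a short fixed-length embedding with a learned encoder–decoder,
so that segmentation and visualization run on the embeddings and the
spectra can still be reconstructed, with minor quality loss, whenever needed.

## Model

The codec is a 1-D convolutional encoder–decoder over the binned spectrum
`z ∈ R^{F_s}`:

* **Encoder** — a stack of strided convolution blocks (convolution →
  per-channel batch normalization → ReLU), followed by a linear layer onto
  the embedding `w ∈ R^{F_e}`.  Default: four blocks, channels (8, 16, 32,
  64), kernel 7, stride 4, i.e. 256× temporal downsampling; `F_e = 64`.
* **Decoder** — the mirror image: a linear layer back to the flattened
  convolutional shape, then transposed convolutions in reverse order; the
  final block has no normalization or activation and emits all `F_s`
  intensity values.
* `F_s` is zero-padded up to the nearest multiple of the total stride
  (3000 → 3072 for the defaults); the padding is stripped on decode.

Training minimizes a weighted sum of four losses computed per batch of
`2N` rows, where each of the `N` selected pixels contributes its spectrum
and one *augmentation* — a noisy copy whose bins are independently scaled by
uniform factors in `[1−δ, 1+δ]`, `δ = 0.1`:

1. **Contrastive loss** (NT-Xent with cosine similarity).  For anchor `i`
   with positive partner `j`:
   `l(i,j) = −log[ exp(sim(w_i,w_j)/γ) / Σ_{k≠i} exp(sim(w_i,w_k)/γ) ]`,
   summed over all ordered positive pairs and multiplied by `α`.
   Defaults: `γ = 0.5`; `α = 1/(2N)` so the term is a per-anchor average and
   independent of batch size.  The similarity is computed on embeddings
   (the objects the remaining losses shape), and the positive pair is
   (original, one noisy copy).
2. **Mean loss** `(1/2N) Σ_i μ(w_i)²` — keeps embeddings centered at zero.
3. **Standard loss** `(1/F_e) Σ_f (σ_f(w) − 1)²` with *population* standard
   deviations per feature — keeps every embedding feature at unit spread.
   Together these give the embeddings the regular distribution that k-means
   benefits from.
4. **Decoder (MSE) loss** — mean squared error between the batch input and
   its decode, averaged over every entry.

Default weights are 10⁻¹ (contrastive), 10⁻² (mean), 10⁻² (standard) and
10⁻² (decoder); a second preset with decoder weight 1 ships for biopsy-like
use where reconstruction is emphasized.  Optimization uses Adam (learning
rate 10⁻³, L2 weight decay 10⁻⁵), batch size `N = 64`, full-pass epochs over
a seeded shuffle, early stopping after 30 epochs without relative improvement
≥ 10⁻⁶ in the weighted training loss, and restoration of the best epoch's
weights.  No validation split is used: the monitored quantity is the
training loss itself.  The network, its backward passes and the optimizer
are implemented in numpy inside `msicodec.nn`, in single precision by
default (loss math runs in double precision on the small embedding
matrices); every backward pass is validated against finite differences in
the test suite.

## Preprocessing

Raw profile-mode points are accumulated onto a uniform m/z grid by rounding
to the grid step (0.1 Da default; ties round away from zero), which conserves
total intensity exactly.  Binned spectra are then convolved with a discrete
Gaussian (σ = 0.1 Da, truncated at 4σ and renormalized to sum 1) — the
standard smoothing step of the pipeline, also recommended for centroid-mode
input — and scaled into [0, 1] by the dataset-wide maximum.  The scale is
stored in the codec so decoding restores original units.

## Segmentation and evaluation

* **k-means** (k-means++ init, 10 restarts, seeded) on raw spectra, on the
  top-128 mean-intensity bins, or on embeddings.
* **Iterative k-means** estimates the cluster count: principal components of
  the (centered) data are examined in order; for component `i`, k-means runs
  on the 1-D projection for every candidate count `c ∈ {2..10}` and the
  silhouette-optimal `c` is kept; the loop multiplies the counts (`k ← k·c`)
  until `k ≥ K` or a component shows no structure (`c = 1`).  Final clusters
  are the nonempty cells of the Cartesian product of the per-component
  assignments.
* **Structurelessness threshold.**  A mean silhouette below a threshold τ
  declares a component structureless.  On *1-D projections* k-means splits of
  a single Gaussian score ≈ 0.54–0.60 across seeds, while genuinely
  multimodal projections score ≥ 0.9, so the default is τ = 0.7 — the
  midpoint of that gap.  (Thresholds near 0.5, natural for multivariate
  silhouettes, never declare a 1-D projection structureless and make the
  procedure over-split.)
* **Convolutional smoothing** reassigns each pixel to the majority label in
  its (2r+1)×(2r+1) window (default r = 1, one iteration), synchronously;
  unlabeled pixels neither vote nor change; ties go to the smallest label.
* **Matching** assigns every predicted cluster to the baseline class most
  frequent among its pixels (ties to the smallest class id; clusters with no
  labeled pixels stay unassigned).  Two clusters may map to one class — this
  is what merges an over-segmented prediction down to the anatomical classes.
  **Accuracy** is the percentage of baseline-labeled pixels whose matched
  class equals the baseline class; unlabeled baseline pixels are excluded
  from votes and the denominator, and unassigned predictions on labeled
  pixels count as wrong.

## Synthetic data

The generator emulates the structure that makes tissue MSI segmentable:
a pixel grid partitioned into contiguous classes (stripes, nested rings, or
Voronoi cells), each class emitting 5 characteristic Gaussian peaks
(σ_peak = 0.15 Da) at class-specific m/z positions plus 10 background peaks
shared by all classes, with mean intensities uniform in [50, 100].  Noise:
each peak's amplitude is scaled per pixel by an independent log-normal
factor (σ = 0.2), and a Gaussian floor (σ = 1% of the largest mean peak)
is added and clipped at zero.  The standard image is 32 × 32 pixels, 4
nested-ring classes, 3000 bins from m/z 100.0.

What it does **not** emulate: isotope envelopes, mass-accuracy drift,
spatial intensity gradients, correlated (chemical) background, and
class-overlapping signatures.  Passing tests on these images therefore
demonstrate that the algorithmic chain is correct and recovers planted
structure under realistic noise magnitudes — not that a particular accuracy
will transfer to real tissue, where class signatures overlap heavily.

As a control, plain k-means on the raw rendered spectra already reaches
≥ 95% matched accuracy on the standard image, so codec-based tests measure
the codec rather than fixture difficulty.

## Numerical and design choices

* Binning ties round away from zero — one fixed rule keeps results identical
  across platforms.
* Augmentation noise is per-bin i.i.d. multiplicative; it preserves peak
  locations ("spectral structure") while perturbing intensities.
* Batch normalization uses exponential running statistics (momentum 0.1) for
  inference, making encoding deterministic and row-independent.
* Embeddings are stored single precision (4 bytes/value); the storage
  arithmetic (`n_pixels · F_e · 4` bytes, binary megabytes) follows from
  that.
* Problem sizes in the test suite: unit tests use a 12 × 12 / 400-bin image;
  the end-to-end acceptance checks train on the standard 32 × 32 / 3000-bin
  image for up to 100 epochs, which keeps a full run on one CPU core in the
  minutes range while leaving a wide margin on every threshold.
* The codec file carries a SHA-256 content hash (`codec_id`); embedding
  stores record it, and decoding with a different codec is refused.

## Known limitations

* The training loop is single-threaded numpy; it is meant for desk-scale
  images and method work, not for GB-scale cohorts on GPUs.
* Iterative k-means inspects principal components one at a time; cluster
  structure that only appears in joint projections can be missed.
* `read_pixel_table` accepts foreign tables only on a grid matching the
  resolution implied by the bin column names.
* t-SNE is exposed as an off-the-shelf convenience (perplexity 1000 by
  default, capped below the sample count) and is smoke-tested only.
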