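# msicodec

Contrastive-learning compression and segmentation of mass spectrometry
images (MSI).

An MSI dataset stores a full mass spectrum per pixel of a tissue section and
easily reaches gigabytes, which makes segmentation, t-SNE and long-term
storage painful.  `msicodec` trains a 1-D convolutional encoder–decoder so
that every pixel spectrum `z ∈ R^{F_s}` collapses to a fixed-length embedding
`w ∈ R^{F_e}` (64 floats by default) and can be decoded back with minor
quality loss.  It is written for MSI method developers and analysts who want
desk-scale, fully reproducible compression + segmentation experiments.

## The model

Training minimizes a weighted sum of four losses over batches of `2N` rows
(each spectrum paired with a noisy copy whose bins are scaled by independent
uniform factors in `[1−δ, 1+δ]`, `δ = 0.1`):

* an NT-Xent contrastive loss on cosine similarities,
  `l(i,j) = −log[ exp(sim(w_i,w_j)/γ) / Σ_{k≠i} exp(sim(w_i,w_k)/γ) ]`,
  summed over ordered positive pairs and scaled by `α` (default `1/2N`),
* a mean loss `(1/2N) Σ_i μ(w_i)²` pulling embeddings toward zero mean,
* a standard loss `(1/F_e) Σ_f (σ_f(w) − 1)²` pulling every embedding
  feature toward unit spread,
* an MSE decoder loss between input and reconstructed spectra.

Optimization: Adam (lr 10⁻³, weight decay 10⁻⁵), batch size 64, early
stopping with patience 30 epochs.  Segmentation runs k-means — or an
*iterative k-means* that walks the principal components one at a time,
choosing a silhouette-optimal cluster count per component and multiplying
counts until a target `K` is reached.  Predicted clusters are matched to a
baseline class map by per-cluster majority vote, which also defines the
reported accuracy.  See `docs/methods.md` for the full description.

## Worked example

```python
import numpy as np
from sklearn.cluster import KMeans
from msicodec import SpectrumCodec, synthetic_data, preprocess, segmentation, evaluation

# a ground-truthed synthetic MS image: 32x32 pixels, 4 nested-ring tissue
# classes, 3000 bins from m/z 100.0
image, baseline, _ = synthetic_data.default_fixture(seed=1)
image = preprocess.gaussian_smooth(image, sigma=0.1)

codec = SpectrumCodec(f_e=64, max_epochs=100, random_state=0).fit(image)
W = codec.transform(image)                      # (1024, 64) embeddings

rel_mse = (np.mean((codec.inverse_transform(W) - image.intensities) ** 2)
           / np.mean(image.intensities ** 2))
print(f"relative reconstruction MSE: {rel_mse:.3f}")

pred = segmentation.labels_to_map(
    KMeans(8, n_init=10, random_state=0).fit_predict(W),
    image.pixel_coords, image.width, image.height)
acc, _, _ = evaluation.evaluation_report(pred, baseline)
print(f"matched segmentation accuracy: {acc:.1f}%")
```

Output (about 3 minutes on one CPU core):

```
relative reconstruction MSE: 0.041
matched segmentation accuracy: 99.8%
```

A relative MSE of 0.041 means the decoded spectra retain ~96% of the signal
energy; 99.8% accuracy means k-means on the 64-float embeddings, matched to
the planted class map by majority vote, reproduces the ground truth almost
pixel-perfectly even though k = 8 over-segments the 4 classes (matching
merges them back).

The same pipeline is available from the shell:

```bash
msicodec simulate --out run/sim --seed 1
msicodec train    --image run/sim/image.parquet --out run/train --seed 0
msicodec encode   --image run/sim/image.parquet --codec run/train/codec.npz --out run/enc
msicodec segment  --embeddings run/enc/embeddings.h5 --out run/seg --k 8
msicodec evaluate --prediction run/seg/segmentation.csv --baseline run/sim/baseline.csv --out run/eval
```

## Storage accounting

`io_formats.estimate_encoded_size(n_pixels, f_e)` gives the embedding
payload: a 260 × 134-pixel image (34,840 pixels) encoded at `F_e = 64`
occupies 34,840 · 64 · 4 bytes = 8.5 binary MB — a 99.4% reduction of a
1.5 GB raw image.  Only the embeddings and the trained codec (a few hundred
kilobytes) need to be archived; spectra are reconstructed on demand.

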