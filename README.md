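# cgcnn

A dual-branch, attention-modulated Chebyshev graph convolutional network for
motor-imagery EEG classification, implemented in pure numpy/scipy (a small
built-in reverse-mode autodiff engine replaces a deep-learning framework, so
the package runs on a single CPU with no GPU dependencies).

The pipeline:

1. **Montage → graph** (`cgcnn.montage`): an electrode layout on an integer
   grid becomes a graph where each electrode connects to its 8 grid
   neighbours (plus a self-loop). From the adjacency we build the symmetric
   normalized Laplacian, its rescaled variant `L~ = 2L/λmax − I`, and the
   Chebyshev polynomial basis `T_k(L~)`.
2. **Representations** (`cgcnn.representations`): each trial becomes a
   spatial-temporal tensor (anti-aliased resampling to `T` steps) and a
   spatial-spectral tensor (per-electrode Welch PSD pooled into `F` bins).
   Sliding-window and additive-white-noise augmentation operate on whole
   trial sets and track provenance `trial_id`s.
3. **Model** (`cgcnn.model`): per branch — pairwise attention with row-wise
   L2 normalization, attention-modulated Chebyshev graph convolution,
   attention-contracted temporal/spectral convolution (kernel `(1,5)`,
   valid padding), global spatial then temporal/spectral aggregation, and a
   shortcut projection of the branch input; branch features are concatenated
   into a softmax head. Ablation toggles reproduce the published variants
   (single branches, plain dual branch, +aggregation, +attention).
4. **Training / evaluation** (`cgcnn.training`): Adam + cross-entropy
   (defaults lr 0.001, batch 64), stratified 5-fold cross-validation that
   splits on *source* trials and augments only inside training folds
   (leakage-safe), accuracy and Cohen's kappa.
5. **Synthetic EEG** (`cgcnn.synthetic`): band-limited oscillations with
   class-dependent topography and carrier frequency over 1/f + white noise,
   fully seeded — every other module is testable without external data.

## CLI

```bash
cgcnn simulate   --out trials.h5 --trials-per-class 100 --seed 0
cgcnn write-config --out run.yaml          # then edit paths/params
cgcnn preprocess --config run.yaml --out tensors.h5
cgcnn train      --config run.yaml --out weights.h5
cgcnn evaluate   --config run.yaml --out cv.json
cgcnn predict    --config run.yaml --weights weights.h5 --out probs.csv
```

`simulate` also writes the matching montage CSV (`<out>.montage.csv`,
header `name,row,col`). All randomness flows from the single `seed` in the
config via named substreams.

## Notes

- Example montages are grid reconstructions; the exact per-dataset grids
  used in the original experiments are not published.
- Reproduction of the published per-subject accuracies on the four public
  BCI datasets is out of scope (external downloads, GPU-scale training).
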