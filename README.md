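# eeggnn

Cross-modal temporal–spectral graph neural network toolkit for classifying
5-second EEG segments as spasm/seizure vs. background.

Each segment is represented as **two graphs over the 16-channel 10–20
montage** (Fp1…T6):

- a **temporal graph** — edge weights are sliding-window Pearson dynamic
  functional connectivity averaged over windows; node features are the
  z-scored series;
- a **spectral graph** — edge weights are the broadband (0.7–40 Hz) weighted
  phase lag index from Hann-windowed, 50%-overlap cross-spectra; node
  features are per-band log Welch power (delta/theta/alpha/beta/gamma).

The classifier runs both graphs through multi-scale 1-D convolutional
encoding (kernels 100/50/25), a shared-width projection, edge-conditioned
graph convolution (an MLP maps each scalar edge weight to a D×D kernel,
mean-aggregated over neighbors with ReLU + LayerNorm), softmax attention
pooling into five anatomical regions (frontal, central, parietal, occipital,
temporal), bidirectional multi-head cross-modal attention, gated fusion, and
a two-layer classifier with dropout. Training uses Adam with focal loss and
patient-grouped cross-validation (grouped stratified k-fold and
leave-one-patient-out); explanations use gradient×input attribution per
modality, fused with a fixed coefficient (default 0.5), averaged over time
into per-channel scores, aggregated into per-region evidence, and rendered
as scalp topomaps.

The neural network is implemented on a small in-repo reverse-mode autodiff
engine over NumPy (`eeggnn.autodiff`) — no deep-learning framework is
required — and EDF reading/writing is self-contained. A synthetic-data
module generates labeled 16-channel EEG with controlled spasm-like events in
known channels, so the full pipeline is testable without any external data.

## Test

```bash
python -m pytest tests/
```

The suite includes `tests/test_acceptance.py`, which trains the end-to-end
synthetic benchmark twice (≈10 min on one CPU); everything else runs in well
under a minute.

## CLI

```bash
# generate a synthetic labeled corpus (with ground truth)
eeggnn simulate --seed 1 --out epochs/

# preprocess an EDF recording into labeled 5-s epochs
eeggnn preprocess --in recording.edf --annotations ann.csv --out epochs/

# build temporal + spectral graphs
eeggnn build-graphs --epochs epochs/ --out graphs/ --modality both

# patient-grouped cross-validated training
eeggnn train --epochs epochs/ --graphs graphs/ --protocol kfold --out run/

# attribution topomaps + channel/region score CSV
eeggnn explain --checkpoint run/fold0.ckpt.npz --epochs epochs/ --out maps/
```

`preprocess` applies the fixed pipeline: channel selection → resample to
250 Hz → 0.7–40 Hz zero-phase Butterworth bandpass → average reference →
5-s epoching (any-overlap event labeling) → per-epoch per-channel z-score.

Annotations are CSV rows `onset_s,duration_s,label`; CHB-MIT-style
`*-summary.txt` files are also supported
(`eeggnn.io.read_chbmit_summary`).

## Layout

| module | contents |
| --- | --- |
| `eeggnn.io` | EDF read/write, epoch/graph stores, checkpoints, annotations |
| `eeggnn.preprocess` | channel selection, resampling, bandpass, re-referencing, epoching, z-score |
| `eeggnn.graphs` | windowed Pearson + wPLI graph builders, band-power node features |
| `eeggnn.autodiff` | minimal tape-based autodiff (Tensor, conv1d, einsum, Adam) |
| `eeggnn.model` | the classifier: encoder, ECC, region pooling, cross-attention, fusion |
| `eeggnn.train_eval` | focal loss, metrics (incl. rank AUC), grouped splits, training loop |
| `eeggnn.explain` | gradient×input attribution, fusion, region evidence, topomaps |
| `eeggnn.synth` | synthetic EEG generator with ground-truth event records |
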