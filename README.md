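# mdte — multi-domain transfer-entropy EEG state classification

`mdte` implements a hybrid pipeline for classifying mental states (e.g.
baseline vs. task-induced stress) from multichannel EEG. It is aimed at
researchers in computational neurophysiology who want a reproducible,
fully-testable implementation of connectivity-based EEG classification —
including a synthetic-data generator that emulates the statistical
structure the method exploits, so everything runs without access to any
private recordings.

## The method

Given 32-channel EEG at 512 Hz, the pipeline is:

1. **Preprocessing** — per-channel baseline (mean) correction, common
   average reference (CAR), zero-phase 0.5–60 Hz Butterworth band-pass and
   50 Hz notch, then segmentation into non-overlapping 2 s epochs.
2. **ICA denoising** — whitening-plus-rotation independent component
   analysis (`Z = QX`, `W = BᵀQ`, fixed-point negentropy maximization);
   heavy-tailed (high-kurtosis) components, typical of ocular/muscular
   artifacts, are removed and the signal reconstructed.
3. **Multi-domain representation** — each epoch channel is transformed by
   the discrete fractional Fourier transform (FrFT) at orders
   p ∈ {0, 0.5, 1}: time, time–frequency and frequency domains. The
   absolute coefficient amplitude |X_p(u)| is kept. The FrFT operator is
   built from the discrete Hermite eigenbasis of the DFT, so it is exactly
   unitary, order-additive (F^a F^b = F^{a+b}) and periodic with period 4.
4. **Directed connectivity** — for every ordered channel pair (i, j) and
   every domain, the transfer entropy
   TE(i→j) = H(j_{t+1} | j_t) − H(j_{t+1} | j_t, i_t)
   is estimated in bits from quantile-binned sequences (8 symbols,
   history k = 1), giving a 32 × 32 directed connectivity matrix per
   domain; the three matrices are cascaded into one 32 × 96 image per
   epoch.
5. **PCANet features** — a two-stage PCA network: 3 × 3 patch PCA filters
   (9 per stage), same-size convolution, binarization and bitwise hashing
   of the stage-2 maps into integers in [0, 511], and 32 × 32 block
   histograms at 0.5 overlap → a 9 · 512 · 5 = 23,040-dimensional count
   vector per epoch.
6. **Classification** — linear SVM (C = 2, one-vs-one for three classes)
   under stratified 10-fold cross-validation, with the PCANet filters and
   feature standardization refitted on the training folds of every split.
   Reported metrics: accuracy, sensitivity and specificity in percent.

The synthetic generator produces stable VAR(2) recordings whose states
differ only in their sparse directed coupling topology — exactly the
structure transfer entropy detects — plus 50 Hz line interference,
Poisson-timed ocular transients and sensor noise for the preprocessing and
ICA stages to remove.

## Worked example

```python
from mdte.io_formats import PipelineConfig
from mdte.synthetic_eeg import two_state_spec
from mdte.pipeline import run_all

cfg = PipelineConfig(seed=1)
report, manifest = run_all(cfg, spec=two_state_spec(seed=1))
print(f"acc={report.accuracy:.1f}% sen={report.sensitivity:.1f}% "
      f"spe={report.specificity:.1f}%")
```

prints

```
acc=100.0% sen=100.0% spe=100.0%
```

i.e. with two 5-minute simulated states (150 epochs each) whose coupling
topologies differ by 12 directed edges at gain 0.8, the cascaded
multi-domain representation separates the states perfectly under 10-fold
CV, while the same pipeline on permuted labels scores ≈ 50 % (chance).
The same run is available from the shell:

```bash
mdte run-all --seed 1 --out workdir/
```

Each stage also has its own subcommand (`mdte simulate`, `mdte preprocess`,
`mdte ica`, `mdte frft`, `mdte tren`, `mdte pcanet fit/transform`,
`mdte classify`) operating on plain EDF/CSV/JSON files.

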