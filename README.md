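# coiscal

COI-aware wavelet-scalogram classification toolkit for ERP/EEG signals.

The continuous wavelet transform of a finite epoch contains edge-artifact
coefficients wherever the wavelet footprint extends past the observation
interval; the cone of influence (COI) separates those from the accurately
computed ones. `coiscal` builds analytic-Morlet scalograms with explicit
full/same/valid convolution semantics, delineates the COI, and extracts
four feature representations from one scalogram:

* **S** — the entire (same-convolution) scalogram, row-concatenated;
* **Z** — the same vector with out-of-COI entries zeroed;
* **V** — only the in-COI (valid-convolution) entries;
* **V̄** — the out-of-COI complement (a control representation).

Around that core it provides:

* **m-subsample averaging (m-SA)** — generation of arbitrarily large
  ensembles of m-trial averages from a small single-trial ensemble, with
  per-average source-trial bookkeeping and a fold protocol that keeps
  train and test sets mutually exclusive at the single-trial level;
* **rank-of-rank-sum (RRS) channel ranking** — channels scored by a
  scatter-normalized interclass separation, ranked per class pair,
  rank-summed and re-ranked per subject, then across subjects;
* **a classifier zoo** — RBF-kernel SVM (inner grid search), random
  forest, k-NN, and MLP on scikit-learn, plus 1-D and 2-D convolutional
  networks on a small self-contained NumPy backend (the 2-D network
  accepts only equal-row matrix input, so it runs on S/Z but not V);
* **an experiment harness** — multi-run, k-fold comparison of every
  (approach, classifier) pair on identical splits, accuracy records,
  summary tables with a vector-family global average, relative
  improvements, and Student-t confidence intervals;
* **synthetic fixtures** — two-class oscillatory trial generators with
  controllable component frequencies, latencies, amplitudes, jitter and
  noise, so every stage runs without external data.

## CLI

Trial data lives in a long-format TSV (`# fs=<Hz>` header line, then
columns `subject  channel  label  trial  s0 s1 ...`); see
`coiscal.io.save_trials`.

```sh
coiscal rank-channels trials.tsv --top-k 8
coiscal make-ensembles trials.tsv -m 4 -k 5 --channel Cz --out run.json
coiscal extract-features trials.tsv --approach V --channel Cz --out feats.tsv
coiscal train-eval trials.tsv --families SVM,RF,KNN --approaches S,Z,V \
    --channel Cz -m 4 -k 5 --runs 10 --records-out records.tsv
coiscal report records.tsv
```

Wavelet options (`--f-min/--f-max/--voices/--cycles/--truncation`) are
shared by the feature and evaluation commands.

## Library sketch

```python
import numpy as np
from coiscal import (
    FrequencyGrid, Signal, WaveletParams,
    compute_coi, cwt_scalogram, extract,
)

fs, n = 200.0, 200
grid = FrequencyGrid.logarithmic(2.0, 40.0, voices_per_octave=12)
params = WaveletParams(cycles=6, truncation="2pct")
signal = Signal(np.random.default_rng(0).standard_normal(n), fs)

coeffs, scalogram = cwt_scalogram(signal, grid, params, mode="same")
coi = compute_coi(grid, n, fs, params)
v_features = extract(scalogram.G, coi, "V")
```
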