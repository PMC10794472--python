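# pa-ssid

Subspace identification and modal-feature classification of photoacoustic
(PA) sensor traces.

Each trace is modeled as the impulse response of a discrete-time
state-space system estimated directly from the data by a subspace (N4SID
style) algorithm: block-Hankel construction, projection of future onto past
outputs, SVD with singular-value-gap order selection, observability/state
reconstruction, and a linear least-squares solve for (A, B, C).  The fitted
second-order model is converted to continuous time (matrix logarithm / ZOH
relation) and rotated into a canonical modal form whose four parameters —
decay time constant `alpha`, natural frequency `omega_n`, and modal mixing
amplitudes `c1`, `c2` — serve as features for five-class blood-sample
classification with linear discriminant analysis (LDA).  Time-domain,
frequency-domain (spectral line fit over 1–20 MHz), and ARMA(2,2)
coefficient features are implemented as comparison baselines.

Because no measurement data are publicly deposited, the package ships a
synthetic generator (`pa_ssid.synthetic`) producing labeled underdamped
second-order traces with class-dependent parameter distributions for five
classes (HF, HM, A1, A2, L); all numeric class defaults are invented,
documented, and overridable via JSON configuration.

## Layout

| module | contents |
| --- | --- |
| `pa_ssid.signal` | `PASignal` trace container, onset detection |
| `pa_ssid.synthetic` | class parameter tables, damped-sinusoid generator, dataset simulation |
| `pa_ssid.subspace` | Hankel split, projection, weighted SVD, order selection, system-matrix solve, NRMSE |
| `pa_ssid.modal` | discrete→continuous conversion, canonical modal form, SS feature extraction |
| `pa_ssid.baselines` | time-domain, spectral (periodogram + band line fit), and Hannan–Rissanen ARMA features |
| `pa_ssid.classify` | ANOVA + Bonferroni, Fisher LDA (optional shrinkage), confusion/accuracy, confidence ellipses, benchmark |
| `pa_ssid.io` / `pa_ssid.cli` | text signal format, run configuration, report writer, `pa-ssid` CLI |

## CLI

```sh
pa-ssid simulate  --out data/ --seed 42              # synthetic dataset + manifest.csv
pa-ssid identify  --in data/signal_000.txt --i 20 --out model.json
pa-ssid features  --family ss --in data/ --out features.csv
pa-ssid features  --family fd --in data/ --band 1e6:2e7 --out fd.csv
pa-ssid classify  --features features.csv --train-manifest train.txt \
                  --test-manifest test.txt --out report/
pa-ssid benchmark --seed 7 --out report/             # full four-family pipeline
```

Signal files are plain text: `# ts=…`, `# t0=…`, `# label=…` headers
followed by one amplitude per line.

## Notes

* The identification default decimates heavily oversampled input (0.2 ns
  hardware sampling) to 100 MS/s by stride after onset alignment; for
  exponential-modal signals this is an exact model-rate change.
* The modal canonicalization fixes the similarity freedom by mapping the
  initial-state vector to `[1, 0]ᵀ` (scale absorbed into the output
  matrix), making `(c1, c2)` unique and reproducible; `alpha` is stored as
  a time constant in seconds.
* Overdamped (real-eigenvalue) fits are excluded from downstream statistics
  with a logged warning rather than coerced.
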