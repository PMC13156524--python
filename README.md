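# trfaad

Temporal response function (TRF) estimation and auditory attention decoding
(AAD) for wearable EEG, with a fully synthetic data generator so the entire
analysis is testable end-to-end without any recordings.

The pipeline mirrors a three-condition selective-listening paradigm:

- **SustAC** — sustained attention to one of two competing talkers,
- **SwitAC** — attention switching between talkers twice per 180-s trial
  (switch times drawn from U(35, 55) s and U(125, 145) s),
- **ConvAC** — a two-talker front conversation with a competing side talker,

recorded with a 44-channel scalp montage plus a 20-electrode around-the-ear
(cEEGrid) array.

## What's inside

| Module | Role |
| --- | --- |
| `trfaad.synth` | Synthetic sessions: speech-like envelopes, ground-truth P1/N1/P2 kernels, condition protocol, spatially mixed 1/f noise at configurable SNR |
| `trfaad.features` | Gammatone filterbank (128 ERB-spaced bands, 80–15 000 Hz), acoustic envelope and acoustic-onset features, 1–20 Hz / 50 Hz / z-score preparation |
| `trfaad.preprocess` | EEG chain: rereferencing (common average / linked L4-R4), 50-Hz notch, 0.1–40 Hz and 1–20 Hz zero-phase FIR bandpasses, resampling to 50 Hz, normalization |
| `trfaad.trf` | Forward/backward TRFs on lags −1…1 s, Hamming-window basis (50-ms width), sparse boosting minimizing MAE with inner-validation early stopping |
| `trfaad.evaluate` | Leave-one-trial-out CV, decision-window classification (1.1–178 s), optimal-lag scans (45-ms windows, 15-ms steps, −600…600 ms), cross-condition generalization |
| `trfaad.stats` | Gaussian TRF smoothing, mass-univariate t-maps, threshold-free cluster enhancement with max-statistic permutation p-values, Benjamini–Hochberg FDR, paired t-tests |
| `trfaad.pipeline` / `trfaad.cli` | YAML configuration, orchestration, manifests, CSV/HDF5/EDF/WAV I/O |

## CLI

```bash
trfaad config --out config.yaml            # dump the default configuration
trfaad simulate --seed 1 --out raw.h5      # synthesize a session container
trfaad preprocess raw.h5 --out prep.h5     # EEG chain + feature preparation
trfaad fit prep.h5 --condition SustAC --out kernel.h5
trfaad evaluate prep.h5 --condition SustAC --out scores.csv
trfaad lagscan prep.h5 --condition SustAC --out lagscan.csv
trfaad stats prep.h5 --out stats_out/
trfaad features speech.wav --feature envelope --out envelope.csv
trfaad run --config config.yaml --seed 42 --out results/
```

Every stage is a pure function of (config, seed); `trfaad run` writes a JSON
manifest (config digest, seeds, stages) sufficient to reproduce any output.

## Acceptance

The acceptance criteria are property-based (convolution identities, kernel
recovery, classifier calibration at chance on null sessions, window-length
monotonicity, cross-condition generalization, optimal-lag localization,
TFCE/permutation calibration and power, filter contracts) and live in
`tests/test_acceptance.py` — one test per criterion, run with the normal
suite. Simulation-based criteria use reduced-scale sessions (fewer
channels, shortened trials) to stay within CI budgets.

The report script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

first runs a deterministic end-to-end smoke pass (exiting non-zero on any
breakage) and then writes the acceptance report. No numeric acceptance
targets are defined for this build — the source study's headline accuracies
were computed on a non-public participant dataset — so the report is an
empty JSON object and the property-based suite is the acceptance authority.
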