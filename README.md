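# semgvowel

A tested, reusable pipeline for recognizing silently-articulated vowels from
single-channel facial surface EMG (sEMG):

1. **synthetic** — class-conditioned synthetic sEMG generator (resonantly
   filtered Gaussian noise under an attack–sustain–decay envelope),
   corrupted with DC offset, 50 Hz mains hum, slow drift and measurement
   noise. The original study's recordings are not publicly deposited, so
   every downstream stage is developed and tested against this generator.
2. **preprocessing** — DC removal, zero-phase Butterworth band-pass
   (0.15–450 Hz) and a zero-phase 50 Hz IIR notch (Q = 30), applied to the
   continuous recording before segmentation.
3. **features** — a 57-value multi-domain catalogue per trial:
   9 time-domain moments, 13 entropy/complexity descriptors (Hjorth,
   envelopes, Higuchi FD, Lempel–Ziv, Rényi/Shannon/Tsallis, Hurst,
   ApEn/SampEn), 9 spectral descriptors (flatness, flux, entropy, SEF/SEP
   at 80/90/95 %), and 26 time–frequency statistics from an in-repo
   Symlet-4 level-3 discrete wavelet transform.
4. **feature_selection** — greedy mRMR ranking (relevance − redundancy) on
   3-state z-threshold discretized features, mutual information in bits.
5. **classifier** — one-hidden-layer tanh network sized by the
   `2·n_inputs + 1` rule, trained with Møller's scaled conjugate gradient
   (implemented from scratch, gradient-checked) with 70/15/15 split and
   validation-based early stopping.
6. **evaluation** — stratified 10-fold cross-validation with per-fold
   selection/scaling refits (leakage-audited), pooled confusion matrix,
   per-class accuracy and one-vs-rest ROC.

## CLI

Every stage is a subcommand of `semgvowel`; configuration is YAML with
strict key validation, and `--seed` makes any run bit-reproducible.

```bash
semgvowel simulate  --seed 11 --out runs/sim
semgvowel preprocess --sim-dir runs/sim --out runs/trials.csv
semgvowel extract   --trials runs/trials.csv --out runs/features.csv
semgvowel select    --features runs/features.csv --k 12 --out runs/selection.json
semgvowel train     --features runs/features.csv --selection runs/selection.json --out runs/model.json
semgvowel evaluate  --features runs/features.csv --folds 10 --out runs/eval
semgvowel run-all   --seed 11 --out runs/full     # all of the above + manifest
```

## Notes on reported accuracies

The study this pipeline re-implements reports 82.3 % overall / 84.27 %
ten-fold accuracy on an 8-subject dataset that was never deposited. Those
numbers are **not reproducible** here and are not acceptance surfaces; the
repository instead verifies end-to-end class recovery on its own synthetic
benchmark (pooled 10-fold accuracy well above chance, label-shuffled
control at chance).
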