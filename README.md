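# canicoh

Analysis toolkit for comparative vocal-rhythm and speech-tracking studies:
amplitude-envelope rhythm estimation for vocal sequences, command-word-stream
stimulus construction and manipulation (speech type × speech rate),
EEG evoked power and cerebro-acoustic coherence with a surrogate null,
behavioural intelligibility indices, and the matching statistical layer.
A seeded synthetic-data module generates audio, EEG and tabular fixtures
with known ground truth, so the entire pipeline is testable offline.

## Modules

| module | contents |
|---|---|
| `canicoh.synth` | call trains, word streams, envelope-locked EEG epochs, paired speaker tables — all seeded and deterministic |
| `canicoh.acoustics` | Hilbert envelope, Morlet modulation-spectrum rhythm estimate, dominant frequency, autocorrelation F0 tracker, PIC (CVb / mean CVw) identity-coding index |
| `canicoh.stimulus` | stream building (high-pass, −2 dBFS normalisation, jittered silences), normal / content-only / prosody-only resynthesis, phase-vocoder tempo change, word & syllable rate extraction |
| `canicoh.eeg` | FIR band-pass + notch preprocessing, z-threshold artifact rejection, baseline-normalised Morlet power, peak-power frequency, lagged-ridge stimulus reconstruction |
| `canicoh.coherence` | cerebro-acoustic coherence spectra, randomised-envelope surrogate null, delta/theta and rate-centred band summaries |
| `canicoh.behaviour` | human (proportion-correct) and dog (best-response) intelligibility indices on a common 0–1 scale |
| `canicoh.stats` | paired t, Mann–Whitney U, Kruskal–Wallis + Dunn/Bonferroni, REML mixed models with per-term F tests |
| `canicoh.supplements` | loaders and analyses for the deposited supplementary-table layouts |

## CLI

Everything is reachable through one entry point:

```bash
canicoh synth calls --rate 2 --duration 10 --seed 1 --out calls.wav
canicoh synth stream --n-words 5 --silence-ms 300 --jitter-ms 50 --seed 1 --out stream.wav
canicoh acoustics calls.wav --band 100:3900 --env-lowpass 20 --order 4
canicoh stimulus w1.wav w2.wav w3.wav --mode content_only --factor 2 --out out.wav
canicoh synth eeg --coupling 2 --n-trials 20 --out epochs.csv
canicoh coherence epochs.csv epochs.envelope.csv --grid 1:20:0.1 --window 0.6:1.3 --null-runs 100 --seed 0 --out coh.csv
canicoh behaviour score responses.csv
canicoh stats paired-t pairs.csv ads_rate_hz dds_rate_hz
canicoh stats lmm perception.csv "intelligibility ~ word_coh + C(speech_type)" subject
```

## Notes on method choices

- Pitch manipulation is a phase-warp resynthesis: the unwrapped Hilbert
  phase of the fundamental band is used as an exact cumulative pitch
  contour, and contour changes are monotone time warps between phase
  tracks. Integral-matched warps are exact inverses, so flatten→restore
  ("normal" mode) and reverse→reverse round trips cancel to interpolation
  error.
- Coherence pools Morlet cross-spectral terms over time points and trials
  before a single normalisation; transforms are circular so the surrogate
  null (pool draw + random circular shift) reuses precomputed envelope
  transforms exactly.
- Mixed-model F tests use a between-within (containment) denominator-df
  approximation; a Kenward–Roger implementation is not available in this
  environment (documented in the fit output `note`).
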