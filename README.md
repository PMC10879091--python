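# fbft — forward–backward Fourier transform for biomedical signals

`fbft` turns multi-channel biomedical recordings — EEG, headband exports,
heart-sound audio — into classifier-ready time–frequency (TF) images. It is
aimed at researchers who want to feed EEG or phonocardiogram data to image
classifiers (or to human readers) and need a TF representation that localises
transient oscillations sharply in both time and frequency.

The pipeline has three stages:

1. **Channel selection.** For channels $x_1,\dots,x_n$ the absolute Pearson
   correlation $|r_{x_i x_j}|$ is computed for every pair, giving a
   correlation matrix; each channel is scored by its **mean correlation
   coefficient** (mCC), the mean of its column. Channels with *low* mCC carry
   the least redundant information and are kept.

2. **The forward–backward Fourier transform (FBFT).** For each time index
   $u$ of a signal $x$ of length $n$, both the prefix $x[0{:}u{+}1]$ and the
   suffix $x[u{:}]$ are zero-padded to a common length and Fourier
   transformed, and the element-wise **minimum** of the two magnitude
   spectra is kept:

   $$X[f, u] = \min\big(\,|\mathrm{FFT}(x[0{:}u{+}1])|_f,\; |\mathrm{FFT}(x[u{:}])|_f\,\big)$$

   A frequency survives the minimum only while both halves contain it — so a
   tone active on $[a, b)$ produces a ridge at its frequency exactly inside
   $[a, b)$, without a windowing trade-off. Standard baselines (STFT
   spectrogram, CWT scalogram, DWT band map, power spectrum) are provided on
   the same grid for comparison.

3. **Imaging.** Each window's TF map is min–max normalised (optionally
   log-compressed), per-channel images are composed into one RGB (≤3
   channels, positional planes) or vertically concatenated (any number)
   picture, and resized with cubic interpolation to a CNN input geometry
   (224×224×3, 227×227×3 or 256×256×3).

A synthetic module generates ground-truth signals — gated-sinusoid
composites and latent-mix multi-channel surrogates with planted correlation
structure — so the whole pipeline is testable without downloading any data.

## Worked example

```python
import fbft

sig = fbft.three_tone_preset()          # 10, 20, 60 Hz in consecutive 1 s slots, fs=500
tf = fbft.fbft(sig.samples[0], fs=sig.fs)
for f0, a, b in fbft.THREE_TONE_INTERVALS:
    print(f0, round(fbft.ridge_frequency(tf, a, b), 2))
```

prints

```
10.0 9.89
20.0 20.14
60.0 60.06
```

— in each one-second interval the dominant FBFT ridge sits on the active
component's frequency to within one bin of the 0.12 Hz grid
(pad length 4096 at fs = 500 Hz). The same flow from the shell:

```bash
fbft simulate --preset three-tone --seed 1 --out sig.csv
fbft transform --in sig.csv --fs 500 --out tf.npz
fbft render --in tf.npz --out tf.png            # 224x224 RGB image
```

and the full batch pipeline (read → clean → select channels → window →
transform → render → export, with a JSON manifest and resolved config in the
output directory) runs from a YAML/JSON config via `fbft batch --config run.yaml`.

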