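# Methods

## The transform

For a real, uniformly sampled signal $x[0..n-1]$ the forward–backward
Fourier transform evaluates, at each time index $u$,

$$X[f,u]=\min\big(|\mathrm{FFT}_{L}(x[0{:}u{+}1])|_f,\;|\mathrm{FFT}_{L}(x[u{:}])|_f\big),$$

where $\mathrm{FFT}_L$ denotes the FFT after zero-padding the subarray to a
common length $L$. The intuition: the prefix spectrum "knows about" a
frequency component only after its onset, the suffix spectrum only before
its offset, so their pointwise minimum is large exactly while the component
is active. Unlike a sliding-window spectrogram there is no fixed analysis
window, hence no single time–frequency resolution trade-off; the price is
cost (one FFT pair per evaluated time index) and the loss of phase — the
map stores magnitudes only, since a minimum of two complex numbers is not
defined and the construction is explicitly a minimum-magnitude analysis.

Conventions fixed here:

* **Alignment.** Column $u$ pairs prefix `x[0:u+1]` with suffix `x[u:]`;
  sample $u$ belongs to both. This is the unique alignment under which the
  continuous definition (an indicator split at $u$) and the discrete
  procedure (a forward list of prefix FFTs and a reversed backward list of
  suffix-from-the-end FFTs) coincide. The continuous form's strict
  inequalities would exclude sample $u$ from both halves; the discrete
  procedure includes it in both, and the discrete reading is implemented.
* **Pad length.** Default $L$ = the smallest power of two ≥ $2n$. All
  subarrays share one frequency grid ($f_k = k\,f_s/L$, one-sided,
  $L/2+1$ bins) and FFTs stay fast. $L < n$ is rejected: padding must
  extend the signal, never truncate it.
* **Raw vs normalised magnitudes.** Spectral magnitude grows with subarray
  length, so the map brightens toward the middle of the record. The default
  keeps raw magnitudes (faithful to the defining procedure); an opt-in flag
  divides each prefix/suffix spectrum by its subarray length before the
  minimum, for visualisation.
* **Stride.** The evaluated time grid is $0, s, 2s, \dots$ and always
  includes $n-1$. The literal reference implementation (`fbft_reference`)
  is stride-1, list-based, and exists as the oracle: the fast path at
  stride $s$ must equal it restricted to the same columns (asserted in
  tests to $10^{-12}$, plus an independent $O(n^2)$ direct-DFT check).
* **Ridges.** The dominant frequency of an interval is the arg-max of the
  time-averaged magnitude over the interval's columns, excluding the DC
  bin. An all-zero interval returns the sentinel `None` rather than an
  arbitrary bin. With `top_k > 1`, peaks are ranked by prominence.

Properties that hold by construction and are asserted as tests: the map
never exceeds either contributing spectrum; time-reversing the signal
mirrors the time axis; scaling the signal by $c$ scales the map by $|c|$;
FFT magnitude is invariant to circular shifts of the padded sequence.

Cost: $O(n)$ FFTs of length $L$ per window, i.e. $O(nL\log L)$. Windows of
a few thousand samples keep desk runtimes in seconds; the `stride`
parameter thins the time grid for longer records.

## Channel selection

The mCC score of a channel is the mean of its column of the absolute
Pearson correlation matrix, **diagonal included** — the rule is read
literally as the column mean, and including the self-correlation shifts
every score equally by $1/n$, so the ranking is unaffected either way.
Selection keeps the $k$ lowest-mCC channels in ascending order, ties broken
by original channel order; $k$ is a user parameter (default 4 in the CLI,
matching typical 4–6-channel use). A constant (dead) channel makes the
correlation a 0/0 form; it is scored 0 with a warning, so it ranks as
maximally unique and surfaces for human review instead of crashing a batch.
Correlation is computed once on the full cleaned recording per subject, not
per window.

## Synthetic data

* **Composite tones** sum components
  $a_k \sin(2\pi f_k t + \phi_k)\,\mathbf 1\{t^{on}_k \le t < t^{off}_k\}$
  plus optional seeded Gaussian noise; components violating Nyquist are
  rejected by name. The `three-tone` preset places 10, 20 and 60 Hz
  components in consecutive 1 s intervals. Only the three frequencies are
  given by the source material; amplitude 1, fs = 500 Hz, 3 s duration and
  the consecutive 1 s intervals are this package's documented defaults.
  Activity windows may overlap (components sum).
* **Latent-mix surrogates** set channel $i$ to
  $\lambda_i\,g(t) + \varepsilon_i(t)$ with $g$ a shared white-Gaussian
  source low-pass filtered to 0–40 Hz (4th-order zero-phase Butterworth,
  unit variance) — an EEG-like spectrum with a planted correlation
  structure, not a biophysical model — and $\varepsilon_i$ independent
  Gaussian noise of sd `noise_sd`. A zero-loading channel among
  unit-loading channels is the planted "most unique" channel the mCC
  ranking must recover (asserted over 20 seeds at 5 000 samples,
  noise sd 0.3).

What passing these tests shows: the transform localises known components,
and the selection recovers planted independence, on clean surrogates. What
it does not show: robustness to artifacts, drift, line noise, volume
conduction or non-stationary spectra of real recordings — the generators
model none of these.

## Imaging

Per map: optional $\log(1+m)$ compression, min–max normalisation over the
*whole* map (per-window, never global across windows, so each image uses
its full dynamic range and no amplitude leaks between windows), frequency
increasing upward, cubic (bicubic) resampling to the target geometry with
post-clip to $[0,1]$ since cubic kernels overshoot at edges. An
all-constant map renders as zeros. Composition: `rgb` maps up to three
channel images positionally onto the red/green/blue planes (missing planes
zero); four or more channels must use `concat`, which stacks images
vertically (one shared time axis per row) and replicates the grayscale into
three planes. Supported output geometries include 224×224×3, 227×227×3 and
256×256×3; geometry is configuration, not hard-coded. Exports are
deterministic — file names encode subject, window start and transform, the
manifest contains no timestamps, and reruns are byte-identical.

## I/O and windowing

EDF is read via `mne`, WAV via `scipy.io.wavfile`, delimited text via
`pandas` (one column per channel, header row of names). Text carries no
sampling rate, so `fs` is a required explicit parameter for it — never
guessed. Heart-sound audio is passed through at its native rate;
resampling, filtering, re-referencing and artifact rejection are out of
scope (cleaning is NaN removal only: drop any time index with a non-finite
value in any channel, or per-channel linear interpolation with edge
extension). Windows have exactly `round(window_s * fs)` samples (avoiding
off-by-one drift for non-integer products), start at
$k\,(\text{window} - \text{overlap})$ on the sample grid, use half-open
time intervals, and the trailing partial window is discarded to keep image
sizes uniform; a window longer than the record yields an empty list with a
warning so batch runs skip short files.

## Problem sizes used in the checks

The shipped checks run the three-tone preset (1 500 samples, pad 4 096,
stride 1), equivalence sweeps over 50 random signals of length 16–256,
direct-DFT comparisons at $n \le 64$, 20-seed planted-recovery runs at
5 000 samples × 5 channels, and a 10 s / 1 s / 0.25 s windowing pipeline —
sizes chosen so the whole suite completes in seconds on one CPU while still
exercising every code path at realistic EEG window scales.

## Known limitations

Magnitude-only (no phase, no inverse); raw-magnitude maps brighten toward
the record centre unless normalisation is enabled; ridge extraction is
arg-max based and assumes one dominant component per interval; the CWT
adapter's log-spaced scale grid limits its frequency precision; the DWT
"map" is a piecewise-constant band image, not a dense TF estimate.
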