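# Methods

This document defines the quantities the package computes and records the
conventions and numerically load-bearing choices behind them.

## 1. Synthetic cohort model

Each subject is an epoched recording of `C` channels × `Nt` trials ×
`T` samples (defaults 16 × 60 × 2001 at 1 kHz, epoch −1…+1 s around the
pulse at t = 0).  The signal is

```
x_c(n, t) = background_c(n, t) + Σ_k  a_k · cos(2π f_k t + φ_k(n) + [lag if c = b_k])
```

* `background` is 1/f (pink) noise, independent per channel and trial.
* Each coupling `k` acts on a channel pair `(a_k, b_k)` and a band; its
  carrier frequency is the geometric mean of the band edges, with phase
  continuity across each trial.
* The cross-trial phase offset `φ_k(n)` is drawn per trial from a von Mises
  distribution whose concentration switches from `κ_pre` to `κ_post` at the
  pulse (cosine crossfade over 20 ms, so the switch itself is not a
  discontinuity).  `κ = 0` gives uniform phases (chance-level PLV);
  `κ → ∞` (capped at 1e4) gives perfect locking.
* Optional: an instantaneous mixing matrix (volume-conduction scenario) and
  a large-amplitude pulse artifact confined to a closed ms interval.

Because the generator prescribes the cross-trial phase concentration
directly, the expected pre/post change of every phase-locking estimator is
known by construction, which is what makes end-to-end validation possible.

## 2. Preprocessing

Operations (each exposed separately; `preprocess_recording` composes them):

* **Excision + interpolation** — samples in the pulse window (default
  −1…10 ms, closed) are replaced by a natural cubic spline fitted to 20 ms
  flanks on each side.  The spline is fitted to local ~5-sample means of
  the flank data rather than interpolating every raw sample: an
  interpolant through noisy samples inherits noise-scale derivatives at
  the gap edges and overshoots across the gap, while the binned fit keeps
  the replacement at flank level and still reproduces smooth signals
  (constants exactly; an epoch-scale cubic to ~5e-8).
* **Bad-data handling** — robust z-scores (median/MAD) of per-channel and
  per-trial peak-to-peak amplitude; channels above threshold are replaced
  by the mean of the remaining channels, trials above threshold dropped.
* **Common-average re-reference**, **polyphase resampling**, zero-phase
  4th-order Butterworth band-pass 0.5–70 Hz (`sosfiltfilt`, preserving
  phase for the downstream estimators), **baseline correction** over
  −800…0 ms.

The chain order is excise → bad handling → re-reference → resample+filter →
baseline.  Placing the reference and baseline steps so that every later
step preserves them keeps both contracts exact at the output (channel means
and baseline-window means ≤ 1e-10), which the test suite asserts.

## 3. Wavelet transform and cone of influence

Complex Morlet with bandwidth `fb = 1` and center frequency `fc = 1`
(mother wavelet `exp(2πi fc t) exp(−t²/fb)`), analyzed on a logarithmic
scale grid (default 12 voices/octave from 70 down to 4 Hz).  At analysis
frequency `f` the Gaussian envelope has temporal standard deviation

```
σ_t(f) = sqrt(fb/2) · fc / f
```

Implementation: per analysis window, the windowed segment is treated as an
isolated finite recording; the transform is computed in the FFT domain with
a one-sided (analytic) Gaussian filter (factor 2, so a unit sinusoid gives
unit-magnitude coefficients at the matched scale), and the output is
produced directly on a decimated time grid by folding the filtered spectrum
modulo `Nfft/hop` before the inverse FFT — no full-resolution coefficient
array is ever materialized.  Coefficients are complex64 by default;
`WaveletParams(single_precision=False)` selects a complex128 path when
tolerances below ~1e-6 matter.  The implementation is verified in the tests
against a direct time-domain oracle (relative error < 1e-5 inside the COI)
and cross-checked against PyWavelets' `cmor1.0-1.0`.

**Cone of influence**: a coefficient at time `t` is valid iff its
Heisenberg box `[t − σ_t, t + σ_t]` lies inside the analysis window.  At
4 Hz the box is `2σ_t = √2/4 ≈ 354 ms` wide and does not fit the 300 ms
post-stimulus window — this is the arithmetic behind excluding the delta
band from short response windows, and the package raises an explicit
`BandInvalidError` in that case rather than silently averaging nothing.

## 4. Connectivity estimators

For a channel pair at one wavelet cell, with `u_n = exp(i Δφ_n)` the unit
phasor of the cross-trial phase difference and `P = (1/Nt) Σ_n u_n`:

```
PLV   = |P|                       ∈ [0, 1]
ciPLV = Im(P) / sqrt(1 − Re(P)²)  ∈ [−1, 1]
```

Chance level for PLV with `Nt` uniform trials is `sqrt(π/(4 Nt))`
(≈ 0.114 at 60 trials).  ciPLV discounts the zero-lag (real) component and
is the volume-conduction-robust reading.

A connectivity matrix entry is the unweighted mean of the per-cell field
over the COI-valid cells of a band × window region.  Bands: theta 4–8,
alpha 8–13, beta1 13–19, beta2 19–30, gamma 30–70 (closed top), global
4–70 Hz; membership is by scale center frequency, half-open `[low, high)`
except the topmost edge.  For ciPLV the *signed* field is averaged and the
magnitude of the average is stored, so zero-mean noise around a zero-lag
interaction cancels instead of accumulating as a positive bias.

## 5. Graph metrics

For a symmetric, nonnegative, zero-diagonal weight matrix `W` of `N` nodes:

* **CS** — mean off-diagonal weight.
* **ClC** — mean over nodes of `2 t_i / denom_i` with geometric-mean
  triangle intensity `t_i = ½ Σ_{j≠i} Σ_{h≠i,j} (w_ij w_ih w_jh)^{1/3}`.
  Two denominators are provided:
  * `strength` (default): `s_i (s_i − 1)` with `s_i = Σ_j w_ij`.  This
    variant **decreases** under any broad increase of edge weights — on a
    uniform complete graph it equals `(N−2)/((N−1)w − 1)` — and it
    degenerates when any `s_i ≤ 1` (guarded: error by default, NaN on
    request).
  * `degree`: `(N−1)(N−2)`, the dense-graph normalization, which is
    monotone increasing in the weights.
* **PL** — mean shortest-path distance over ordered node pairs with edge
  distance `1/w` (or `1 − w`), Dijkstra on the dense graph; zero-weight
  edges are "no edge" and disconnection raises unless a weight floor is
  given.

**Why the validation scenarios use the degree denominator.**  A
joint "strength up **and** clustering up" effect signature is only
well-posed under a normalization that is monotone in the weights; under
the strength denominator a uniform increase of coupling *lowers* ClC by
construction, so the cohort-level direction-recovery scenarios and the
acceptance report evaluate ClC with `clc_denominator="degree"`.  Both
conventions are exposed in `PipelineConfig` and tested against the same
triple-loop oracle.

## 6. Statistics

Within-subject paired t-tests on (pre − post) per parameter × band: 18
tests for the active design (6 bands), 15 for sham (alpha excluded), each
Bonferroni-corrected at α = 0.05.  An increase after the pulse appears as a
negative t.  The default p value is one-tailed, `P(T ≥ |t|)`: the printed
(t, p) pairs in this literature are mutually consistent only under that
convention (|t| = 2.76 at df = 28 → 0.0050 one-tailed vs 0.0101
two-tailed).  Cohen's d defaults to the pooled-SD convention
`|Δmean| / sqrt((sd_pre² + sd_post²)/2)`; the paired (difference-SD)
convention is selectable.  Under this procedure each null test fires with
probability `2α/n` (strong effects of either sign pass the |t| threshold),
giving a nominal familywise rate of `1 − (1 − 2α/n)^n ≈ 0.095` for n = 15.

**Matched-window null comparison.**  The standard analysis windows are
1000 ms pre vs 300 ms post.  Those windows are *not* exchangeable under the
null: the shorter window averages fewer COI cells, so its matrix entries
have higher variance, and the nonlinear graph reductions (1/w distances,
geometric-mean triangles) turn that variance difference into a systematic
mean shift that a paired test detects reliably (PL biased up, ClC down in
the short window).  Null false-positive calibration therefore compares two
non-overlapping 300 ms windows (−315…−15 vs 15…315 ms).  This is a general
caveat for pre/post designs with unequal window lengths: window-length
asymmetry alone can produce "significant" graph-metric changes.

## 7. Known limitations

* ICA-based artifact rejection (an expert-manual procedure) is out of
  scope; bad-data handling is a simple robust-amplitude rule.
* Bad-channel repair is the mean of the remaining channels, not a
  spherical-spline interpolation.
* The strength-normalized ClC is degenerate on small or weakly coupled
  graphs (node strength ≤ 1); the pipeline maps those to NaN and drops the
  parameter from the statistics with a warning.
* Graph metrics are computed on dense weighted matrices without
  thresholding; sparsification conventions from other toolchains will give
  different absolute values.
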