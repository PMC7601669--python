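# Methods

## Pore geometry and conductance

A conical pore is described by its tip diameter `d_t`, base diameter
`d_b` and length `L` (the membrane thickness, 13 µm for the reference
pores). Assuming bulk-like electrolyte conductivity κ inside the pore,
the open-pore conductance is `G = κ π d_t d_b / (4 L)`. The relation is
linear in each diameter and is inverted exactly for `d_t`, which is how
few-nanometre tips are sized in practice. The base diameter follows from
the total etch time through a lab-calibrated factor (default
2.5 nm per unit time, exposed as a parameter since it depends on etchant
and film). The half-angle is defined as `atan((d_b − d_t)/(2L))`; this
definition reproduces both reference values (0.4° and 0.8° after
rounding to one decimal). All geometry is SI internally; the CLI accepts
lengths only with explicit unit suffixes (`3nm`, `13um`) to make nm/µm
mix-ups impossible.

## Trace model (synthetic benchmark)

Experimental recordings for this system are not publicly deposited, so
the generator produces traces whose *statistical structure* matches the
published account of three DNA samples (A10/T10, A40/T40, T40) measured
with a ~3 nm-tip pore at 500 mV:

- baseline current `I₀ = G·V` (≈0.18 nA for κ = 10 S/m at 500 mV),
  plus a slow sinusoidal drift (4 pA, 5 s period) and a small random
  walk (2 fA/sample);
- white Gaussian noise, σ = 1.5 pA raw (≈0.3 pA after the 2.5 kHz
  filter), i.e. a typical event depth of ≈15 pA is ten times the raw
  noise sd;
- events are trapezoidal current decreases: linear fall over the entry
  edge, flat blocked level, linear recovery over the exit edge. The
  trapezoid is a deliberate idealization — downstream analysis uses five
  scalar features only, and the trapezoid gives closed-form expected
  values for all of them, making parameter recovery exactly testable.

Per class, event parameters are drawn as:

| parameter | distribution | defaults (A10/T10, A40/T40, T40) |
|---|---|---|
| relative depth ΔI/I₀ | truncated normal, sd 0.025, bounds [0.02, 0.30] | means 0.085, 0.093, 0.066 |
| dwell Δt | log-normal, geometric sd 1.7, left-truncated at 0.55 ms | medians 1.07, 0.95, 1.29 ms |
| edge times t_rise, t_fall | per-edge log-normal jitter (gsd 1.25) around `(T/2)·e^{∓A/2}`, T = 0.55 ms | asymmetry A = ln(t_fall/t_rise) ~ N(m, 0.5), m = −1.2, 0, +1.2 |

Design rationale for the non-obvious choices:

- **Depth and dwell spreads.** The class centers differ by much less
  than the spreads, so the ΔI/I₀ and Δt marginals overlap heavily
  (pairwise histogram intersection > 0.5) — the defining difficulty of
  the real experiment. The dwell spread also produces the strong
  dwell–area correlation (≥ 0.8) seen in measured heat maps.
- **Dwell floor at 0.55 ms.** Recorded event populations have a
  detectability floor set by the analysis bandwidth: a 2.5 kHz low-pass
  has a ≈0.14 ms rise time, and pulses not much longer than that are
  neither resolved nor timed. Published dwell histograms accordingly
  start at a few hundred µs. Without the floor, a heavy sub-0.5 ms tail
  would be reported with >10% timing error purely because of the filter.
- **Absolute edge times, independently jittered.** If edges were drawn
  as fractions of the dwell, both flank slopes would inherit the large
  dwell spread and correlate at |r| ≈ 0.9; measured heat maps show
  ≈ −0.2. Absolute, per-edge-jittered times leave the slopes sharing
  only the depth, giving |corr(LS, RS)| ≈ 0.2–0.3. For short events the
  drawn edges are rescaled to at most 0.7 of the dwell, preserving the
  asymmetry ratio that carries the class signal.
- **Class signal in the asymmetry.** The separability between classes is
  injected predominantly into the flank asymmetry, so that the headline
  "five features beat two features" outcome holds *by construction*.
  This is a modeling choice that mirrors the published interpretation
  (conical pores produce class-informative pulse asymmetry); it is not a
  claim about the real samples.

Events are placed sequentially with at least one full baseline-smoother
window (48 ms) between them, so neighbouring events cannot interact
through the baseline estimate; remaining slack is distributed randomly
(Dirichlet) over the gaps. Everything is driven by one seeded generator:
fixed seed ⇒ bit-identical output.

What the generator does **not** emulate: 1/f and interference noise,
multi-level (sub-state) blockades, event-rate/voltage dependence,
electrolyte-specific conductivity, and any physical translocation
dynamics. Passing tests therefore demonstrate the correctness and
statistical behaviour of the *analysis chain* under realistic signal
scales — not instrument-level fidelity.

## Conditioning

Filtering is a 2.5 kHz, order-2 Butterworth applied forward and backward
(`sosfiltfilt`). Zero-phase filtering preserves edge timing, which the
slope features need; the attenuation doubles in dB, so a tone at the
cutoff emerges at half amplitude. The baseline is a Savitzky–Golay
smoother with 2400 side points (4801-point window, 48 ms at 100 kHz) and
polynomial order 1 — "side points" is read as the half-window. Order-1
smoothing reproduces linear drift exactly and a millisecond event only
nudges the 48 ms window average by ~1% of the event depth. Near the
trace edges the window is truncated symmetrically with a per-position
least-squares fit (for order ≤ 1, the truncated-window mean), which
keeps polynomial exactness at the edges; the first/last 2400 samples are
still flagged and events overlapping them discarded. The deviation
series is `baseline − current`, so blockades are positive and all
thresholds and slopes are defined on it.

## Detection and features

The noise scale σ is 1.4826 × MAD of the deviation by default: the
blockades occupy a few percent of samples and would inflate a plain sd
(which remains available as `global_sd` for comparison). An event is any
maximal region crossing `3σ`, with boundaries extended outward to the
`k_boundary·σ` re-crossings, and a minimum time above the detection
threshold (band-limited Gaussian noise crosses 3σ at ~16 events/s with
~0.1 ms excursions; a floor of 0.3 ms ≈ twice the filter rise time
removes essentially all of them while losing almost no real events).

Features per event: Δt between the boundary crossings; ΔI/I₀ as peak
deviation over the local baseline at the peak (the local value matters
because drift is present); AUC as the trapezoidal integral of the
deviation; LS and RS as least-squares line fits on the two flanks. The
flank is delimited by the first (respectively last) sample reaching 90%
of the peak deviation: on a noisy blocked plateau every sample is
statistically tied with the maximum, so fitting "to the argmax" would
inject large artifact variance into both slopes. On noise-free
triangular or trapezoidal pulses the flank fits equal the exact edge
slopes (±2a/d for a symmetric triangle of depth a and duration d).

Two detection profiles are used. The library defaults follow the
classical parameterization (boundaries at 1σ, 5-sample minimum dwell).
The benchmark profile (`BENCHMARK_DETECTION`) uses a 2.8σ boundary and
the 0.3 ms floor: at 1σ the smeared tails of the filtered pulse pull the
boundaries outward and bias the measured dwell by ≈ +0.08 ms, while at
2.8σ that outward pull cancels the inward offset of the crossing point
on the flank, making the dwell estimate nearly unbiased under the
2.5 kHz filter. Both multipliers are configuration parameters.

## Statistics and classification

Histogram densities use `d_i = f_i/(n·w_i)` with left-closed bins
anchored at zero (default widths 0.01 for ΔI/I₀, 200 µs for Δt), so
histograms are comparable across event counts and integrate to one.
Correlations are Pearson throughout (the diagnostics are explicitly
linear); zero-variance columns yield missing entries, never zero. The
regression of ΔI/I₀ on Δt is OLS and its R² equals the squared Pearson
correlation.

Classification is a stratified 5-fold cross-validated SVM. Within each
outer training fold, C ∈ {0.1, 1, 10, 100} and the RBF width
(γ ∈ {scale, 0.03, 0.3}) are chosen by an inner 3-fold grid search, with
standardization fitted on training folds only (Pipeline). The RBF kernel
is the default because the event clouds are not linearly separable;
multi-class handling is scikit-learn's one-vs-one voting. The two- and
five-feature runs share the same folds (same seed), so their accuracy
difference is paired; per-class recall is reported alongside accuracy so
imbalanced tables remain interpretable. A label-permutation run
estimates the chance level the accuracies must be judged against.

## Problem sizes and determinism

The test suite analyses a benchmark of 150 events per class (three ~10 s
traces at 100 kHz); the acceptance script uses 200 per class and derives
every random stream from its `--seed`. At these sizes detection recall
is 100%, depth and dwell are recovered within 10% for ≈99% and ≈95% of
events, and the five-feature accuracy exceeds the two-feature accuracy
by ≈30 points — stable across seeds. All stochastic stages take explicit
seeds and are bit-reproducible.

## Known limitations

- The trapezoid + Gaussian noise model understates real-world artifacts
  (baseline jumps, clogs, multi-level events); recall and recovery rates
  here are upper bounds on experimental performance.
- Dwells below ~0.5 ms are not reliably measurable through a 2.5 kHz
  filter; the generator's detectability floor encodes this rather than
  hiding it.
- AUC and the slopes are reported in absolute amperes; a variant
  normalized by the local baseline would be needed to compare pores with
  very different conductances.
- The SVM protocol (CV scheme, kernel, grids) is a documented choice;
  published accuracies for the experimental recordings were obtained
  with an unspecified protocol and are not directly comparable.
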