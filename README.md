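# porepulse

Resistive-pulse analysis of conical track-etched nanopore recordings:
trace conditioning, 3σ blockade detection, five-feature event
characterization, and SVM discrimination of DNA samples.

## The problem

A single conical nanopore in a polymer membrane, held at fixed voltage,
passes a steady open-pore current *I₀*. Each translocating molecule
transiently blocks part of the pore and produces a current-blockade
*event*. Track-etched pores have low intrinsic resolution: for short DNA
strands the two classical event descriptors — the relative blockade
ΔI/I₀ and the dwell time Δt — have class distributions that overlap
almost completely, so the samples cannot be told apart by eye or by
clustering. The conical geometry, however, makes the entry and exit
flanks of an event asymmetric, and that shape information is recoverable
by machine learning.

`porepulse` implements the full chain for this analysis, and a synthetic
trace generator with ground truth so every stage is testable without
experimental recordings (none are publicly deposited for this system):

1. **geometry** — conductance of a conical pore,
   `G = κ·π·d_t·d_b / (4L)`, its inversion for the tip diameter, the
   etch-time→base-diameter calibration and the cone half-angle.
2. **simulate** — labeled traces: baseline (from G × voltage) + drift +
   Gaussian noise, with trapezoidal blockades drawn from per-class
   distributions of depth, dwell and flank asymmetry.
3. **preprocess** — zero-phase Butterworth low-pass (2.5 kHz, order 2)
   and Savitzky–Golay baseline estimation (2400 side points, order 1);
   deviation = baseline − current.
4. **events** — detection at 3σ of the robust noise scale with
   boundaries at a lower re-crossing threshold; five features per event:
   ΔI/I₀, Δt, area (AUC), left and right flank slopes (LS, RS).
5. **stats** — density histograms `d_i = f_i/(n·w_i)`, the 5×5 Pearson
   matrix, OLS of ΔI/I₀ on Δt.
6. **classify** — stratified 5-fold cross-validated SVM (RBF, nested
   grid search, fold-wise standardization), evaluated on the classical
   two features and on all five over identical folds.

## Worked example

```python
import porepulse as pp
from porepulse.pipeline import analyze_dataset

dataset = pp.make_benchmark_dataset(n_per_class=100, seed=42)
table = analyze_dataset(dataset)              # detect + extract features
reports = pp.compare_feature_sets(table, pp.SvmConfig(seed=42))
```

Running `python examples/05_svm_discrimination.py` (which does exactly
this) prints:

```
feature table: 300 events, 3 classes

--- two features: accuracy 44.3% ---
--- five features: accuracy 79.0% ---

five-feature gain : +34.7% (paired, same folds)
permutation null  : 31.0% (chance = 33.3%)
```

With only ΔI/I₀ and Δt the classifier barely beats chance because the
class marginals overlap; adding AUC, LS and RS exposes the flank
asymmetry and lifts the accuracy by tens of points, while permuting the
labels collapses it to chance — the gain is genuine class signal, not
overfitting. The other scripts in `examples/` walk through geometry
(`0.434°`/`0.762°` half-angles for the 3 nm- and 4 nm-tip pores),
simulation, detection (robust σ ≈ 0.38 pA, threshold ≈ 1.15 pA on a
0.18 nA baseline) and the feature diagnostics
(corr(Δt, AUC) ≈ 0.82, corr(LS, RS) ≈ −0.2, R² ≈ 0.02).

A thin CLI mirrors the stages:

```sh
porepulse geometry --d-t 3nm --d-b 200nm --l 13um
porepulse run --seed 1 --out out/        # simulate → detect → stats → classify
```

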