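# Methods

## Problem setting

A tri-axial accelerometer attached to a sheep's ear, collar, or foreleg
samples static (gravity) plus dynamic acceleration at 12 Hz. Behaviour
observations annotate the record with intervals of grazing, standing,
walking, and lying, each observed in a sound (unimpaired) and a lame phase.
The pipeline classifies 10 s epochs into these behaviour classes, with lame
walking as its own class; detecting lame walking epochs is the point of the
exercise.

## Epoch model

Epochs are consecutive, non-overlapping windows of `epoch_s × rate_hz`
samples (default 120), phase-locked to the record start. A window is kept
only if **every** sample falls inside annotation intervals of one single
non-reserved behaviour; windows touching `unknown`/`transition` intervals or
straddling a behaviour change are excluded entirely rather than
majority-voted, and trailing partial windows are dropped. Record-start
alignment (rather than annotation-boundary alignment) was an open design
point; it is the simpler convention and makes the conservation property
(kept·T + dropped = total samples) exact. Windows are half-open
`[start, start + epoch_s)` in seconds.

## Features

All 14 metrics are computed on raw, gravity-inclusive samples in g — no
filtering or gravity separation is applied anywhere in the pipeline. The
entropy and energy sums are per-sample over the three axes
(`Ts_i = x_i + y_i + z_i`, `TSS_i = x_i² + y_i² + z_i²`), normalised by the
epoch sample count T, as are MV (with T−1 difference terms per axis) and
SMA/AI. Since axis values can be negative, `1 + Ts_i ≤ 0` is possible; the
entropy term is then evaluated as `(1+Ts)·ln|1+Ts|` (0 at `Ts = −1`) with a
runtime warning, switchable to rejecting the epoch. For realistic postures
(gravity magnitude ~1 g distributed over axes) the guard never triggers.

## Feature ranking

A from-scratch CART ensemble: 500 trees on bootstrap resamples, Gini
impurity splits over 4 randomly drawn candidate features per node, minimum
node size 1, unlimited depth, no pruning. A feature's importance is the
node-size-weighted Gini decrease `(n·G − n_L·G_L − n_R·G_R)/n_root` summed
over its splits and averaged over trees (mean decrease in Gini). Writing
the ensemble ourselves gives exact seeding (one integer seeds bootstrap
and per-node feature subsampling) and an internal conservation check: the
importance vector's sum equals the mean per-tree total decrease. The
numerically heavy tree-growth loop is compiled with numba. Ranking ties are
broken by the fixed feature-table column order. The ranking is done once on
the full dataset before cross-validation (selection precedes the
classifier); this mirrors the procedure being reimplemented and is mildly
optimistic relative to per-fold selection. Iterative variable elimination
is deliberately not implemented — the procedure is rank-then-take-top-k
(default k = 3).

## Classifier

QDA with per-class sample means, covariances (denominator n_k − 1), and
empirical priors (uniform priors available). Covariances receive a diagonal
shrinkage of `shrinkage · trace(S)/d` (default shrinkage 1e-6; unit scale
when a class is exactly constant) because synthetic static behaviours can be
near-singular. Discriminants are evaluated in the log domain via Cholesky
factorisation (no explicit inverses); posteriors are the softmax of the
discriminants; ties break by class order. Features are not standardised:
QDA is equivariant under common affine maps, so the ranking-selected raw
features are used directly.

## Validation

Leave-one-epoch-out: each epoch is predicted by a model refitted on all
remaining epochs. The confusion matrix is oriented rows = predicted,
columns = observed. Per class, one-vs-rest: sensitivity TP/(TP+FN),
specificity TN/(TN+FP), accuracy (TP+TN)/total, precision TP/(TP+FP); a
zero denominator yields a missing value, never 0. Specificity uses the
standard TN/(TN+FP) definition (the report metadata notes this choice).
The per-observed-class "prediction accuracy" (diagonal over column total)
is algebraically identical to sensitivity and is asserted as such.
Percentages are rounded half-up to whole numbers for comparison against
printed tables. Leave-one-animal-out grouping would be the honest
generalisation test but is not the validated procedure here; the epoch-wise
variant is what the reference results use.

## Synthetic data generator

Each behaviour is gravity orientation + two-harmonic sinusoid + white
Gaussian noise (g units, gravity magnitude 1):

| behaviour | gravity | f (Hz) | amp x/y/z (g) | asym | noise sd |
|---|---|---|---|---|---|
| sound standing / lame standing | upright | 0 | 0 | 0 | 0.03 |
| sound lying / lame lying | recumbent | 0 | 0 | 0 | 0.03 |
| sound grazing | head-down | 0.8 | 0.10 / 0.07 / 0.08 | 0 | 0.03 |
| lame grazing | head-down | 0.8 | 0.6 × grazing | 0 | 0.03 |
| sound walking | upright | 1.5 | 0.30 / 0.18 / 0.24 | 0 | 0.03 |
| lame walking | upright | 1.5 | 1.8 × walking | 0.4 | 0.03 |

Axis phase offsets are fixed at 0, 2π/3, 4π/3. Lameness on walking is an
amplitude multiplier (×1.8) plus a second-harmonic distortion (0.4),
emulating the larger, asymmetric swing of uneven weight-bearing; lame
grazing keeps the grazing posture with a reduced (×0.6) step component so
it overlaps sound grazing — the known failure mode of Analysis I.
Amplitude and frequency values are this package's own choices: they
preserve the ordinal relations that matter (lame walking amplitude strictly
above sound walking; lame grazing near sound grazing), not any absolute
published values, none being available. Per-animal variation multiplies
each animal's oscillation amplitudes by log-normal factors (σ = 0.15),
shared across deployments, so cross-validation is not memorising one
waveform.

A generated study concatenates, per animal, one contiguous block per
behaviour (block length = epoch count × 10 s), separated by 10 s
`transition` gaps that segmentation must exclude; the default study shapes
reproduce the epoch totals of the three reference deployments (e.g. 342
sound-grazing epochs in the ear study). Totals are split near-evenly
across the default 5 animals. All randomness flows from one study seed via
a seed tree; identical configurations give byte-identical CSV output.

### What the generator does not emulate

Real signal features absent here: aperiodic stride-to-stride variability,
posture drift within a behaviour bout, rumination, head-flick pain
behaviour, sensor mounting slippage, and deployment-specific signal
colouring (a collar damping the head-bob, a leg sensor bearing the
forequarter weight). Consequently the synthetic classes are more separable
than field data — default-parameter runs reach diagonal confusion matrices
— so passing pipeline tests demonstrates correctness of the machinery and
qualitative failure modes (grazing overlap), not field-level accuracy.

## Problem sizes and numerical choices

Pipeline-level tests use 100 epochs per class over 5 animals (500 epochs,
500-tree ranking, leave-one-out over all epochs), which exercises every
stage at a scale where the statistical properties (lame-walking sensitivity,
grazing-confusion dominance) are stable across seeds. Feature agreement
with the naive per-sample oracle is asserted at 1e-10 over 1000 random
epochs; QDA posteriors against brute-force Gaussian densities at 1e-10 and
posterior normalisation at 1e-12; forest planted-feature recovery at ≥95 of
100 seeded runs. Reference confusion matrices are compared after half-up
integer rounding of percentages (a 1e-9 epsilon protects exact halves from
binary-representation ties).

## Known limitations

- Epoch-wise leave-one-out overstates generalisation to unseen animals;
  grouped CV is available in principle by splitting on `animal_id` but is
  not the validated procedure.
- Full-dataset feature ranking is mildly optimistic (see above).
- The forest follows classic CART defaults (unlimited depth, min node 1);
  importance values are ranking-grade, not calibrated effect sizes, and
  correlated features share importance.
- The published collar worked example's specificity/accuracy operands are
  not derivable from the printed collar matrix under the standard TN
  definition; only sensitivity and precision are asserted against it.
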