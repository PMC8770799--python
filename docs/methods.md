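# Methods

## Problem

Grassland parcels under agri-environmental subsidy schemes must be mown
during the vegetation season, and paying agencies verify this remotely.
Two satellite signals carry the evidence. Sentinel-2 optical imagery
gives NDVI, which drops sharply when the grass is cut; in northern
Europe about three quarters of NDVI acquisitions are lost to clouds, so
the optical record alone is too sparse. Sentinel-1 interferometric
coherence (VV and VH polarization, 6-day repeat) rises after a cut —
the scattering surface stops changing — and stays elevated for roughly
24–36 days, independent of weather. `mowsense` fuses both into a daily
mowing probability per field and turns that into discrete, tolerance-
checked events plus a season-level mown/not-mown call with an optional
abstention band.

## Preprocessing

**NDVI outlier rule.** Cloud-mask failures produce isolated NDVI
samples crashing toward zero. For every three consecutive valid NDVI
measurements `(n1, n2, n3)` whose first and third samples are at most
10 days apart, the middle one is removed when `n3 − 2·n2 + n1 ≥ 0.6`.
All triplets are evaluated on the original values and removals applied
in one pass, so the result does not depend on scan order; a genuine
mowing drop recovers slower than 10 days and passes the guard. At the
usual 4–5-day optical cadence the rule is idempotent: a removal widens
the surviving triplets past the 10-day guard.

**Coherence smoothing.** Both coherence channels are smoothed on the
valid measurements, before interpolation, with an exponential moving
average `out_n = α·in_n + (1−α)·out_{n−1}`, `out_1 = in_1`, α = 1/3 by
default. A centred moving average (default width 7, window truncated
symmetrically at the edges) is available as an alternative. Smoothing
before interpolation keeps interpolated segments straight lines between
smoothed anchors rather than smearing the interpolation artefacts.

**Daily grid.** Every channel is linearly interpolated onto the fixed
215-day season axis (April 1 through October); outside the observed
range the nearest value is held. Validity masks record which days carry
real measurements. A channel with zero valid samples in a season is
filled with a neutral constant (NDVI 0.5, coherence 0.3).

## Features

14 per field-day, in fixed order: the three raw channels
(`ndvi`, `cohvv`, `cohvh`); normalized day of year `t = doy/365`;
normalized gap `dt` (days since the previous real measurement, min-max
scaled with bounds fitted on training fields only and clipped on unseen
extremes — this is what lets the network distinguish real from
interpolated days); the smoothed coherences; the mixed coherence
`sqrt(cohvh·cohvv)` (the geometric mean per its defining formula; the
accompanying prose in the source work calls it a harmonic mean — the
formula wins); and six change features — difference and slope between
consecutive *valid* measurements of `ndvi`, `cohvv_sm`, `cohvh_sm`,
carried unchanged across interpolated days.

Daily labels are 1 on the 7 days starting at each mowing start,
matching the −3/+6-day evaluation tolerance, else 0.

## Detector

A three-layer 1-D convolutional network maps the 14×215 field-season
to 215 daily probabilities:

    conv1d(14→32, k=9) → channel softmax → batch norm
    conv1d(32→32, k=9) → channel softmax → batch norm
    conv1d(32→1,  k=9) → sigmoid

All convolutions use same-length padding; the receptive field spans
±12 days, wide enough to see the coherence plateau build while keeping
the probability bump localized. "Softmax activation" after a conv layer
is interpreted as softmax across the channel axis at each timestep —
the only axis where it is well defined per day; activation precedes
normalization. Channel counts and kernel size are not dictated by the
architecture's source and are config-exposed.

Training minimizes mean per-day binary cross-entropy over all 215 days
(interpolated days included) with the Nadam optimizer (keras-legacy
momentum schedule: β₁ = 0.9, β₂ = 0.999, schedule_decay = 0.004,
ε = 1e-7), batches of 64 fields, up to 300 epochs with early stopping
(patience 20) on validation loss and best-epoch weights restored. The
default learning rate is 1e-4, the value favoured by the rate sweep;
1e-3 is the common alternative and reachable via config. The engine is
a self-contained numpy implementation (forward and backward passes,
batch normalization with running inference statistics), single-threaded
and deterministic under a fixed seed. Adam and SGD are provided for the
optimizer sweep harness.

## Evaluation

**Decoding.** Each maximal run of consecutive days with probability
above 0.5 is one predicted event starting on the run's first day. The
decoding rule is a package convention; nothing in the underlying method
prescribes one.

**Event matching.** Actual starts are processed in order; each claims
the earliest unmatched prediction within [a−3, a+6]. Leftover
predictions are FP, unmatched actuals FN, and a season with neither
actual nor predicted events contributes one TN (the TN unit is a
package convention that makes the accuracy ratio well defined). Event
accuracy is (TP+TN)/(TP+TN+FP+FN). For disjoint windows — real labels
are ≥ 10 days apart — the greedy matching equals the maximum-cardinality
assignment, and the tests verify this equivalence by exhaustive
enumeration including overlapping-window configurations.

**Season level.** The season score is noisy-or, `1 − Π(1 − p_d)`
(a `max` alternative exists); a field is called mown when the score
exceeds 0.5. EOS accuracy is the fraction of correct season calls; AUC
is the tie-aware Mann–Whitney rank statistic. Noisy-or saturates when
daily probabilities are well above zero on many days; ranking (AUC) is
unaffected, which is why the reject thresholds on a sharp model sit
close to 1.

**Reject region.** On validation season scores, `t_upper` is the score
of the ⌈TPR·n_pos⌉-th positive in descending order and `t_low` the
score of the ⌈TNR·n_neg⌉-th negative in ascending order. Scores
strictly inside (t_low, t_upper) abstain; ties at a threshold are
decided. Demanding higher rates pulls both thresholds toward the middle
and *shrinks* the abstention interval — the fraction rejected is
monotone non-increasing in the requested rates; if the thresholds cross
the interval is empty and nothing is rejected.

## Synthetic data

No field-labelled mowing dataset is publicly deposited, so the
generator reproduces the signal phenomenology the detector relies on.
Defaults are the study conditions: 95% of fields mown (exactly, at the
dataset level), 1–3 events per mown field with summer-weighted start
days and separation of at least the regrowth upper bound, NDVI drop per
event uniform in [0.20, 0.45] with linear regrowth over 25–40 days,
coherence rise uniform in [0.10, 0.30] decaying over 24–36 days, 6-day
SAR cadence, 4-day optical cadence with 75% of NDVI samples invalid,
single-sample cloud-mask outliers at rate 0.001 (never consecutive, by
construction), and rain days (rate 0.08) multiplying coherence by
0.4–0.8. The unmown NDVI baseline is an ellipse arc ("half-oval"):
`n_min + (n_max − n_min)·sqrt(1 − ((t − t_mid)/h)²)` with per-field
`n_min ∈ [0.1, 0.3]`, `n_max ∈ [0.6, 0.9]`, `t_mid ∈ [90, 130]`,
`h ∈ [80, 120]` days. Observation noise is Gaussian (σ 0.02 NDVI, 0.03
coherence); values the study conditions do not pin down (noise levels,
rain rate, baseline coherence `cohvv ∈ [0.15, 0.40]` with
`cohvh = cohvv·U[0.6, 0.9]`, the half-oval timing) were fixed once at
values typical of published field-average series.

The generator does **not** emulate multi-orbit coherence overlap,
spatial correlation between neighbouring fields, drought-induced NDVI
drops that mimic mowing, or systematic cloud seasons. Passing the
synthetic-recovery tests therefore shows the pipeline recovers events
whose signature matches the documented phenomenology at realistic
sparsity and noise; it does not certify performance on real Sentinel
archives, where confusers and correlated gaps are harsher.

## Problem sizes and numerical choices

The shipped end-to-end study uses 1000 synthetic fields split 64/16/20
(train/validation/test); the reproduction script
(`scripts/acceptance.py`) and the end-to-end tests both run at this
size, which gives stable metrics while keeping a full run in minutes
on one CPU. Early-stopping improvements smaller than 1e-7 in BCE count
as no improvement; batch-norm uses ε = 1e-5 and running-stat momentum
0.9; weights are Glorot-uniform from a seeded generator; probabilities
are computed from logits with a ±60 clip before the sigmoid. Dataset
generation spawns one independent RNG stream per field from the root
seed, so any field can be regenerated in isolation and results are
bitwise reproducible.

## Known limitations

* The detector's capacity and defaults target field-averaged series;
  no pixel-level or boundary-mixed signals.
* The Kalman-filter smoothing variant considered alongside EMA and
  moving average is not implemented; EMA is the selected method.
* Event decoding with a fixed 0.5 threshold is blunt when probabilities
  are poorly calibrated; the reject region operates at season level
  only, not per event.
* With very sparse validation sets the fitted reject thresholds are
  step functions of the requested rates; between steps different rates
  yield identical intervals.
* At small training sizes (roughly two batches per epoch at the default
  learning rate) the batch-norm initialization transient can keep the
  validation loss from improving within the early-stopping patience,
  halting training near epoch 0. At the shipped study size the defaults
  train reliably; for very small datasets raise the patience or the
  learning rate.
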