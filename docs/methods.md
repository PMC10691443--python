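# Methods

This note documents the models, conventions and numerical choices behind
`spherosynergy`, in the order the pipeline runs them.

## Study layout

The package targets two-drug checkerboard screens on single-spheroid
cultures: each plate is one (cell line, drug pair, technical replicate)
and carries a 6×6 dose matrix — five 3-fold dilutions per drug plus a zero
dose, with the untreated well at matrix position (0, 0).  Row index is the
drug-1 dose and column index the drug-2 dose, both ascending from zero, so
doses increase toward the bottom-right of the matrix.  At full scale
(3 cell lines × 16 pairs × 2 replicates × 36 wells) one imaging day yields
3 456 well images.  Imaging days are 0-based from seeding; the default
schedule is days 1, 4, 8, 11, 15, 18 with drug exposure on days 4–8 and
11–15 and the lysing endpoint viability assay on day 18 only.  (The source
protocol lists the first imaging day inconsistently as day 0 or day 1; the
package stores the day-1 convention and exposes the alternative as a
documented constant rather than silently resolving the discrepancy.)

Concentrations are stored unrounded; the 4-decimal rounding seen in
concentration tables is presentation-only (`DoseSeries.rounded_values`).

## Synthetic data generator

The screen's true pharmacology was never published, so the generator's
constants are explicit stand-ins chosen to produce a well-spread 0–100 %
endpoint viability range.  What it emulates, and how:

**Growth.** Each well starts from 750 seeded cells and grows logistically,
`dN/dt = g·N·(1 − N/K)`, with defaults `g = 0.35/day` and `K = 1e8`
(effectively exponential over 18 days, ending near 4×10⁵ cells untreated).

**Drug effect.** Each drug contributes a Hill effect
`e_i = d^h / (d^h + EC50^h)`; the pair combines as
`e = e1 + e2 − e1·e2 + α·e1·e2`, clipped to [0, 1].  `α`
(`synergy_alpha`) is the ground-truth interaction: 0 is exactly
Bliss-independent, positive is synergy, negative antagonism.  Default
pharmacology is heterogeneous across (cell line, pair): each drug's EC50
lands log-uniformly between the second- and fourth-highest dose of its
dilution series and its Hill slope uniformly in [1.0, 2.5], drawn once
from a fixed module constant so the simulated screen is always the same.
Distinct per-pair shapes matter: they give between-pair score dispersion
the standard error of a mean synergy estimate is supposed to measure
(pharmacological clone pairs would make it collapse).

**Kill kinetics.** During exposure windows the kill enters as a hazard
`k·(−ln(1 − e))` subtracted from the growth rate, and the integrator uses
multiplicative (exponential-Euler) steps of 0.1 day, which are exact for
piecewise-constant rates.  Two consequences drove this design:

1. With `α = 0` and exponential growth, `1 − e12 = (1−e1)(1−e2)` makes the
   true viability matrix satisfy the Bliss product identity
   `V12 = V1·V2/100` to machine precision — the additive-truth oracle used
   throughout the tests.  A hazard linear in `e` itself (the more obvious
   choice; `−ln(1−e) ≈ e` to first order) would *not* compose this way.
2. The default `k = 0.125/day = 1/(8 days of total exposure)` makes a full
   two-window course at effect `e` leave survival exactly `1 − e`, so the
   true endpoint monotherapy curves are themselves four-parameter
   log-logistic — inside the family the synergy stage fits, which keeps
   the reference surfaces free of lack-of-fit bias at additive truth.

A single `max_kill_rate` is shared by both drugs of a pair; per-drug rates
would break consequence 1.

**Viability truth vs. assay labels.** Per well and day the generator
records both the noise-free viability ratio (`true_viability_pct`,
100·N/N_untreated — the quantity the rendered image encodes) and a noisy
assay readout (`measured_viability_pct`, truth plus Gaussian noise of sd
5 %, truncated at 0), emulating a luminescent endpoint assay.  The labels
CSV contains the measured values for the endpoint day only; the untreated
well is the normalization reference and is pinned to exactly 100.

**Rendering.** One grayscale image per well per day: a soft-edged dark
disk of radius `0.30·N^(1/3)` px (volume ∝ cell count; the scale puts the
day-18 untreated spheroid at roughly a third of a 128 px frame), a bright
halo ring, a linear background illumination gradient in a random
direction, Gaussian speckle, and Poisson-count debris blobs.  All
randomness flows through explicit seeds; identical seeds give bitwise
identical images.  A configurable number of empty-well renders (labelled
0 % viability) joins the training pool as references.

**What the renders do not capture:** phase-contrast optics, internal
spheroid texture (necrotic cores, blebbing), out-of-focus planes, well
walls, or multi-spheroid wells.  Viability is encoded purely through
spheroid size, so a passing decoder demonstrates that the pipeline
recovers a size-coded signal through preprocessing, training, and
normalization — not that the architecture suffices for real
phase-contrast texture.

## Preprocessing

A deterministic chain: percentile contrast stretch (1st/99th mapped to
0/1; concretizes "contrast maximization" without a tuned constant) →
median filter (3 px) + Gaussian blur (σ = 1 px) → margin trimming →
small-artifact removal (foreground components below 50 px², via Otsu's
threshold, replaced by a local median background; the largest component is
never removed) → resize to 224×224 by default (area-averaging down,
bilinear up).

Trimming locates the spheroid as the largest foreground component and
crops its bounding box expanded by 25 %, squared and clamped to the frame,
falling back to a centered crop for empty wells.  `min_crop_frac` floors
the window size as a fraction of the frame: the synthetic pipeline runs
with a floor of 1.0 (fixed full-frame window) because the renders carry no
large margins and the spheroid's *absolute* scale is the viability signal
that adaptive per-spheroid zooming would discard; fully adaptive cropping
(floor 0, the default) is intended for real microscope frames with large
empty margins.  Segmentation polarity (dark-on-light) is a config flag.

## Viability decoder

A compact dense-connectivity convolutional regressor, implemented in
numpy (no deep-learning framework dependency): 5×5 stride-2 stem
convolution → 2× average pool → dense blocks whose 3×3 convolutions each
receive the concatenation of all earlier maps in the block (2 + 2 layers,
growth 8), separated by a 1×1 compression transition with 2× pooling →
global average pooling → 16-unit hidden layer → single linear output, no
output activation.  He initialization, Adam (lr 3e-3), MSE loss on
labels scaled by 1/100, inputs standardized by the training-set mean/sd.
Training runs up to 150 epochs (batch 32) with best-validation-MSE
checkpointing and patience 40; the long schedule matters — shorter runs
systematically under-predict the top of the viability range, and the
per-day normalization then inflates every other well on the plate.
Everything is seeded and CPU-deterministic; two runs with equal seeds give
identical loss histories.

Splits are by drug pair, never by image: a pair's images are all in the
train+validation pool or all in the held-out test set (empty-well
references always join the pool).  Within the pool, wells split 70/30 by a
seeded shuffle.  Only endpoint-day labels exist; earlier days are decoded
by the frozen model and then re-anchored per plate and day against the
untreated well (exactly 100 %, negatives floored at 0).  A plate-day whose
untreated prediction is missing or non-positive is flagged missing as a
whole and flows into the missing-data rules below.

Agreement is reported as the adjusted R² of the observed-on-predicted
ordinary least squares fit, `1 − (1−R²)(n−1)/(n−2)`, with the two-sided
slope p-value; technical replicates are averaged before the regression.

## Synergy scoring

Monotherapy margins (first row/column) are fitted with a four-parameter
log-logistic `V(d) = emax + (e0 − emax)/(1 + (d/EC50)^s)` by bounded
least squares (e0 ∈ [80, 120] around the normalized control,
emax ∈ [0, 100], EC50 within two decades of the tested range,
s ∈ [0.2, 10]), multi-started over five log-spaced EC50 seeds.  All-equal
margins give a flagged flat fit (inactive drug); a margin that rises with
dose by more than 5 % is flagged `poor_fit` but still used.

Reference surfaces are built from the *fitted* curves (not raw margin
cells), which smooths assay noise and makes the Loewe construction
well-defined:

- **Bliss:** `V_ref = V_A(d1)·V_B(d2)/100`.
- **HSA:** `V_ref = min(V_A(d1), V_B(d2))`.
- **Loewe:** per cell, solve `d1/D_A(V) + d2/D_B(V) = 1` for `V` by
  bracketed root finding (Brent) on `(max(emax), min(e0))` with 1e-9
  tolerance, `D_X` the inverse Hill dose.  A drug that cannot reach the
  effect level (`V < emax_X`) contributes 0; if the dose pair exceeds the
  jointly reachable depth the cell clamps to that bound; an inactive
  (flat) partner collapses the reference to the active drug's curve, and
  two flat curves give a flagged untreated plane.  Sham self-combination
  reproduces the monotherapy at the summed dose to < 1e-6 — the canonical
  Loewe correctness check.

All computation stays on the % viability scale with
`delta = reference − observed`, so positive values mean the combination
killed more than the additive expectation.  The scalar score is the mean
delta over the 25 combination wells; a log-dose-step-weighted volume is
also emitted.  No claim of numeric identity with any external synergy
tool's aggregate is made — the convention is stated here and reported
with every result.

Replicate/missing rules, applied before fitting: a matrix missing any
monotherapy cell is excluded entirely; missing combination cells in
surviving matrices are imputed at 100 %; two survivors merge by cellwise
mean (a value present in only one replicate is used as-is); a lone
survivor is used alone; if neither survives the sample is absent from the
output and logged.

## Longitudinal assembly and evaluation

Synergy results group into per-(pair, line, method) trajectories sorted
by day, gaps preserved, no smoothing or trend fitting.  Endpoint
agreement between predicted and assay-derived synergy uses the same OLS
machinery as the viability evaluation, pairing by (pair, line, method).

## Problem sizes and run times

The default verification scale is 1 cell line × 4 pairs × 2 replicates:
64 px images for end-to-end runs (~35 s each on one CPU core) and 128 px
for the decoder-recovery experiment (~2 min).  The acceptance script runs
the whole set in about 3–5 minutes; full-screen scale (3 × 16 × 2,
224 px) uses identical code paths.

## Known limitations

- The decoder's evidence of validity is synthetic; see the renderer's
  non-goals above.  Real phase-contrast data will need the adaptive crop,
  polarity flag, and likely a deeper network preset.
- Loewe references inherit any monotherapy misfit; strongly non-logistic
  margins are only flagged, not remodeled.
- The additive-truth calibration is exact only for effectively exponential
  growth; near carrying capacity the Bliss identity degrades smoothly.
- Trajectories are descriptive; the package deliberately fits no
  time-trend model and performs no between-line statistics.
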