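# Methods

This note records the models the package implements, the defaults it ships,
what the synthetic-data generator does and does not emulate, and the design
choices made where the problem was genuinely open.

## Normalization model

Each plate carries its own controls: casper wells (pigment-free larvae whose
only melanin is retinal, measuring the background absorbance at 340 nm) and
vehicle-treated V12RAS wells (the untreated transgenic level). A well's
normalized signal is

    (raw − mean_casper) / (mean_v12ras_dmso − mean_casper),

an affine map fixing casper at 0 and the untreated transgenic mean at 1.
Normalization is strictly per plate — plates are internally calibrated and
no screen-global scaling is applied — and is invariant to any plate-wide
additive offset. Control wells are aggregated with the arithmetic mean by
default; the median is available (`control_stat="median"`) for plates with
suspect control wells. No positional (row/column/edge) corrections are
applied; the assay this models uses none.

The raw control means of the generator (casper 0.05, wild type 0.35,
transgenic 0.479 AU) are calibrated so that the background-subtracted
transgenic/wild-type ratio is 0.429/0.30 = 1.43 and the wild-type level is
0.699 on the normalized scale. Fold changes between groups are computed on
background-subtracted values by default (per-experiment ratio of group
means, summarized as mean ± SEM over experiments); computing on raw values
is possible by passing unsubtracted arrays, since whether background
subtraction precedes such ratios is an assay-reporting convention rather
than a mathematical necessity.

Assay quality is summarized by the Z-factor, Z′ = 1 − 3(σp+σn)/|µp−µn|,
computed from whichever control pair the caller designates. In the
simulated pipeline report the positive control is the untreated transgenic
well population and the negative the casper background; with a fully
suppressing pharmacological control the wild-type level would be the
natural positive instead, and `z_factor`/`assay_qc` are agnostic to the
choice.

## Hit-calling cascade

Toxicity is assessed per well as embryos_alive/embryos_in with an inclusive
80% pass threshold. A compound whose analysed wells all fail is queued for
one rescreen at half dose; failing again excludes it (`toxic_excluded`)
from all further statistics.

The primary call is the median ± MAD rule computed over the whole screen
arm after exclusions: hit ⇔ signal < median − k·c·MAD with k = 2.5. The
scale constant c defaults to 1.4826 (MAD consistent with a normal SD) and
may be set to 1.0 for the raw-MAD convention; the synthetic screen preset
is constructed so both conventions select the same hit set, since which
convention the original assay used is not recoverable from a "−2.5 MAD"
statement alone. The cutoff is one-sided: only suppression is called.
A zero MAD (e.g. quantized or constant signals) falls back to the arm SD
with a warning, or declares no hits if that is also zero — preventing the
everything-is-a-hit pathology of a zero denominator.

Retest re-evaluates each primary hit on 5 replicate wells (≥ 3 must pass
survival, otherwise the compound is indeterminate and not a hit) against
the same primary cutoff — the replicate mean must clear it. A significance
test on 5 wells would be an alternative; the cutoff criterion was chosen
because it keeps the primary and retest stages on one scale and one
decision rule.

Triage turns three qualitative follow-up criteria into predicates with
configurable thresholds (all in normalized units):

- dose dependency: Spearman ρ(dose, per-dose mean signal) ≤ −0.8 over ≥ 3
  doses and max−min mean signal ≥ 0.15 (the span condition rejects flat
  series whose noise happens to rank monotonically);
- cooperation: combination mean < single-agent mean − 0.05;
- wild-type sparing: |wild-type mean − wild-type DMSO baseline| ≤ 0.10.

The numbers 0.8/0.15/0.05/0.10 are operational definitions of "clear",
"stronger" and "negligible" — they are exposed as `TriageConfig` keys and
should be tuned to the assay's noise when used on real data. A final hit is
the conjunction of all three; a compound missing any series is
indeterminate with the reason recorded.

## Median-effect model and combination index

Dose-response series are fitted with the median-effect equation
fa/(1−fa) = (D/Dm)^m by unweighted least squares on
log10(fa/(1−fa)) vs log10(D); Dm = 10^(−intercept/slope) is reported as the
IC50 and r² comes from the same regression. Fractions affected are clipped
to [0.005, 0.995] before the logit (points at exactly 0 or 1 carry no
finite logit; the clip keeps them informative while bounding their
leverage), and the number of clipped points is recorded. A non-positive
slope flags the series as a non-inhibitor rather than erroring, so
screening code can log and move on. For melanin data the natural mapping is
fa = 1 − normalized_signal (suppression of the transgenic excess); for
cell-viability data fa = 1 − treated/control.

The combination index at observed effect fa for applied doses (d1, d2) is
CI = d1/Dx1(fa) + d2/Dx2(fa) with Dx(fa) = Dm·(fa/(1−fa))^(1/m). Classes
follow the common bands: CI < 0.3 strong synergy, < 0.9 synergy,
0.9–1.1 additive, > 1.1 antagonism (configurable). Constant-ratio designs
are produced by `design_fixed_ratio`, anchoring the ratio at the two
single-agent excess-melanin ED50s and serially diluting; the ED50 itself is
obtained by log-linear interpolation between bracketing tested doses, never
by extrapolation. Bliss/HSA/ZIP/response-surface models are out of scope.

The combination generator inverts the CI definition: for each total dose it
solves d1/Dx1(fa) + d2/Dx2(fa) = CI for fa by bracketed root finding
(Brent, xtol 1e−15) — the left side is strictly decreasing in fa, from +∞
to 0, so the root is unique. `compute_ci` after noiseless fits recovers the
generator's target CI to better than 1e−6, which is the module's central
correctness oracle: the fit, the Dx inversion and the CI sum must all be
consistent for it to hold.

## Image quantification

Measurements use a binary mask (foreground = intensity below threshold) so
that per-cell melanin intensity cannot influence area or count — halving
foreground intensities changes nothing, which is the point of masking. The
stripe measurement restricts to a 1000×500 px rectangle (pixels, top-left
origin, half-open) anchored at a user-supplied yolk-sac-extension landmark;
no landmark auto-detection is attempted. Counts use 8-connected components
with a ≥ 4 px de-noising floor (both configurable). The default threshold
is a fixed 128 — appropriate for the synthetic fixtures' bimodal histogram —
with Otsu available for real images (in Otsu mode the returned threshold
belongs to the dark class, so the comparison is ≤). Spheroid growth is the
area ratio of the largest dark component at t72 vs t0.

## Synthetic-data generator

The generator produces the statistical structure the analysis assumes, not
zebrafish biology: signals are role means plus noise, with compound effects
acting multiplicatively on the excess over background
(signal = casper + effect·(v12ras − casper), so effect 0.5 halves the
excess melanin). There is no plate-position structure, no drift, no
pharmacokinetics, and no optics beyond additive background; passing tests
therefore demonstrate the correctness of the decision logic and estimators,
not robustness to real-plate artifacts.

The screen preset (the generator defaults) is the study-scale construction:
640 compounds read once each at 1 µM in a backbone-combination arm, on
24-well plates with 2 casper + 2 transgenic-DMSO controls and 10 embryos
per well; 25 true suppressors at normalized 0.55; 12 null compounds whose
single primary well flukes to 0.55 and reverts on retest; 5% of null
compounds toxic in the primary pass (rescreened clean at half dose — the
assay's average rescreen concentration); 5 retest wells per primary hit;
and follow-up profiles such that exactly 11 suppressors pass triage, the
other 14 cycling through single-predicate failure modes (flat dose series;
insufficient combination margin; wild-type suppression, the profile of a
potent but non-selective pigment bleacher). Well noise is uniform with
half-width 0.04 in normalized units by default: bounded noise makes the
cascade counts 37 → 25 → 11 deterministic by construction, because no null
well can reach the cutoff (≈ 0.95 with c = 1, ≈ 0.92 with c = 1.4826) and
no suppressor well can miss it. Gaussian noise is available for estimator
bias studies where tails matter. Control wells of generated screen plates
are rendered at their exact means so the normalization scale is exact;
placing bounded noise on controls as well would let per-plate calibration
wobble push null wells across the raw-MAD cutoff and make the hit set
depend on the scale-constant convention. No well-to-well variance estimate
exists to emulate, so these noise scales are chosen for test determinism,
not biological realism.

Survival is a per-well binomial draw (p = 0.995 healthy, p = 0.4 toxic);
the drawn count for a designated-toxic primary well is capped just below
the 80% threshold so "toxic" wells are toxic by construction, while all
downstream classification acts only on the integer counts. Image spots are
filled discs rasterized by center-distance test without anti-aliasing
(areas are exact pixel counts), with centers spaced at least
2·max_radius + 2 px so discs stay disjoint under 8-connectivity and the
component count equals the spot count; ground truth records the exact
rendered foreground pixel set.

Every generator is deterministic given its seed (bit-identical tables), and
each has a downstream estimator that recovers its parameters exactly at
zero noise — the package's round-trip oracles.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full 640-compound screen
(about 4,400 wells — milliseconds to generate and analyse), 60 images of
1100×600 px for the count contrast, 200 replicate fits for the noisy-IC50
study, and 1,000 random tables for the median/MAD cross-check. Tolerances:
CI recovery 1e−6 (dominated by fit round-off; the root finder itself is at
1e−15), sham-combination additivity 1e−9, rasterized disc-area ratio 1%.
Ties in the MAD computation follow numpy's median (mean of central order
statistics).

## Known limitations

- The screen model has one well per compound per arm in the primary pass;
  pooling across arms or replicate primaries would need a small extension
  of the cascade's per-compound aggregation.
- Triage thresholds are assay-calibration parameters, not universal
  constants; defaults reflect the synthetic preset's noise scale.
- The imaging module measures; it does not detect or register larvae, and
  the ROI landmark must be supplied.
- Real plates have positional effects this package neither simulates nor
  corrects.
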