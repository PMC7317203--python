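# Methods

## The detection problem

Leafminer adults puncture leaves for feeding and egg laying; larvae tunnel
inside leaf tissue from about day seven. Both kinds of damage perturb leaf
reflectance — chlorophyll-linked changes near the red edge (~680–750 nm)
and structure/water-linked changes in the NIR plateau — but so do nutrient
status and plant age. The pipeline therefore asks two questions: can any
*single* spectral band indicate infestation without also responding to
fertilizer (band screen), and can a multivariate classifier detect
infestation reliably across fertilizer regimes, plant ages, and
independently grown crops (SVM with binary collapsing)?

## Synthetic campaign generator

No raw imagery from the original trials is deposited, so the generator
emulates the campaign's statistical structure. A plant's noise-free
spectrum is a logistic red-edge curve

    R(λ) = R_vis + A / (1 + exp(−(λ − λ_e) / w))

with a visible floor `R_vis`, plateau amplitude `A`, red-edge position
`λ_e` and width `w`. Treatment effects act on these parameters:

| effect | parameter | default | rationale |
|---|---|---|---|
| plant age (period step) | A +0.02, λ_e +1.5 nm | per period | canopy growth, chlorophyll accumulation |
| fertilizer level | λ_e ±3 nm | per level | chlorophyll tracks nutrient strength |
| infestation, early | A −0.015, w +1.0 nm | — | adult puncture damage |
| infestation, late | A −0.04, w +2.5 nm | — | larval mining ≥ early damage (enforced) |
| series random effect | A sd 0.004, λ_e sd 0.5 nm | per series | growing-batch variation |
| plant random effect | A sd 0.008, λ_e sd 0.6 nm | per plant | biological variability |
| pixel noise | 2% multiplicative | per pixel/band | sensor/illumination noise |

5% of infested plants are *escapes*: the transferred insects fail to
establish and the plant expresses only 40% of the infestation effect.
Escapes give the campaign the two properties the real study reports
qualitatively: cross-series binary accuracy in the high 90s rather than
100%, and a partition sweep whose accuracy distribution is much wider at
95:5 than at 50:50 (a single hard plant in a 17-profile validation set
costs ~6 points). Without them the synthetic task is perfectly separable
and both signatures vanish.

Per-class plant counts reproduce the published validation table's "Plants"
column (172 profiles per series for bok choy, 174 for spinach; half-integer
cells alternate the extra plant between series). Baseline cells carry the
future infestation assignment with true status non-infested. Each
plant-observation is treated as an independent profile (the study pools
measurement days into periods); per-plant repeated-measures correlation is
not modelled.

Scenes are rendered as raw digital numbers under a smooth halogen-like
illuminant (3200 K Planck shape — the acquisitions were made at night
under active lighting precisely to avoid shadows and scattered skylight,
so no such artifacts are simulated). The stored white reference is the
panel capture already corrected for the panel's known 0.99 reflectance, so
`DN / white` recovers reflectance exactly and panel pixels calibrate to
0.99. Soil background has low red/NIR contrast (NDVI ≈ 0.04), far below
every crop's masking window. Pixels per plant (400) and scene geometry are
arbitrary and configurable; nothing downstream depends on them beyond the
averaging count.

What passing tests do **not** show about real data: the generator has no
leaf-mine spatial texture, no radiative-transfer realism (PROSPECT/SAIL),
no insect population dynamics, and its effect sizes are chosen, not
measured — so end-to-end accuracies on synthetic campaigns validate the
*machinery* (bookkeeping, calibration, masking, model fitting, validation
arithmetic), not the detectability of real leafminer damage.

## Preprocessing conventions

* Calibration is the white ratio only; no dark-current subtraction is
  modelled. Values outside [0, 1.5] are clipped with a warning count.
* The NDVI filter uses the retained bands nearest 670 nm (red) and 800 nm
  (NIR) — the classical NDVI pair inside the 619.5–983 nm window — and is
  strict at both ends. Thresholds are configurable per crop.
* Binning averages contiguous triplets (93 → 31); partial bins are an
  error. New band centers are member-center means.
* The first derivative is the forward difference indexed by the left band.
  To keep 31 values for the per-band analyses, the last difference is
  repeated by default (`keep_length=False` gives the strict n−1 form).
* The chain is order-fixed (calibrate → subset → mask → average → bin →
  derivative) and each stage validates its input, so re-running a stage on
  its own output fails loudly.

## Band screening

Per band × period: `y ~ C(fertilizer) + C(group) + (1 | series)`, additive
fixed effects (no interaction — the design names two treatment factors),
REML. At baseline the infestation factor is the assigned group. p-values
are Wald tests on the factor terms in F form — with ~100 observations per
period the chi-square form is measurably liberal (empirical size ≈ 0.068
at α = 0.05 in null simulations; the F form restores ≈ 0.05). A two-level
random intercept is frequently degenerate; if the mixed fit fails or
returns non-finite p-values, the model falls back to OLS with series as a
fixed block and the fit is flagged `converged=False`. No multiple-testing
correction is applied by default (matching the original analysis); a
Benjamini–Hochberg flag is available.

## Classification

Features are the 31 binned derivative bands, z-scored on the training set.
The SVM is linear-kernel, one-vs-one, C = 1 (the conventional libsvm
default; no hyperparameter search, matching the original toolchain). A
raw-reflectance mode and a 33-feature variant (bands + numeric period and
fertilizer covariates) are available by flag; the derivative-only 31-band
form is the default. Models serialize to a documented JSON sidecar
(scaler moments + pairwise hyperplanes); the deserialized predictor votes
over pairs with ties broken deterministically by summed decision values.

## Validation

The partition sweep draws unstratified simple random splits; splits
leaving a training class empty are redrawn and counted. Accuracy is always
binary-collapsed. True validation runs both train/validate directions;
percentage confusion rows are averaged cell-wise and stored at one-decimal
precision (the precision at which such tables are printed), while binary
metrics come from the pooled un-rounded predictions. Recomputing metrics
*from* a table weights each cell by (cell% / 100) × plants × 2; with
integer rounding the FP/FN totals are rounded to whole plants before the
accuracy ratio.

## Numerical and testing choices

* Monotonicity properties (sweep mean vs training fraction; accuracy vs
  infestation amplitude) concern expectations; tests compare Monte-Carlo
  estimates (n_iter = 200, or 3-seed means) and allow a 0.005–0.01 slack,
  2–3 Monte-Carlo standard errors.
* Sweep-based checks run at n_iter = 200 and the screening null
  calibration at 500 independent fits; the full campaign sizes (344/348
  profiles) are used everywhere else. These sizes keep the whole suite at
  a few minutes while leaving the binomial error bars well inside the
  asserted bands.
* The degenerate band-subset window [983, 983] keeps exactly one band;
  empty subsets are errors.
* NDVI of a zero-reflectance pixel is NaN and never passes a threshold.
* Seeded `numpy.random.Generator` streams are derived from the config seed
  via `SeedSequence` with fixed stream keys, so design, per-series effects
  and pixel noise are independently reproducible.

## Known limitations

* The generator's grid is piecewise-uniform (23 bands below 619.5 nm, 93
  above); the real sensor's exact band centers are not published.
* The exact derivative formula cited by the original analysis is not
  given there; the forward difference is used.
* Whether the original NDVI filter used sensor-native or binned bands is
  unstated; masking here precedes binning on the subset grid.
* The published per-band significance maps and accuracy curves depend on
  the real imagery and are not reproduced quantitatively — structural
  counts, calibration properties and qualitative behaviours are.
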