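# Methods

## Estimation model

The assay cools plates of n replicate droplets through a strictly decreasing
grid of sub-zero setpoints (default −2 … −28 °C in 2 °C steps, 30 min holds)
and records the cumulative number of frozen wells per setpoint. Freezing is
treated under the singular approximation: a droplet's fate depends only on
the coldest temperature it has reached, not on hold-time kinetics. Under
this approximation the number of INPs per droplet active at or above T is
Poisson with mean λ(T), P(frozen at T) = 1 − e^{−λ(T)}, and the cumulative
INP concentration per cell is

    N(T) = −ln(1 − FF_corr(T)) / (c · V),

where FF_corr = FF_sample − FF_control, c is the cell concentration
(cells µL⁻¹) and V the droplet volume (µL). Cell-free plates (buffer
controls and 0.22 µm filtrates) are normalised per droplet: N_d(T) =
−ln(1 − FF_corr)/V. All spectra live on the protocol's setpoint grid; no
interpolation is performed. "Warmer" always means numerically greater in °C.

Per-setpoint status flags:

* negative corrected fractions (control out-freezing the sample) are
  excluded, not clipped to zero — they carry no estimate downstream;
* a fully frozen sample plate (k = n) is **saturated** regardless of the
  control, because the plate cannot resolve activity above its upper
  detection limit; the reported value is the continuity-corrected lower
  bound using FF = (n − ½)/n minus the background, with an unbounded upper
  confidence limit;
* estimates below the plate's lower detection limit −ln(1 − 1/n)/(cV) (one
  frozen well) are **below_detection** with value retained (often 0);
* anything else is **ok**.

Uncertainty is a two-sided Clopper–Pearson interval at level 0.95 (default)
on the sample frozen-well count, shifted by the control frozen fraction
(clipped at 0) and pushed through the monotone Vali map. The interval
therefore reflects the sample's binomial noise only; control noise enters
the point estimate but is not propagated, which is acceptable because the
background is tuned (and in practice kept) far below sample activity except
near the cold end, where plates saturate anyway. Standard deviations across
biological replicates can be computed from the per-replicate spectra the
pipeline writes.

Dilution series are combined per setpoint by the unweighted arithmetic mean
of the estimates (and of the interval endpoints) over dilutions flagged ok.
Equal weights are the transparent choice in the absence of a principled
variance model for a censored dilution ladder; the empirical coverage of the
averaged interval is verified by simulation (≈98 % at nominal 95 % in the
recovery test). When no dilution is usable at a setpoint, a saturated
dilution dominates (its largest lower bound is kept), else below_detection,
else the setpoint is removed. The merge is permutation-invariant.

The three-replicate quality rule keeps a strain only when each of exactly
three biological replicates has at least one ok setpoint; the warmest
setpoint ok in *all* replicates is the onset temperature (configurable to
*any*), which bins into warm (≥ −6 °C), mid (−6 > T ≥ −12), cool
(−12 > T ≥ −18) and cold (−18 > T ≥ −24) classes; the −6 boundary belongs to
the warmer class, colder boundaries to the colder side. Screening uses the
raw (uncorrected) frozen fraction at −24 °C with an inclusive 0.5 cutoff by
default; a background-corrected screen is available by configuration.
Confirmation requires every one of at least two independent screens to be
positive.

## Nature inference

Heat treatment (100 °C, 10 min) denatures proteins; filtration (0.22 µm)
removes cells and fragments, leaving the soluble exudate. The inference
brings all arms onto a common per-droplet scale (per-cell spectra × c),
restricts to an optional temperature window — this is how
temperature-resolved verdicts are produced for strains whose active
component changes along the spectrum — drops setpoints removed in any arm,
maps below_detection to 0 and keeps saturation lower bounds, then runs a
Kruskal–Wallis test across arms followed by Dunn pairwise contrasts against
the untreated arm. The protein axis is proteinaceous iff the heated arm is
significantly lower (gate + pairwise, default α = 0.05, unadjusted p as
default with Holm/BH available); the localization axis is cell_associated
iff the filtrate arm is significantly lower, soluble otherwise. A missing
arm yields an indeterminate axis with a logged reason. Rank tests tolerate
the strong temperature trend because it is shared across arms.

## Statistical tests

`dropfreeze.stats` implements the three tests directly from their formulas:
the 2×2 equality-of-proportions chi-squared with Yates continuity
correction (correction capped so equal proportions give exactly 0, df = 1),
the Kruskal–Wallis H with mid-ranks and tie correction
1 − Σ(t³ − t)/(N³ − N), and Dunn's z with tie-corrected pooled variance
N(N+1)/12 − Σ(t³ − t)/(12(N − 1)). Only the chi-squared/normal asymptotic
p-values are provided — no permutation variants. Multiplicity adjustment
across Dunn pairs defaults to none, with Holm and Benjamini–Hochberg
selectable. The test suite checks the implementations against closed-form
and brute-force rank oracles and against scipy's Kruskal–Wallis, and
verifies type-I error behaviour by simulation (the corrected proportion
test is conservative by construction).

## Simulator

The generator emulates the study conditions: 16-well screens and 32-well
profile plates of 20 µL droplets at a stock concentration of 100 cells µL⁻¹,
a 10-fold dilution ladder (1, 10, 100), three biological replicates, and a
PBS control per plate batch. Ground truth is a sum of log-linear cumulative
components K(T) = A·e^{γ(onset − T)} for T ≤ onset — the minimal parametric
family reproducing onset-plus-point-value reporting — each labelled
proteinaceous/non-proteinaceous × particulate/soluble (and optionally
epibiont-derived). Treatments transform the truth: heating removes
proteinaceous components, filtration keeps soluble ones (exuded activity
scales with the source suspension's cell concentration, recorded on the
cell-free droplet), and the axenic treatment attenuates epibiont components
by a configurable factor (default 0.05). Both heating and filtration are
idempotent. Per-droplet background freezing uses a small soluble
non-proteinaceous component (A = 10⁻³ per droplet, onset −20 °C, γ = 0.4)
tuned so a 16-well control rarely freezes above −24 °C.

Wells freeze by the stochastic inverse of the Vali relation: one uniform
draw per well, frozen at the warmest setpoint where 1 − e^{−rate(T)} ≥ u,
with rate(T) = K(T)·c·V + K_bg(T). Randomness derives from one master seed
through SHA-256 keyed substreams per (plate, replicate, dilution), so
identical seed and configuration give byte-identical output.

The default strain panel fixes the design margins exactly rather than
binomially: 81 airborne strains (40 Trebouxiophyceae / 6 Chlorophyceae /
11 Xanthophyceae / 24 unknown) of which 14 are INA (6 warm / 5 mid /
3 cool onsets) and 66 screen-positive initially, 32 aquatic strains of
which 16 are INA (2 mid / 12 cool / 2 cold), 10/32 aquatic and 38/38 tested
airborne freeze survivors, 11 aquatic desiccation-tested with no survivors,
and a generalist fraction of 0.5 across four media. Which strains carry
which label is randomised under the seed. The screen-to-confirmation
attrition (66 initial vs 14 confirmed positives) has no mechanistic model —
no plate-level process is described that would produce a transiently
positive screen — so unconfirmed screens are represented in the metadata
(`ina_status = screened_only`) while plates are generated from the stable
truth only.

What the simulator deliberately omits: hold-time (stochastic-rate) freezing
kinetics, droplet-volume variability, cell-counting error, inter-replicate
biological variability of the spectrum, and plate-position effects. Passing
tests therefore demonstrate correctness of the estimation chain under the
singular Poisson model, not robustness to these real-data complications.

## Numerical and design choices

* Vali evaluation uses `log1p` for accuracy at small corrected fractions.
* The saturation bound FF = (n − ½)/n is a continuity correction preserving
  order statistics at the plate ceiling.
* The Vali estimator is convex in FF, so plate-mean estimates carry a small
  positive Jensen bias (≈ +2 % at FF = 0.5, n = 32) that shrinks with well
  count; the consistency checks use Monte Carlo standard-error bands that
  accommodate it.
* Taxonomy rank assignment: coverage ≥ 89 %, identity strictly > 89 % and
  e-value below threshold gate any assignment; then species at ≥ 97 %
  identity, genus at ≥ 95 %, else higher rank. The e-value bound "< e^−189"
  is read literally as exp(−189), with the 10^−189 convention selectable —
  the notation is ambiguous in the field's reporting style.
* Percentages: one decimal for composition tables, nearest integer for
  survival headlines; denominators are always reported explicitly.
* Problem sizes in tests and the acceptance script (500 plates for the
  consistency check, 100 simulations × 9 plates for recovery, 200 factorial
  batches for nature inference, 2000 null simulations for type-I error)
  were chosen to put Monte Carlo error well below the tested margins while
  keeping the default suite fast on a single CPU.

## Known limitations

* Control-noise propagation into the confidence intervals is omitted (see
  above); with high backgrounds the intervals are anti-conservative.
* The background-corrected frozen-fraction difference is not exactly the
  rate difference (FF subtraction vs rate subtraction differ by a factor
  e^{−λ_bg}); the bias is negligible for the default background but grows
  with control activity.
* The chi-squared/normal approximations of the rank tests are inaccurate
  for very small groups (≲ 5 per arm); no exact variants are provided.
* `infer_nature` assumes the arms share a protocol and batch; it does not
  model batch effects between treatment runs.
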