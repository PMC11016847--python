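# Methods

This note documents the models, the numerical conventions and the design
choices behind `buddormancy`, and what the synthetic-data generator does
and does not emulate.

## Isotope stage

Delta values are per mil against VSMOW. Conversion to atom percent uses
the standard ratio form `atom% = 100·R·(δ/1000+1) / (1+R·(δ/1000+1))`
with library constants `R(²H/¹H) = 1.5576e-4` and
`R(¹⁸O/¹⁶O) = 2.0052e-3` (overridable per analysis). The inverse is
algebraic, and the round trip is exact to better than 1e-10 relative
over δ ∈ [−900, 10000]‰ — important because the uptake statistic is a
small difference of atom-percent values.

The natural-abundance background δ²H of a labelled sample is predicted
from its measured δ¹⁸O via a per-species ordinary least squares line
fitted on natural-abundance campaigns. Lines are fitted **pooled across
sites** by default (per-site fitting is a config switch): the
δ¹⁸O–δ²H relationship reflects species-level evaporative physiology
rather than site climate, and pooling doubles the fitting sample. A
line needs at least 3 samples; zero δ¹⁸O variance is a hard error.
Twig-tissue samples reuse the bud line of their species — their
natural-abundance slope is indistinguishable from the bud slope, and
only buds are sampled in the background campaigns.

Uptake values are **not clipped**: small negative values are the
signature of instrument noise around a true zero, and clipping would
bias campaign means upward exactly where the biology says "closed".
Values outside [−5, 105]% are flagged, not rejected. A guard requires
the label δ²H to exceed the predicted background by ≥ 100‰ (about 30×
the 1‰ instrument noise on the numerator terms); closer labels make the
denominator ill-conditioned and the call fails loudly.

The slope comparison against the global meteoric water line (slope 8,
intercept 10‰) flags evaporative enrichment when `β₁ + 2·se(β₁) < 8`.

## Phenology stage

Hourly logger series aggregate to daily mean/min/max and within-day
standard deviation; days with fewer than 20 hourly readings are flagged
but kept (no gap imputation). The period summary — mean of daily means
± mean of daily sds — is the convention used for campaign-window
climate. First frost supports two definitions: first day with minimum
below 0 °C and first day with mean below 0 °C; the former can never be
later than the latter.

Budburst success is the per-twig fraction of buds at stage ≥ 2.
Thermal time is `days to first observed stage-2 date × (forcing −
base)`; with the default base of 0 °C and constant 20 °C forcing this
is days × 20 °C·d. Any base rescales thermal time monotonically under
constant forcing, so inference is invariant to the choice. The stage-2
date is the first **monitoring** date at which stage ≥ 2 was seen
(twice-weekly checks); no interpolation between visits — interpolation
would invent precision the protocol does not have. Twigs that never
reach stage 2 are censored: they contribute a success fraction but no
thermal time, which is why the success and depth models have different
n. Stage 2 on the forcing start day itself is kept but flagged
suspicious. Water content is on a fresh-mass basis,
`100·(fresh − dry)/fresh`, keeping values in [0, 100); a dry-mass basis
is available by config.

## Statistical stage

Four response models, all with species (5 levels), site (2 levels) and
every two-way interaction as fixed effects and donor tree as the
grouping unit:

* **budburst success** — binomial GLM on per-twig proportions with
  binomial weights, logit link, sampling date continuous (units of 30
  days), **cluster-robust covariance by tree**; type II ANOVA.
  A frequentist binomial mixed model is deliberately not attempted:
  the fixed-effects-plus-cluster-robust route estimates the same
  population-level contrasts and is robust to the within-tree
  correlation a random intercept would absorb.
* **dormancy depth** — linear mixed model (random tree intercept) on
  ln(thermal time) with an orthogonalised second-order date polynomial;
  both polynomial orders interact with species and site (the date main
  term has 2 df, date×species 8 df). Restricted to campaigns on/after
  the first frost (auto-detected as the earliest daily-minimum frost
  across sites, overridable), because pre-frost depth patterns are
  non-linear and inconsistent across species. Type III ANOVA.
* **water content** and **uptake** — linear mixed models with campaign
  as a categorical factor (15 levels), type III ANOVA. If a mixed fit
  fails to converge the model falls back to OLS with cluster-robust
  errors by tree, recorded in the diagnostics; on well-conditioned data
  the two routes give the same coefficient signs.

ANOVA tables are Wald chi-square tests computed on sum-coded designs
built by the package's own design-matrix layer: type III tests each
term's coefficient block in the full model (valid under sum-to-zero
coding), type II refits per term without the higher-order terms that
contain it (marginality rule). The two coincide exactly on balanced
designs without interactions, which is tested. Rank-deficient blocks
use a pseudoinverse with the block's matrix rank as df.

Post-hoc comparisons are Tukey-HSD contrasts of estimated marginal
means: the design is averaged over the reference grid (cartesian
product of factor levels, continuous covariates at their data means),
pairwise differences are tested with the studentized-range distribution
(k = number of levels, df = residual df capped at 1e4). For a
two-level factor the adjusted p equals the unadjusted one. Adjustment
is within a factor's family only; no across-model correction is
applied. α = 0.05 throughout.

Correlations between the four proxies are per species, Pearson, paired
at the **tree × campaign** level (twig-level responses averaged per
tree and campaign first; twig-level pairing is a config option). The
leaf-senescence campaigns 1–3 are excluded by default: while leaves are
active, uptake reflects senescence physiology rather than bud
dormancy. Pairs with fewer than 4 complete observations are marked not
computable rather than dropped.

Endodormancy onset: on the per-species campaign means of uptake, the
peak is located inside an autumn window (campaigns up to mid-December
by default); the onset is the first later campaign whose mean falls
below `threshold_fraction × peak` (default 0.1) **and stays below at
the next campaign**. The persistence rule rejects single noisy dips;
the last campaign can therefore never be an onset. The detector is
invariant to uniform rescaling of the series.

## Synthetic-data generator

The generator emulates the study conditions: two sites ~2.3 °C apart
(campaign-window means ≈ 6.4 ± 2.7 and 4.1 ± 1.8 °C; hourly series =
seasonal sinusoid with mid-January minimum + diurnal sinusoid peaking
at 14:00 + AR(1) noise), five species with contrasting dormancy
parameters, 12 biweekly campaigns October–March plus 3 extra
mid-winter ones, 5 trees per species × site, three natural-abundance
campaigns the following winter (8 samples per species × site × date),
and instrument noise of 1‰ (δ²H) and 0.2‰ (δ¹⁸O).

Latent biology: chilling hours accumulate while air temperature is in
[0, 10] °C (a deliberate simplification — the chilling band and
hours-accounting are configurable); ln(dormancy depth) declines
linearly with chill from its autumn value to ln(forcing requirement),
reached at the species' chilling requirement. Requirements are sized so
release stretches into late winter, as observed. Budburst success
rises from a base to a maximum proportion with the chill fraction, with
a tree-level random effect on the logit; per-twig bud counts are
binomial, and twigs with zero successes are censored. Observed stage-2
days are snapped to the twice-weekly monitoring grid.

Uptake trajectories: a low pre-senescence value, a peak during the
senescence window (late October–mid November), a collapse to a
near-zero floor — the first floor campaign, campaign 4 under the
default calendar, is the programmed onset — and, for beech and lime, a
rise at the final pre-budburst campaign. Biological spread is
**multiplicative** (lognormal tree and sample effects, cv ≈ 0.3 and
0.2) plus a small additive term: spread proportional to the signal
keeps near-zero winter uptake near zero, whereas additive noise of the
autumn-peak magnitude would inflate zero-clipped winter means and make
any onset detector miss the spec'd collapse. The uptake magnitudes
themselves (peaks of ~25–45%) are order-of-magnitude choices; no field
calibration exists for them.

Water content follows a U: autumn plateau, post-senescence minimum,
then a recovery **coupled to the chill fraction** (bud rehydration
tracks deacclimation — this coupling is exactly what makes water
content a usable proxy for dormancy release, and it is what the
correlation stage must recover), plus a faster rise in the final ~45
days before the species' field budburst date.

Isotopes are generated on the atom-fraction scale: the sample's true
atom% is `background + uptake/100 × (label − background)`, inverted to
delta, then instrument noise is added. With all noise terms zeroed the
pipeline recovers the programmed per-sample uptake exactly (to
floating-point round-off), which is the airtight oracle for the whole
isotope chain. Natural-abundance δ¹⁸O drifts from −4‰ to +6‰ over the
season (the late-winter evaporative shift) with the species line
preserved by construction, so the background prediction remains valid.

What the generator does **not** emulate: extraction-efficiency effects
of the water extraction itself, within-bud tissue compartments,
frost-damage or ABA/callose dynamics, spatial structure beyond the two
sites, and any autocorrelation of residuals beyond the tree random
effects. Passing tests therefore demonstrate that the pipeline recovers
the programmed structure at realistic noise levels — not that the
simplified latent biology is itself correct.

## Problem sizes and determinism

The default experiment is 750 forced twigs, 750 labelled bud samples
(+50 twig-tissue samples at the mid-January campaign) and 240
background samples; a full simulate-plus-analyse run takes about one
second, and the acceptance script's replicate studies (20 seeds for
background-line recovery, 100 onset replicates, 50 power and 200 null
fits for the success model) run in well under a minute. All randomness
flows from a single integer seed through `numpy.random.SeedSequence`;
identical seeds give byte-identical output files (output headers carry
a config hash, never timestamps).
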