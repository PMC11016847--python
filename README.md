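# buddormancy

Quantitative analysis of winter bud dormancy in temperate deciduous
trees from four complementary proxies measured on twig cuttings sampled
repeatedly through winter:

* **short-term water uptake** — twigs incubated 24 h in
  deuterium-enriched water (δ²H ≈ 2000‰); the fraction of bud water
  replaced by label reads out whether the vascular pathway into the bud
  is open;
* **bud water content** — fresh vs dry mass of the bud, a low-tech
  marker that tracks rehydration during dormancy release;
* **budburst success** — fraction of a forced twig's buds reaching the
  budburst stage (stage 2 on the 0–4 scale);
* **thermal time to budburst** — degree-days at 20 °C forcing until
  budburst, the classic readout of dormancy depth.

The package is aimed at tree ecophysiologists and phenology modellers
who run (or simulate) such multi-campaign, multi-site labelling
experiments and want the full analysis chain — isotope arithmetic,
climate aggregation, mixed-model ANOVAs, post-hoc contrasts,
campaign-filtered correlations and endodormancy-onset detection — as
tested, reusable code.

## The core calculations

Natural-abundance bud water drifts isotopically through winter, so the
unlabelled background δ²H of each sample is predicted from its measured
δ¹⁸O via a species-specific regression fitted on natural-abundance
campaigns:

    δ²H_background = β₀ + β₁ · δ¹⁸O_sample

Delta values convert to atom percent with the VSMOW reference ratio R:

    atom% = 100 · R · (δ/1000 + 1) / (1 + R · (δ/1000 + 1))

and the short-term uptake of labelled water is the excess over
background normalised by the label excess:

    uptake% = (atom%_sample − atom%_background) /
              (atom%_label − atom%_background) · 100

A background slope β₁ below the global meteoric water line slope of 8
flags evaporative (Rayleigh) enrichment of the bud water pool.

The statistical stage mirrors the experiment's design: budburst success
is a binomial (logit) model with sampling date continuous, species,
site, all two-way interactions and donor tree as the grouping unit
(type II ANOVA); ln(thermal time) gets a second-order date polynomial
restricted to campaigns after the first frost (type III); water content
and uptake are modelled with campaign as a 15-level categorical factor
(type III), with Tukey-HSD contrasts of estimated marginal means.
Per-species Pearson correlations between the four proxies exclude the
leaf-senescence campaigns 1–3, and the endodormancy onset is located as
the first campaign after the autumn uptake peak whose mean falls below
a threshold fraction of the peak and stays there (persistence rule).

A fully parameterised synthetic-data generator (`buddormancy.simulate`)
emulates the two-site, five-species, 15-campaign experiment with known
ground truth, so every stage is testable without field data.

## Worked example

```
buddormancy all --out run/ --seed 42
```

simulates a default experiment into `run/data/` and analyses it into
`run/analysis/`. The report starts with the climate and the fitted
background lines:

```
Site climate (first to last sampling campaign)
  Muttenz: 6.5 ± 2.8 °C over 173 days; first frost (daily min < 0 °C): 2019-11-17; ...
  Uetliberg: 4.2 ± 1.8 °C over 173 days; first frost (daily min < 0 °C): 2019-11-18; ...

Natural-abundance background lines (d2H = b0 + b1 * d18O)
  beech     (pooled): b0 =  -11.78 ‰, b1 =  6.17 (se 0.07), n = 48, slope deficit vs GMWL = 1.83  [evaporative]
  hornbeam  (pooled): b0 =  -20.52 ‰, b1 =  5.82 (se 0.05), n = 48, slope deficit vs GMWL = 2.18  [evaporative]
  ...
```

The two sites differ by ~2.3 °C; every species line sits significantly
below the meteoric slope of 8, the signature of evaporative enrichment.
Further down, the onset table locates the collapse of short-term uptake
after the senescence peak — campaign 4 (late November) for every
species in this run:

```
Endodormancy onset from campaign-mean short-term uptake
 species  scope  onset_campaign_index  peak_campaign_index  peak_uptake_pct ...
   beech pooled                     4                    3            34.26
hornbeam pooled                     4                    2            48.41
...
```

and the correlation table shows the programmed biology recovered from
noisy data: thermal time is negatively correlated with both budburst
success (e.g. maple r = −0.55, p = 1e-10) and bud water content
(all five species negative, all p < 0.01) — water content rises as
dormancy is released, while mid-winter uptake stays near zero.

The same stages are available as library calls (`simulate_experiment`,
`uptake_table`, `outcomes_table`, `BudburstSuccessModel(...).fit()`,
`dormancy_correlations`, `detect_endodormancy_onset`) and as separate
subcommands (`simulate`, `uptake`, `phenology`, `analyze`, `report`).

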