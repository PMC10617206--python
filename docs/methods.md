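# Methods

## Model and procedure

The package implements a comparative risk assessment of the direct
healthcare costs of colorectal cancer attributable to red and processed
meat consumption, in five stages.

**1. Dose-response to category risks.**  Meta-analytic relative risks
are supplied per fixed intake increment: RRₓ per x = 100 g/day for red
meat and x = 50 g/day for processed meat, with 95% confidence
intervals, by sex.  They are rescaled to a per-gram risk,
RR₁ = exp(log RRₓ / x), and band risks are
RR_c = RR₁^(Mc − ref), where Mc is the band's median intake and *ref*
the reference exposure level.  The reference for red meat is the
empirical median within the reference band (< 70 g/day), not the 70
g/day boundary, so the reference band's own RR is exactly 1 under the
formula; for processed meat the reference is exactly 0 g/day.  Band
medians below the reference clamp to RR = 1 rather than extrapolate a
protective effect the meta-analyses do not model.

**2. Exposure categorization.**  Consumption records carry one usual
intake value (g/day) per person per meat, with a survey weight.  Red
meat bands: < 70, [70, 140), [140, 210), [210, 280), ≥ 280 g/day.
Processed meat bands: exactly 0, (0, 50), [50, 100), [100, 150), ≥ 150
g/day.  Weighted band proportions form the prevalence vector; Kish's
effective sample size (Σw)²/Σw² feeds the uncertainty draws; empirical
weighted band medians supply Mc.

**3. Impact fractions.**  PIF = (Σ Pᵢ RRᵢ − Σ P′ᵢ RRᵢ) / Σ Pᵢ RRᵢ; the
PAF is the special case with all counterfactual mass in the reference
band.  The two meats combine as Joint PIF = 1 − Π(1 − PIFᵢ) under
assumed absence of interaction.  Attributable cost is PIF × total cost.
Both-sex results are derived downstream, never by pooling records:
attributable costs add across sexes and the both-sex fraction is the
cost-weighted ratio (summed attributable over summed cost).

**4. Cost projection.**  Annual BRL costs (2008–2019, by sex) are fitted
by OLS on calendar year, centered before fitting to keep the design
well conditioned.  Projections carry a 95% confidence interval for the
*mean response* on n − 2 t-degrees of freedom — the published interval
half-widths are consistent with a mean-response band rather than a
prediction interval, and this choice is recorded as an assumption.
Regression runs on BRL; conversion to international dollars divides by
the purchasing-power-parity factor, 2.226 for current (2018) costs and
2.281 for projections.  Fitting is per sex; both-sex costs are sums.

**5. Uncertainty.**  Monte Carlo with 10,000 iterations by default.
Per iteration and stratum: each baseline band proportion is drawn as
Binomial(n_eff, pᵢ)/n_eff and the vector renormalized to sum to one
(the categories are strictly multinomial; independent binomials with
renormalization follow the stated estimation approach, and a Dirichlet
alternative that respects the simplex by construction is available via
`prevalence_draw_mode="dirichlet"`); log RRₓ is drawn normal with
sd = (log CI_hi − log CI_lo)/(2·1.96).  One RR draw per exposure per
iteration is shared across all bands, preserving dose-response
coherence.  The counterfactual vector is held at its point estimate —
the stated simulation draws baseline prevalence and log-RR only.
Negative PIF draws truncate to 0.  Summaries are the 2.5th/50th/97.5th
percentiles with linear interpolation between order statistics (the
percentile convention is not standardized elsewhere, so it is fixed
here).  Deterministic point estimates are exposed separately so worked
examples are exact rather than simulation medians.

## Lag pairing and scenarios

Exposure and cost years are paired with at least a 10-year lag, as
explicit configuration rather than inference: 2008-2009 consumption →
2018 costs; 2017-2018 → 2030.  Counterfactual scenarios transform
individual records and re-categorize (a categorical-only rule would
leave the serving-reduction scenario undefined):

* Scenario 1: −120 g/week red and −50 g/week processed meat, applied as
  reduction/7 g/day per person, floored at zero.
* Scenarios 2–4: consumption caps at band boundaries (red < 140/210/280
  g/day; processed < 50/100/150 g/day).  Everyone at or above the cap
  moves to the median of the highest band strictly below it — a
  minimal-change interpretation; proportional redistribution across
  lower bands would be an equally defensible reading and is not
  implemented.

Scenario savings are the truncated PIF times the 2040 projected cost.
Counterfactual prevalences reuse the baseline band medians so P and P′
share one set of category RRs.

## Synthetic data: what it emulates and what it does not

The restricted inputs (dietary survey microdata, cost registries, and
the per-category RR supplementary tables) are emulated:

* **Survey records.**  Usual red-meat intake is lognormal — dietary
  intake is right-skewed — with (meanlog, sdlog) solved exactly from two
  published tail marginals (P ≥ 70 and P ≥ 280 g/day, per sex and
  period).  Processed meat is zero-inflated lognormal: the zero mass
  equals 1 − P(> 0) as published, and with only one published positive
  tail (P ≥ 150 g/day) the meanlog is solved at a fixed sdlog of 0.8, a
  typical dispersion for episodically consumed foods.  Default sizes
  emulate the source surveys (17,000 records per sex for 2008-2009,
  18,850 for 2017-2018).  Survey weights default to 1; a gamma
  weight-dispersion option exercises the weighted code paths.  Not
  emulated: two-day repeated measures and within-person variance,
  household clustering, stratified sampling, so design effects on the
  uncertainty intervals are not reproduced.
* **Cost series.**  Linear trend plus Gaussian noise (sd 8 million
  BRL/year), with per-sex intercepts and slopes anchored to the
  published projected cost levels, so the fitted both-sex 2030
  projection lands near US$ 450 million PPP.
* **RR table.**  The packaged point estimates — red meat 1.12
  (1.00–1.25) per 100 g/day, processed meat 1.16 (1.08–1.26) per 50
  g/day, identical across sexes — are synthetic placeholders in the
  range reported by colorectal-cancer meta-analyses; the published
  analysis used per-category supplementary values that are not public.
  Replace `rr_table_csv` in the run configuration to use other
  estimates.

Consequently, passing tests demonstrate the correctness of the
machinery and calibration closure on the published marginals; synthetic
end-to-end fractions and intervals are near, but not equal to, the
published table values, which depend on the unpublished inputs.

## Numerical conventions and degenerate inputs

* Percentages print to one decimal and costs to whole dollars in
  formatted reports.  When reproducing published future-year tables, an
  optional code path rounds the fraction to one decimal *in percent*
  before multiplying by cost (the convention those entries follow);
  current-year entries multiply unrounded fractions.
* Zero-variance inputs (point CIs, infinite effective sample size)
  collapse every draw to the point estimate; boundary prevalences (0 or
  1) are degenerate under binomial draws.
* Empty bands carry NaN medians and RR 1; they hold no mass, so they
  cannot affect any sum.
* All randomness flows from explicit seeds through
  `numpy.random.Generator`; identical configuration and seed reproduce
  reports byte for byte.  Run metadata (seed, iterations, configuration
  hash) is logged.
* OLS with fewer than 3 points, a constant-year design, negative costs,
  non-positive PPP factors, infeasible calibration targets
  (non-monotone tails) and misaligned category vectors raise typed
  errors; the CLI maps configuration errors to exit code 2 and data
  errors to 3.

## Problem sizes

Default runs use the survey-scale record counts above and 10,000 Monte
Carlo iterations; the full pipeline completes in seconds.  Test-suite
checks use 1,500–50,000 records and 300–5,000 iterations depending on
what the assertion needs: statistical-closure checks (marginal
calibration at n = 50,000, interval coverage over 200 replicates at
1,000 iterations, slope recovery over 500 replicates) use the sizes at
which their tolerances are meaningful.

## Known limitations

* No interaction or substitution between exposures; no mediation; no
  recurrence modelling.
* Category medians Mc and the cost-regression coefficients are not
  given sampling uncertainty inside the PIF Monte Carlo; cost intervals
  come from the regression separately and are reported alongside, not
  convolved with, the fraction intervals (attributable-cost intervals
  multiply the fraction percentiles by the central cost).
* The cap scenarios' "move to the band-below median" rule is one
  reading of an underspecified counterfactual.
* Linear cost extrapolation over a decade ignores structural changes in
  treatment costs; the mean-response interval understates predictive
  uncertainty for any single future year.
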