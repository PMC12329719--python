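# Methods

This note records the modelling choices behind `wetrisk`: the assumptions of
each stage, the parameters that matter, what the synthetic data does and does
not emulate, and the numerical conventions.

## Trial target and preprocessing

The target of one wetland trial is the mean antibiotic removal efficiency
ARE = (1 − Σc_eff/Σc_inf) × 100%, the mass-weighted removal over the
antibiotic types measured.  Negative values (effluent exceeding influent,
which desorption and transformation products can produce) are returned with
a warning rather than clipped, because they are informative; the pure
"remaining fraction" convention Σc_eff/Σc_inf × 100 is available behind
`literal=True` for compatibility with sources that tabulate it that way.

Missing numeric cells are completed by iterative random-forest imputation:
initialize with column means, visit missing-bearing columns in order of
increasing missingness, regress each on all other variables (one-hot
encoding categoricals on the fly), and stop when the normalized squared
difference between successive imputations first rises, returning the
previous iterate.  This is the standard reference scheme for random-forest
imputation; it assumes missingness that is ignorable given the observed
variables (the generator produces MCAR gaps, its reference case).  A single
completed table is used downstream — no multiple-imputation variance
propagation.

Categoricals expand to one indicator per training-seen level; numerics are
z-scored with training statistics (population sd).  Degenerate cases are
deliberate: a zero-variance column maps to all-zeros, an unseen test level
to all-zero indicators, both with warnings, so a transform fitted on train
is never refit on test.  The 80/20 split rounds the train size half-up.

## Learner tournament and uncertainty

Five families are tuned by 5-fold CV maximizing mean fold R² (RMSE reported
alongside and used to break ties): XGBoost, KNN, random forest, SVR, and
"KNN-Boost", implemented as gradient-boosted trees fitted to the residuals
of a stage-1 KNN.  Three search strategies cover the same finite spaces:
exhaustive grid, a 10-draw random subsample, and a small Gaussian-process
expected-improvement loop (5 seeded initial points + up to 7 acquisitions).
Neural networks are out of scope at a few hundred rows.

The default search spaces are deliberately small and regularization-leaning.
At ~270 noisy training rows, unconstrained boosting reaches train R² > 0.96
by memorizing noise while mean CV R² is nearly flat across capacity — CV
cannot see that kind of overfit.  The XGBoost space is therefore capped at
depth 2, learning rate 0.05, 100–150 rounds and min_child_weight 15–40,
which holds train R² near 0.9 and keeps the train−test gap inside the 0.15
overfit-risk threshold that the selection report flags.  The spaces are
plain dicts; widen them when fitting larger or cleaner data.

Selection is by held-out R² (ties by held-out RMSE).  Prediction uncertainty
comes from a Monte-Carlo bootstrap: B = 100 members, member *b* refit on a
with-replacement resample drawn from stream `seed + b`.  Member predictions
are clipped to [0, 100] *before* aggregation (the target is a percentage);
the reported mean is the arithmetic member mean and the 95% CI the 2.5/97.5
member percentiles, so the CI always brackets the mean and collapses to zero
width at B = 1.

Three validations mirror the modelling protocol: per-feature value shuffling
on the held-out set (one-hot blocks permuted jointly so exactly one
feature's information is destroyed at a time), independent-table validation
(a disjoint random stream from the same response surface; mean absolute
error is reported in ARE points), and the train/test regime check above.

## Regional mass balance and risk

County emissions route through wetland inventories under two modes.  NM
distributes the emission over all wetlands in proportion to area.  IM sends
the entire emission through constructed wetlands (including purpose-built
treatment wetlands, excluding reservoirs) first, then passes the summed
first-stage surplus to the remaining wetlands.  The second-stage share is
area-proportional by default — "evenly" in the sense of evenly over the
wetland surface, giving one uniform second-stage concentration per county.
The literal equal-mass-per-wetland reading is retained behind
`stage2_share="mass"`; it is not the default because it loads tiny natural
wetlands with concentrations scaling as 1/area, which makes multistage
management *raise* wetland-scale risk and makes restoration (which adds
wetlands) capable of raising the naturals' mass share faster than their
treatment volume — both contrary to the mechanism the strategy is meant to
capture.  Counties with no constructed wetlands fall back to NM; counties
with no wetlands pass their whole emission to surplus with a warning.

Per wetland, AR = AI × ARE with ARE from the ensemble mean (member-wise
chains propagate uncertainty), and mass conservation
emission = ΣAR + AS holds to float round-off by construction.

The influent concentration a wetland sees is c = AI / V with
V = HLR × area × 1 yr and a default hydraulic loading rate of 0.5 m/d.
This dimensional throughput model is isolated in `regional.concentration`
so a site-specific model can replace it; HLR is configurable.  Risk uses
the cask-effect quotient RQ = c_surp / (n × PNEC_min) with
c_surp = c × (1 − ARE), n the number of emitted antibiotic types and
PNEC_min the inventory minimum (default 3 ng/L).  Bands: high RQ > 1
(strict), medium (0.1, 1], low (0.01, 0.1], no-risk below — the sub-unity
cut points follow conventional risk-quotient banding.

Because the risk quotient is defined per wetland *type* at county scale,
the county high-risk flag and the HRA aggregate each wetland class within a
county (surplus mass over aggregate treated volume) rather than reacting to
any single unit; per-wetland quotients are still emitted as diagnostics.
Reservoirs count as natural-class for the HRA by default (configurable).
There is no hydrological routing between counties and no within-year
dynamics: the balance is an annual steady state.

## Scenarios

The grid crosses management {NM, IM}, restoration {WR1 none; WR2 +180
km²/yr distributed in proportion to existing county wetland area; WR3 the
same national rate split equally among currently high-risk counties,
re-targeted every simulated year, falling back to the WR2 distribution when
none exist} and abatement {20, 40, 60%} — 18 combinations.  Abatement is
phased in by farm participation: 0 in 2020, +10 points/yr to 50% in 2025,
then +5 points/yr to 100% in 2035, applied uniformly across counties
(participation is not spatialized).  New restored area is natural-class and
carries county-median feature attributes.

Each projected year applies expansion, computes effective emissions,
re-allocates, re-predicts ARE and re-scores the HRA.  The point series uses
the ensemble mean; the 95% band reruns the full chain with a seeded
subsample of bootstrap members (default 12) and takes per-year 2.5/97.5
percentiles, widened where necessary to bracket the point series (a
percentile band over members need not contain the mean-chain value).
Because tree ensembles are not perfectly monotone in concentration,
counties sitting at the RQ = 1 boundary can flicker between years; HRA
trajectories are therefore monotone in trend but not guaranteed monotone
year-over-year.

The contribution analysis is control-variable: for each non-reference
measure level (IM; WR2, WR3; 40%, 60%), efficiency is the mean over all
scenario pairs identical in the other two factors and over all 15 years of
(HRA_ref − HRA_level)/HRA_ref, with references NM, WR1 and 20% and zero-HRA
reference years skipped.  Per-family means are reported alongside the
levels.

## Interpretation

Tree models (XGBoost, scikit-learn trees/forests) get exact path-dependent
TreeSHAP attributions from an in-house float64 engine; conditional
expectations follow training cover, the base value is the cover-weighted
mean output, and local accuracy (Σφ + base = prediction) holds to float64
round-off against the engine's own traversal of the same trees.  (XGBoost's
float32 accumulation differs from any float64 sum at ~1e−5; the test suite
cross-checks the engine against both a brute-force coalition-enumeration
oracle and XGBoost's native per-feature contributions.)  Non-tree models get
permutation-sampling Shapley estimates — 64 seeded (permutation, background)
pairs shared across rows, feature groups inserted as units — which satisfy
local accuracy exactly by telescoping.  One-hot blocks are folded back onto
their categorical feature by summing attributions; category shares aggregate
mean |attribution| over the four mechanistic feature groups and sum to 100%.
A grouped permutation-importance ranking (mean held-out R² drop) is the
model-agnostic cross-check, summarized by Spearman agreement with the
attribution ranking.  Outputs are tables, not figures.

## Synthetic data: what it emulates, and what it does not

The trial generator draws features by Gaussian copula over documented
ranges: only nutrient chemistry (NH₄⁺-N, COD, TN) and hydraulics (HRT vs
HLR) are correlated; seven numeric features carry no signal at all, serving
as importance-analysis controls.  The response surface encodes the
qualitative dose–response shapes reported for treatment wetlands —
efficiency falling ~17 points per decade of influent concentration, planting
density saturating above 100 plants/m², pH optimal in 7.2–8, temperature in
25–30 °C, nutrient supply and tetracycline fraction helping, substrate
modification and hybrid/subsurface construction adding offsets — plus
N(0, 8) noise, clipped to [0, 100].  Effect scales were calibrated once, at
design time, so that the explainable variance at n = 337 puts a competent
tabular learner near held-out R² 0.8, the regime the compiled literature
data supports; they were not adjusted afterwards.  Model-regime checks run
on the complete-data fixture; the 10%-MCAR path is validated separately,
because imputed values of weakly correlated features are irreducible feature
noise that would otherwise dominate the regime check.

The synthetic region is an *abstraction*, not a map: counties have areas,
log-normal heavy-tailed emissions weakly coupled (copula ρ = 0.1) to their
wetland endowment — emulating the observed disconnect between restoration
hotspots and emission source zones — and 0–12 wetlands with class labels and
trial-schema attributes.  Emission medians, wetland areas and the default
HLR were chosen together so surplus concentrations land in the
hundreds-of-ng/L range reported for surface waters, putting a meaningful
fraction of counties near the RQ = 1 boundary.  Two consequences limit
external readings: (i) with ~3,000 km² of synthetic wetland stock, the fixed
180 km²/yr restoration rate is proportionally far larger than in a national
inventory, so restoration measures look much stronger here than the weak
contribution a country-scale study finds; (ii) absolute removal masses,
HRA values and contribution percentages are properties of the synthetic
scale, not of any real region.  What passing tests *do* show is the
mechanics: mass conservation, multistage dominance, cask-effect arithmetic,
ramp and expansion bookkeeping, attribution exactness, and the direction of
every policy ordering.

## Numerical conventions and limitations

* One global seed fans out to fixed per-stage streams (`seed`, stage-index
  pairs through NumPy's seed-sequence spawning); identical configs give
  byte-identical summaries.
* Ties: model selection breaks R² ties by RMSE; risk bands use strict
  inequalities at cut points (RQ = 1.0 is medium).
* XGBoost thresholds are compared in float32 inside the attribution engine,
  mirroring the booster, so ties at training values resolve identically.
* Degenerate inputs (no wetlands, zero-variance features, unseen levels,
  empty candidate lists, out-of-range fractions) raise or warn explicitly;
  nothing is silently coerced.
* Known limitations: single-table imputation understates imputation
  variance; the concentration model is a dimensional stand-in; scenario
  uncertainty reflects model-parameter uncertainty only (not generator or
  policy-timing uncertainty); KNN/SVR families underperform on this data and
  exist mainly to make the tournament meaningful.
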