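# Methods

## Data model

The unit of observation is a summary-level flow-cytometry readout: the
percentage of basophils positive for an activation marker (CD63, or high
CD203c) after stimulating a whole-blood aliquot with one allergen
concentration. One *series* is the activation-vs-concentration vector for
one subject × allergen (Pru p 3 or Ara h 9) × marker, plus an unstimulated
background well. Concentrations are µg/mL; the default grid is the seven
ten-fold steps 1e-7 … 1e-1 µg/mL. Event-level cytometry (FCS files,
gating) is outside the data model by design.

## Dose–response model

Activation is modelled as a four-parameter log-logistic in log10
concentration:

    f(c) = b + E / (1 + 10^(h·(m − log10 c)))

with baseline `b` ≥ 0 and span `E` ≥ 0 in percent (`b + E` ≤ 100), log10
EC50 `m`, and Hill slope `h` > 0. Fitting is bounded least squares
(`scipy.optimize.least_squares`, analytic Jacobian) on the reparametrised
box `(b, s, m, h)` with `E = s·(100 − b)`, `s ∈ [0, 1]`, which makes the
joint constraint exact. Slope is restricted to [0.3, 5]; `m` to within one
decade of the measured concentration range. Because plateau-heavy series
have EC50 local minima, the optimiser is multistarted with one `m` start
per measured concentration and the best cost kept. An all-identical series
short-circuits to an exact flat fit (`E = 0`). Noise-free synthetic curves
are recovered to ≈1e-7 in every parameter; the tested contract is 1e-3.

### Nonresponders

A series is a *responder* when its peak activation reaches `min_peak`
(default 5%) **and** at least `fold` (default 2×) the background (background
floored at 0.5% so a near-zero well cannot make the fold test vacuous). The
thresholds are configurable because the underlying clinical criterion is
usually not reported. For nonresponders the baseline estimate is kept and
all other parameters are undefined (NaN): a half-maximal concentration does
not exist on a flat curve. Downstream, this propagates as: CD-sens
undefined (raising `UndefinedValueError` when requested directly), PCA rows
dropped and counted, while curve AUC and single-concentration reactivity
remain available for every subject.

## CD-sens

CD-sens = `100 / C50` with C50 in µg/mL. C50 is taken from the fitted
curve (`10^m̂`), not from log-linear interpolation between measured points,
because the fitted value is markedly more stable under counting noise; the
interpolation variant exists behind a flag for sensitivity analysis. The
magnitude of CD-sens depends entirely on the µg/mL convention — values are
comparable only between analyses using the same unit.

## Curve AUC

Trapezoidal integral of background-subtracted activation (floored at 0)
over the log10-concentration axis, in percent·log10-units. Raw-percentage
and linear-axis switches exist; defaults are background-subtracted and
logarithmic. No normalisation is applied, so values are comparable within
a run only. AUC needs no fit and is defined for all subjects.

## Discriminating concentrations

Concentrations are ranked by the control-vs-allergic two-sample rank
statistic (Mann–Whitney U scaled to [0, 1]) of activation at that
concentration; ties break toward the higher concentration; the top *k*
(default 3) are returned ascending. On cohorts whose curves plateau above
1e-3 µg/mL this selects {1e-3, 1e-2, 1e-1} µg/mL.

## ROC cut-offs and the positivity rule

Empirical ROC curves are built over midpoint thresholds between consecutive
distinct pooled values plus sentinels; sensitivity = fraction of allergic
values strictly above the threshold, specificity = fraction of controls at
or below it. AUC is computed in the Mann–Whitney form (ties weighted ½)
and equals the trapezoidal area under that curve (tested to 1e-12). The
working point maximises the Youden index J = sens + spec − 100, with ties
broken toward larger specificity then larger threshold; a max-accuracy
criterion is pluggable. J = 0 flags the cut-off as uninformative. PPV/NPV
are computed from the confusion counts at the observed cohort composition,
i.e. they inherit the case–control mix and are not population predictive
values.

A subject is BAT-positive for a marker when activation exceeds the
per-concentration cut-off (strictly — "higher than") at **two or more
consecutive** concentrations. By default the rule is evaluated over the
selected discriminating concentrations in ascending order; a switch
evaluates all seven. Positivity is computed per marker. A published set of
reference cut-offs (12.35 / 5.87 / 6.605 %CD63⁺ and 9.96 / 17.25 / 9.655
%CD203c^high at 0.1 / 0.01 / 0.001 µg/mL) ships as a named constant so the
classifier can be applied to new data without re-deriving thresholds; the
PPV/NPV printed alongside them in the source publication are reference
values only and are not recomputable from the entries.

## Statistical battery

Two independent groups: unpaired t when every group passes Shapiro–Wilk at
α = 0.05, else Mann–Whitney (exact small-sample method when feasible).
Three or more: one-way ANOVA with Bonferroni-adjusted pairwise t tests
(`p_adj = min(1, m·p)` exactly), or Kruskal–Wallis with Dunn's rank-based
post hoc (z from rank-mean differences with tie correction,
Bonferroni-style adjustment over all pairs). Dunn's test is implemented
in-package because no installed library provides it. Paired within-subject
contrasts (Pru p 3 vs Ara h 9) use the Wilcoxon signed-rank test. The
dispatch rule is explicit (`scale="auto" | "parametric" | "nonparametric"`)
and the chosen family is recorded in each result. The nonparametric
omnibus holds its nominal size: 3.9–5.7% rejections at α = 0.05 over 1000
seeded three-group null simulations (n = 15/group), within the tested
[3.5%, 6.5%] band.

Summary-table percentages are exact rationals rounded half-up to two
decimals and always stored with numerator and denominator; an audit method
recomputes every stored percentage from its own counts.

OFC (oral food challenge) dose arithmetic is plain volume × concentration
with a running sum; the dose concentration is an explicit argument
(6.2 mg/mL reproduces the 31 mg starting and 1550 mg cumulative doses of a
250 mL peach-juice schedule) because published schedules are sometimes
ambiguous about total-mass vs per-mL quantification.

## PCA

Economy SVD of the centered, by default unit-variance-scaled, feature
matrix; explained variance from the squared singular values; component
signs fixed by making each component's largest-magnitude loading positive,
so results are bit-reproducible. Rows with undefined entries (typically
CD-sens of nonresponders) are dropped and counted. Specific IgE enters the
pipeline's feature table as log10(x + 0.01) — serum IgE is heavily
right-skewed and would otherwise dominate the first component; the
transform is a documented switch, not hard-wired into `run_pca`. A
constant feature under unit-variance scaling is an error naming the
feature.

## Synthetic-cohort generator

The generator emulates the *structure* of an LTP-allergy case–control
study, not any particular patients:

- **Design**: 16 controls; 92 allergic split 23/44/25 into oral allergy
  syndrome / urticaria-angioedema / anaphylaxis; 55 peanut-tolerant
  (Group A) vs 37 peanut-allergic (Group B), assigned at random across
  severity groups. All counts are configurable.
- **Latent curves**: allergic subjects draw (b, E, m, h) from per-severity
  blocks (Emax ≈ 45–55 ± 12%, log10 EC50 ≈ −4.0 to −4.4 ± 0.6, Hill
  1.2 ± 0.3, baseline ≈ 1%); controls draw near-flat curves (Emax ≤ 3%).
  Allergic Emax is truncated to [20, 85]%: the generator emulates an
  *analysed* cohort from which any outright BAT nonresponder has already
  been excluded, so allergic subjects are responders by construction and
  the nonresponder rule is exercised on constructed series in tests.
- **Reactivity–sensitivity coupling**: a shared per-subject factor loads
  (weight 0.8) on Emax and on −log10 EC50, so subjects with larger maximal
  responses also respond at lower doses. This reproduces the strong
  positive CD-sens vs curve-AUC rank correlations (r > 0.7) characteristic
  of allergic cohorts; independent draws would cap the correlation near
  0.6 because Emax noise dilutes it.
- **Ara h 9 vs Pru p 3**: Group B subjects get an Ara h 9 Emax comparable
  to their Pru p 3 one (×0.85–1.05); Group A a strictly attenuated one
  (×0.25–0.5). The attenuation applies to CD63; whether it also applies to
  CD203c is a switch, default off, matching the readout asymmetry the
  generator emulates.
- **Noise**: each well's observed percent is a binomial draw over
  `n_events_per_well` basophil events (default 500) at the latent success
  probability — the minimal counting-noise mechanism consistent with
  flow-cytometry percentages. SD at latent p is 100·√(p(1−p)/N), verified
  by simulation. A noise-free switch returns the latent curve exactly.
  Background defaults to 1% (unstimulated wells are rarely reported; this
  is a free choice).
- **Serology/SPT**: lognormal draws calibrated to the order of magnitude
  of published LTP-cohort tables (allergic sIgE Pru p 3 median ≈ 4–9 kU/L
  vs ≈ 0.01 in controls; controls are clamped below the 0.35 kU/L assay
  threshold and below 7 mm² SPT wheal area by construction). Profilin
  co-sensitization probability decreases with severity (0.3044 / 0.1591 /
  0.04), mirroring the protective association reported for profilin.
- **Determinism**: one `numpy` Generator seeded from the single top-level
  seed drives every draw in a fixed order; identical config + seed gives
  bit-identical tables and pipeline outputs.

What the generator does **not** emulate: event-level cytometry and gating
noise, plate/batch effects, inter-assay drift, nonresponder subjects,
missing wells, and any correlation between serology and BAT reactivity
beyond group membership. Passing tests therefore demonstrate correctness
of the *analysis machinery* under the stated noise model, not clinical
performance on real cohorts; in particular the default cohort is cleanly
separable (ROC AUC 1.0 at the discriminating concentrations), which is the
regime the most favourable published marker × concentration combinations
reach, while real data also show partially overlapping rows.

## Problem sizes and numerical choices

Unit tests run a reduced cohort (8 controls + 15 allergic) so the full
suite fits comfortably in an interactive budget; the acceptance script
runs the full 108-subject design (432 curve fits), 50-responder CD-sens
recovery at 500 events/well, 200 + 100 + 252 oracle-equivalence instances,
and 1000 null simulations. Optimiser tolerances are 1e-12 (xtol/ftol/gtol)
with at most 400 residual evaluations per start. Float comparisons in the
oracle-equivalence tests use 1e-12 absolute; exact-recovery contracts use
1e-3.

## Known limitations

- CD-sens units are tied to the µg/mL convention; cross-study comparisons
  need unit harmonisation.
- Curve AUC is unnormalised and therefore run-internal.
- PPV/NPV reflect case–control composition, not population prevalence.
- Dunn's post hoc uses the normal approximation; very small groups (< ~5)
  deserve exact methods the package does not provide.
- The ROC cut-off is a point estimate; no confidence intervals (e.g.
  DeLong) are computed.
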