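# Methods

## The model

Equity in access to pharmaceutical services is summarised by a grouped
concentration index. Each surveyed person contributes (a) an access
score from a nine-level ordered table (100, 90, 80, 70, 60, 50, 30, 10,
1, best to worst) and (b) a composite socioeconomic-status (SES) score.
The population is partitioned into ordered SES groups, poorest first;
with `P_t` the cumulative population share and `L_t` the cumulative
access share through group *t*,

    C = sum_{t=1}^{T-1} (P_t L_{t+1} - P_{t+1} L_t),

which equals `1 - 2 * AUC` for the polyline through (0,0) and the
(P_t, L_t) points. The origin point is prepended implicitly: the
summation formula only matches the area identity if the curve starts at
(0,0), so both computations include it. Sign convention: pro-rich
concentration gives C > 0.

The composite SES score is a simple-additive-weighting (SAW) sum of
five tabulated indicator scores — income (1–7, banded in city-poverty-
line multiples), occupation rank (1/3/6), education (1/4/7), home
status (1–10) and family size (8/5/3/1) — with impact weights 30, 27,
20, 13, 10 (percent). The elicitation also produced raw SAW weights
4.5, 4.0, 3, 2.0, 1.5; these are proportional to the impact
percentages (4.5/15 = 30%) and are kept only as metadata
(`RAW_SAW_WEIGHTS`): the impact percentages are the multiplicative
weights, because only that choice reproduces both the published scale
minimum of 100 and the published worked example of 516.

Home status merges owners and tenants on one 1–10 scale. Owners:
surface band score (1–5) times price-quintile score (1, 3, 5, 7, 9)
gives a product in 1–45; product ranges 1–5, 6–15, 16–29, 30–39, 40–45
define owner groups scoring 4, 5, 7, 9, 10. Tenants: rent bands in
national-minimum-wage multiples (< 1/3, [1/3, 1), [1, 2), [2, 5],
> 5) score 1, 2, 3, 6, 8.

## Interval conventions and documented table defects

All inequality symbols in the source tables are honoured literally:
income bands are upper-inclusive (`1/2 CPL < income <= CPL`), tenant
band 4 is upper-inclusive (`2 NMW <= rent <= 5 NMW`) while band 5 is
strict (`> 5 NMW`). Two defects in the published tables are handled as
documented decisions rather than silently repaired:

- The last income row reads "C.P.L. < Income" directly after a row
  ending at 5·CPL; it is read as income > 5·CPL (a typographic omission
  of the leading 5), since any other reading overlaps earlier bands.
- The published composite ceiling is 720, but the table maxima
  (7, 6, 7, 10, 8) give 30·7 + 27·6 + 20·7 + 13·10 + 10·8 = 722. The
  top class band is therefore open above (>= 597, no cap) and 722 is
  the true attainable maximum; the tests assert this discrepancy
  explicitly instead of enforcing 720.
- The occupation table's printed column layout is garbled; the mapping
  used is the caption's evident intent: high → 6, average → 3, low → 1.
- The income table's four group labels span seven score rows with
  ambiguous alignment; only the numeric scores are used.

Class bands (100–224, 225–348, 349–472, 473–596, ≥ 597) are calibrated
to the default weights. Weight overrides are accepted — they need not
sum to 100, a warning is logged — but then the composite scale and the
class bands lose their published meaning, and classification rejects
composites below 100.

## Aggregation choices

**Access mass (score vs count).** The source defines the Y-axis as the
"cumulative frequency percentage of access" without saying whether a
person contributes their access score or a binary availability. The
default sums access scores per group (score mass), which uses the full
ordinal-treated-as-interval information in the table. A count mode is
provided for sensitivity analysis: a person contributes 1 unless their
status is `not_available` (the only status under which the medicine was
not obtained at all). Whether the 100…1 scores are a true interval
scale is unknowable from the tables; treating them as such is stated
here as an assumption, and the count mode is the check on it.

**Grouping.** The default groups are the five published SES classes.
A quantile mode splits on the numeric composite into K near-equal
groups after a stable sort on (composite, input row order), so ties at
a boundary land deterministically in the lower (poorer) group. Groups
with zero population are dropped (logged) — a zero-width step
contributes nothing to either cumulative share.

## Numerical choices

- Both cumulatives are computed cumsum-then-divide, so an access
  distribution exactly proportional to population yields bit-identical
  P and L and the index cancels to exactly 0.0 in floating point.
- The index is cross-checked against an independent implementation of
  the area identity (`1 − 2·trapezoid AUC` via `numpy.trapezoid`); the
  two agree to < 1e−10 over 1,000 random grouped distributions in the
  tests.
- With T groups the grouped index cannot reach ±1: five equal quintiles
  with all access in one extreme quintile give C = ∓0.8. The published
  ±1 extremes hold only as the extreme group's population share
  vanishes; the package reports the grouped value as is.
- A single group returns C = 0 (the curve is the diagonal chord).
- Monetary inputs are unit-agnostic — everything enters as a ratio to
  the CPL or NMW — and are parsed with a "." decimal separator only.

## Price quintiles for owners

The price-per-m² score requires the home's local price quintile, for
which no universal breakpoints exist. Owners may supply a precomputed
`price_quintile` (1–5); otherwise a config-supplied breakpoint vector
(4 ascending numbers) is applied to an optional `price_per_m2` column;
otherwise quintile breaks are estimated empirically from the owner
records in the input file (logged). An owner row with none of these is
rejected with a line-numbered diagnostic.

## Synthetic populations

The generator emulates a middle-income-country household survey purely
for testing; it is not calibrated to any real population. Defaults,
chosen once as plausible survey marginals:

- income: lognormal in CPL multiples, median 1.5·CPL, sigma 0.8 (log
  scale) — most households between the poverty line and a few multiples
  of it, a long right tail;
- tenure: 60% owners; owner surface uniform over the five tabulated
  bands (20–600 m²) with a uniform price quintile; tenant rent
  lognormal in NMW multiples (median 1·NMW, sigma 1.0), spanning all
  five tenant bands;
- occupation (high/average/low): 0.15/0.35/0.50; education
  (under-diploma/diploma–bachelor/master+): 0.50/0.40/0.10; household
  size 1–7 with probabilities 0.06/0.16/0.22/0.28/0.15/0.08/0.05;
- anchors CPL = 10, NMW = 8 in arbitrary currency units (only ratios
  matter).

Access is drawn per person from a logistic tilt over the nine levels:
with u the person's composite-SES percentile and z_k a linear grid from
+1 (best level) to −1 (worst), level k has probability proportional to
`exp(gradient · (u − 1/2) · z_k)`. This mechanism keeps every level
possible at every gradient, makes gradient = 0 exactly exchangeable
(everyone draws from the same uniform distribution, so C is
null-distributed around zero), and concentrates good access among the
wealthy for positive gradients. One root seed spawns independent
substreams per component (income, occupation, education, tenure, home,
rent, family, access), so adding a component never perturbs earlier
draws and identical configs reproduce records byte for byte.

What passing tests on these populations do and do not show: they
demonstrate that the pipeline recovers a designed SES→access gradient
with the right sign and monotone strength, and stays inside an
empirical null band when no association exists. They do not validate
the scoring tables against any real survey — real data have correlated
indicators (income, occupation and education are far from independent),
item nonresponse, and access patterns driven by geography and insurance
that the generator does not model.

## Problem sizes

The test suite uses populations of 200–5,000; the null band is
estimated from 200 replicates of n = 5,000 and gradient monotonicity
from 50 replicates per gradient at n = 5,000. These sizes give a null
band of roughly ±0.01 on C, small against the gradient effects tested
(≈ 0.05–0.13), while keeping the whole suite under a couple of minutes
on one CPU.

## Known limitations

- No inference on C: no standard errors, confidence intervals,
  dominance tests, or Erreygers/Wagstaff normalisations.
- The expert-elicited weights and scores are taken as given; the
  package does not re-run the elicitation, impute missing SES
  attributes, or convert currencies.
- Classification bands are meaningless under non-default weights (a
  prominent warning, not an error).
- Free-text occupation titles are out of scope; the scorer accepts only
  the three ranks (a user-side lookup can map titles to ranks).
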