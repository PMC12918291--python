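# Methods

## Problem setting

Federated health-data networks (biobank locators, distributed research
infrastructures) need to advertise the *quality* of each node's dataset —
how complete, consistent, valid, timely and de-duplicated it is — without
the node ever disclosing patient-level data. Even an aggregate quality
metric can leak: "1 patient has a prostate-cancer diagnosis with female
gender" is close to an identification in a small cohort. `dpqc` computes
quality metrics locally and discloses them only after Laplace-mechanism
perturbation, with the total privacy loss of a report explicitly accounted
and capped.

## The disclosure model

A quality check is a counting query `f(D)` over the node's dataset `D`
(e.g. "number of patient records without a gender"). The released value is

    f'(D) = f(D) + Lap(Δf / ε)

which satisfies pure ε-differential privacy (δ = 0 throughout). All built-in
checks are patient-level, so the sensitivity is Δf = 1; for specimen-level
queries `checks.sample_sensitivity` computes Δf as the maximum number of
specimens any one patient contributes.

Percentages are released as `(c̃/ñ)·100` with independent Laplace draws on
numerator and denominator. The check's budget ε is split evenly between the
two draws (each at scale `Δf/(ε/2)`) — a conservative, self-contained
accounting, since the composition of the two halves is exactly ε. Setting
`noise_denominator=False` spends the full ε on the numerator and leaves the
denominator exact; this reproduces the textbook ratio-noise law
`SD[q̃] = √2/(nε)` and is the variant the closed-form forecasts describe.

Released values are clamped (counts to ≥ 0; the denominator to ≥ 1 and the
numerator to `[0, ñ]`, so percentages stay in `[0, 100]`) and rounded to two
decimals. Both operations are post-processing of the noised value — the raw
statistic is never touched — so the ε-guarantee is preserved.

A report composes sequentially: per-report privacy loss is the exact sum of
per-check charges, tracked by a `BudgetLedger` against a hard cap
(default 2.0, per-check default ε = 0.2, stratified check 0.3). The ledger
is fail-closed: a check whose charge would exceed the cap is refused
atomically *before* it runs, and appears in the report as an error entry
with no disclosed value. Stratified checks charge their ε once; the k-way
split `ε_i = ε_total/k` is internal to the mechanism, which inflates
per-stratum noise variance to `2(Δf·k/ε_total)²` — quadratic in k, the
price of granularity.

Correlation-exploiting or advanced composition is deliberately out of
scope: the conservative sequential bound is always used.

## The check battery

Nine built-in checks cover six quality dimensions (accuracy, completeness,
consistency, timeliness, validity, uniqueness). Decisions that the check
descriptions alone do not fix:

- **Missing vs unsupported gender.** Absent element or empty string counts
  as *missing* (completeness); a present, non-empty token outside the FHIR
  AdministrativeGender set {male, female, other, unknown} counts as
  *unsupported* (consistency). The two numerators are disjoint.
- **Duplicates.** Numerator = total records − distinct ids (surplus
  records); denominator = total records. This is order-free and
  unambiguous.
- **ICD-10 validity** is structural by default — the pattern
  `^[A-TV-Z][0-9][0-9A-B](\.[0-9A-TV-Z]{1,4})?$` — because demo data tends
  to fabricate codes from loose regexes rather than a terminology; a
  user-supplied code list switches the check to terminology membership. The
  denominator is patients: a patient fails if at least one linked code is
  invalid.
- **Sex-incompatible diagnosis.** Default exclusion table: C60–C63
  male-only, C51–C58 female-only, category-level prefix match,
  configurable.
- **Timeliness.** Stale means `meta.lastUpdated` more than 365 days before
  the reference date; records with no update timestamp count as stale (the
  worse reading of missing provenance).
- **Birth-date anomaly:** before 1900-01-01 or after the reference date;
  a missing birth date is not an anomaly (that is a completeness matter).
- **Survival** (stratified by recorded gender, female/male): percentage of
  stratum records whose deceased flag is not true. An empty stratum raises
  an "insufficient population" error — explicitly distinct from 0%.
- The reference date is always an explicit input, never the wall clock, so
  time-relative checks are reproducible.
- Legacy spellings ("completness-1", "uniqness-1") are accepted as aliases
  of the canonical ids, so externally produced configs and reports match.

Statuses use warning/error thresholds (defaults 10% / 30%) and are computed
on the *DP* values — the only quantity a public consumer can recompute.

## Risk and utility forecasting

`privacy.ratio_sd(n, ε) = √2/(nε)` forecasts the noise in a released ratio;
at n = 10, ε = 1 it is ≈ 0.141 — large enough to make the release useless,
which motivates the minimum-cohort release gate (inclusive, default
n ≥ 30). Below the gate `build_report` refuses to release and advises
aggregating across sites or reporting periods instead of weakening ε.

For disclosure risk we use the single-query Bayes bound: an adversary with
prior inclusion certainty `P_in` about a specific record can update it
after one ε-DP release by at most the likelihood ratio e^ε:

    P_out = e^ε·P_in / (e^ε·P_in + 1 − P_in)

so a 0.1 prior becomes ≈ 0.45 after one ε = 2 query. The complementary
e^(−ε) update gives the lower band; `certainty_band` and
`plot_certainty_band` visualise both over a grid of priors. Only the
one-query bound is implemented; a composed-update band and the 95% interval
on released ratios are documented limitations, not implemented, because
their constructions are not fixed by the formulas above.

## The synthetic cohort generator

`cohort.generate_cohort` emulates demo-data generators that purposefully
inject quality errors. Each error class has a profile rate; defaults
describe a 1,000-record general cohort with, e.g., 3.7% missing gender,
9.6% unsupported gender tokens, 20% of patients without conditions and
9.7% duplicated records, with 10,000 specimens spread multinomially over
patients (so one patient can contribute many samples — the Δf > 1
scenario).

Injection semantics worth knowing:

- Record-level classes (gender state, birth-date anomaly, staleness,
  deceased) are independent per record; missing and unsupported gender are
  drawn from one categorical so they stay disjoint.
- Condition-linked classes are drawn per unique id, because conditions
  resolve by id and duplicate records share them. The invalid-code rate is
  *conditional on having conditions* — the unconditional default (96.9%)
  would be impossible alongside 20% of patients having no conditions at
  all. `expected_rates` folds the conditioning in (expected observed
  validity rate 0.969·0.8 = 77.5%) and is the oracle the recovery tests
  use.
- Duplicates are freshly drawn records reusing an existing id,
  `ceil(rate·n)` of them appended after the base population.
- Anomalous birth dates are split 50/50 between pre-1900 and
  after-reference-date; stale records sit 400 days before the reference
  date, fresh ones 30.
- One seeded NumPy generator, drawn in a fixed class-by-class order, makes
  a spec byte-reproducible.
- `exact_counts=True` replaces Bernoulli draws with uniformly random
  subsets of exactly `round(rate·total)` records. `reference_cohort_spec()`
  uses it to build a *synthetic stand-in* for the published demo dataset:
  903 base records + 97 duplicates = 1,000 records reproducing the
  headline prevalences digit-for-digit.

What the generator does **not** emulate: clinically coherent longitudinal
trajectories, realistic condition co-occurrence, non-uniform specimen
allocation, or correlated error classes. Passing tests therefore show that
the pipeline recovers *injected, independent* defect rates — not that the
checks capture every failure mode of real clinical data.

## Federation simulation

Each node's agent writes a public JSON report (DP values, statuses, ε
accounting; timestamps truncated to the day) and optionally a local one
(raw counts, raw percentages, noise seed — never transmitted). The
server-side aggregation reads *only* public files — a schema guard rejects
any file containing raw-value keys — and builds a per-check cross-node
table in which a node missing a check is absent (NaN), never zero.
Transport is the filesystem; no network protocol is simulated.

## Numerical choices

- Laplace sampling by inverse CDF of one uniform draw,
  `x = −b·sgn(u)·ln(1−2|u|)` with `log1p` for accuracy, for cross-platform
  reproducibility.
- Stratum budget shares are forced to sum exactly to ε_total (last share
  takes the remainder).
- Ledger sums use `math.fsum`; cap comparisons allow 1e-9 absolute slack so
  charging exactly to the cap never fails on float dust.
- Low-count suppression (strict `raw numerator < threshold` → release 0,
  flagged) is available but disabled by default (threshold 0); 10 is the
  suggested value.
- Status boundaries are inclusive on the lower side (dp ≤ warn → ok).

## Problem sizes used in validation

The test suite validates the sampler and the variance laws by Monte Carlo
with 10⁵ draws (moments), 6·10⁴ draws per neighbouring count (empirical
ε-DP histogram ratio), and 8–10·10³ replicates (stratified variance and
ratio-SD agreement, tolerances 5–20%); parameter recovery uses one
1,000-patient cohort per profile at 3-binomial-SE tolerance. These sizes
put Monte-Carlo error comfortably inside the stated tolerances while the
whole suite runs in seconds.
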