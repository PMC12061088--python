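# Methods

This note records the models, conventions and design choices behind
`mmepi`, in the spirit of the methods documentation of simulation and
statistics packages: what is computed, under which assumptions, and what
the synthetic experiments do and do not establish.

## 1. The identification rules and their reading of the clauses

Both algorithms operate on validated event tables (`mmepi.claims`) with
day-resolution dates, ICD-10 codes stored without dots, and all intervals
half-open `[start, end)` unless a rule's wording forces inclusivity.

**MYLORD** (default identification period 2006-01-01 – 2020-12-31):

* *Arm 1 (`hosp_or_ltd_treated`)*: (≥1 stay with PD/RD/SAD matching
  `C90*` **or** ≥1 LTD registration `C90*`) **and** ≥1 MM treatment date
  (MM-specific drug or chemotherapy dispensing, or ASCT), all inside the
  identification period. The "and/or" between stay and LTD is an
  inclusive or; the treatment clause binds to the whole stay/LTD
  disjunction. Treatment need not postdate the stay/LTD — the rule
  imposes no ordering.
* *Arm 2 (`oral_imid_monitored`)*: the same drug (both dispensings
  lenalidomide, or both thalidomide) on two **distinct** dates with
  difference ≤ 90 days inclusive (a same-day double dispensing does not
  count — the clause proxies treatment continuation); ≥2 SPEP/UPEP events
  (any mix) in the closed window `[d, d+120]` days, where `d` is the first
  in-period dispensing of that drug; and no stay anywhere in the database
  history carrying an exclusion diagnosis. Both dispensings must fall
  inside the identification period. "4 months" is implemented as a fixed
  120-day window to avoid calendar-month ambiguity; the window length is a
  configuration field (`monitoring_window_days`), so the alternative
  reading "within the first year after dispensing" is available as
  `monitoring_window_days=365` without being endorsed. The
  exclusion-diagnosis lookup spans the full history by default
  (`exclusion_whole_history=False` restricts it to the identification
  period).
* Age: ≥18 in the year of the first qualifying evidence
  (age = analysis year − birth year, the finest demographic the schema
  carries).
* First MM information = earliest date among the *satisfied* clauses; a
  stay and an LTD registration tied on the same first day are reported
  under a combined `stay_and_ltd` kind; other ties resolve
  stay > LTD > treatment > oral.

**PALMARO**: `C90*` stay or LTD in 2014–2020, age **>** 18 (implemented
strictly, as printed, versus MYLORD's ≥18), no treatment requirement.
Variants: `from_2006` moves the window start; `treated_only` adds the
MYLORD treatment list. When both algorithms use their defaults,
PALMARO(treated) ⊆ MYLORD: the treated variant's clauses are a
restriction of arm 1 over a sub-window with a stricter age cut.

## 2. Follow-up conventions

* **Index date**: first in-study (2014–2020) treatment date; 2014-01-01
  when treatment precedes the study; the oral arm's qualifying first
  dispensing counts as treatment. Untreated members of the base PALMARO
  cohort have no treatment-defined index; the package anchors their index
  at the first in-study MM information date (a documented extension — the
  source design defines the index only through treatment).
* **Incidence**: washout of 730 fixed days before the first in-study MM
  information date, scanned over the full history (from 2006); the
  information set is stays ∪ LTD ∪ treatments ∪ the oral qualifying date
  for treatment-based cohorts, stays ∪ LTD for the treatment-agnostic
  PALMARO variants (whose inclusion never looks at drugs). A lookback
  that would extend before the available history cannot establish
  incidence. Each member is incident at most once.
* **Censoring**: follow-up ends at min(death, study end, gap date). The
  gap date is the last reimbursed event (stays, dispensings, procedures
  and other reimbursements all count; the follow-up start acts as the
  initial anchor) followed by **more than** 730 days with no
  reimbursement while the person is under observation — so an exact
  730-day silence does not censor, and the member contributes nothing
  after the event that opens the gap. Ties resolve
  death > study_end > gap. Deaths occurring after gap censoring are not
  counted in mortality (the member has left observation); a
  configuration flag could relax this but the shipped pipeline does not.
* **Prevalence**: under follow-up on January 1 of the year
  (`followup_start ≤ Jan 1 ≤ followup_end`), alive (a death dated
  January 1 itself still counts as alive that day) and affiliated on
  January 1. With this convention the bookkeeping identity
  `prevalent(Y+1) = prevalent(Y) + newly_included_alive(Y) −
  deaths_among_prevalent(Y)` holds exactly on a closed population (full
  affiliation, no gap censoring), and the test suite asserts it year by
  year.

## 3. Rates and standardization

Denominators are point-in-time headcounts of persons alive and affiliated
on January 1 of each year, stratified by age group × sex; rates are
labelled per 100,000 person-years with this approximation documented
(exact person-day denominators are out of scope). Ages are binned on
January 1 for prevalence and mortality and in the incidence year for
incidence.

Direct standardization uses the Segi world standard in eighteen 5-year
groups (0–4 … 85+), weights summing to 1, replaceable via
`StandardPopulation.from_csv`. Counts are treated as Poisson. The default
confidence interval is the Fay–Feuer gamma interval: with
`μ = Σ wᵢxᵢ/nᵢ` and `v = Σ wᵢ²xᵢ/nᵢ²`,

* lower bound: the α/2 quantile of Gamma(μ²/v, v/μ);
* upper bound: the 1−α/2 quantile of Gamma((μ+w_M)²/(v+w_M²),
  (v+w_M²)/(μ+w_M)) with `w_M = maxᵢ wᵢ/nᵢ`.

A normal approximation (`μ ± z√v`) is available; for large per-stratum
counts the two agree closely (asserted within 5% relative width at
≥100 events per stratum). Sex-stratified rates apply the same age
standard within each sex; whether a sex-specific world standard should be
used instead is an open question in the source material, and the shared
standard reproduces the published tables' structure. Strata with zero
population and zero events are skipped; zero population with events is an
error, as is a missing stratum.

Extrapolation to a target population is the age×sex ratio method,
`total = Σₛ countₛ · targetₛ/schemeₛ`.

## 4. The synthetic-data generator

The generator (`mmepi.simulate`) is first-class, tested code. It emulates
the event grammar the algorithms consume, not French demography:

* **Population**: `n_persons` with a fixed age×sex structure anchored in
  2014 (a crude western-European pyramid), observed 2006–2020; affiliation
  runs from birth or window start to death or window end.
* **Onset**: Bernoulli per person-year with an age-increasing annual
  hazard (0 below 18, 2·10⁻⁶ at 18–39 rising to 4.5·10⁻⁴ at 80+),
  calibrated so that the planted world-standardized incidence is ≈3.6 per
  100,000 — the order of magnitude reported for treated MM in western
  Europe. Background mortality is age-banded; MM adds a constant excess
  hazard of 0.12/year (median survival of a treated population of several
  years).
* **Care pathways** (mix 55% hospital / 20% LTD / 25% oral-only; the oral
  share matches the reported ~26% of patients first identified through
  the oral criterion): onset-to-treatment delay is geometric with mean 30
  days (no care-timing distributions are published; the care-start date is
  clamped to death/window end so that every patient's first events are
  observable). Hospital patients receive `C90*` stays (PD 70% / RD 15% /
  SAD 15%, occasionally with unrelated co-diagnoses) and MM-specific or
  chemotherapy dispensings, ASCT for 30% of those ≤65, and an LTD
  registration with probability 0.60 — the reported LTD coverage.
  LTD-pathway patients receive the registration with probability 0.60,
  otherwise they are downgraded to hospital evidence (the registration is
  suppressed but treatment remains visible, which is how LTD
  under-reporting manifests in claims). Oral-only patients receive 4+
  dispensings of one IMiD at 21–60-day intervals and, with probability
  0.90, ≥2 SPEP/UPEP within the monitoring window — and never a `C90*`
  stay or LTD record, making them invisible to the comparator.
* **Confusers** (rate 0.002): non-MM patients dispensed an IMiD for a
  listed other indication, always with a hospital stay coded with that
  indication. After event filtering (death, coverage gaps) a safety pass
  guarantees that no confuser retains a rule-qualifying monitoring
  pattern without its exclusion stay: outside adversarial mode the
  generator plants no rule-qualifying false positive by construction.
* **Coverage gaps** (probability 0.03): all events in a sampled ≥731-day
  interval are suppressed and the affiliation is split, making the gap
  censoring rule exercisable.
* **Background reimbursements**: Poisson 4 events/person-year over the
  affiliation segments — sparse relative to real claims, but sufficient
  to drive the censoring logic.
* **Truth labels**: per person, the true status, onset date, pathway,
  confuser indication, and `designed_detectable_by` — the set of
  algorithms that should find the person, derived from the *final* event
  stream by an independent plain-loop re-evaluation of the rules, kept
  deliberately separate from the vectorized implementations so that
  recovery tests compare two code paths.
* **Adversarial mode** replaces half the population with a deterministic
  battery of boundary templates (dispensings exactly 90 days apart,
  monitoring at day 0 and day 120, same-day double dispensings, ages 17/
  18/19 at evidence, window-boundary dates, a stay/LTD same-day tie, an
  untreated LTD patient, a deliberate oral false positive, a planted
  reimbursement gap) and densifies organic patients and confusers in the
  remainder.

Reproducibility: a single PCG64 stream seeded from the configuration;
identical configuration ⇒ row-identical output.

**What the generator does not model** — treatment-line sequencing,
hospital-dispensed (intra-DRG) drugs, realistic reimbursement density,
multi-scheme membership, migration, calendar trends in incidence, and
clinical-trial supply. Passing recovery tests therefore demonstrates the
internal consistency of rules, bookkeeping and standardization — not the
field accuracy of the algorithm on real claims, which requires registry
validation.

## 5. Problem sizes and numerical choices

The reference scenario is 200,000 persons (≈200 true patients), used by
the recovery tests and the acceptance script; at that size a full
simulate-identify-tabulate cycle takes seconds and the planted-versus-
recovered aggregate ASIR comparison has a Monte-Carlo standard error of
≈10%, against which the pipeline is required to agree within 4 standard
errors. Cohort-level unit tests run on 2,000–50,000 persons. Rate
computations use compensated summation only in the test oracle; the
implementation relies on numpy's pairwise summation, which agrees with
the oracle to 10⁻¹² relative tolerance in the asserted range. Empty
cohorts, zero denominators and 0/0 rates are handled explicitly (warning
or typed error, never NaN propagation).

## 6. Known limitations

* The example code lists (ATC-style drug identifiers, synthetic procedure
  codes, exclusion ICD-10 prefixes) are documented placeholders, not an
  authoritative transcription of any national appendix; analyses of real
  extracts must supply their own `CodeListConfig`.
* Age is computed from birth year only, so ages can be off by up to one
  year relative to exact birthdays; all strata use the same convention.
* Point-in-time January-1 denominators approximate person-years; with
  stable populations the bias is negligible, with strong within-year
  migration it would not be.
* The washout cannot be verified for first information earlier than two
  years after the history start; such members are conservatively treated
  as prevalent.
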