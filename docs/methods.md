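# Methods

## Scope and data model

`faersig` implements disproportionality screening over spontaneous
adverse-event reports in the FAERS quarterly-file dialect: `$`-delimited
DEMO, DRUG, REAC and THER tables keyed by `primaryid` (one row per case
*version*) and `caseid` (one per case).  The unit of every count is the
deduplicated report, not the drug–event row.  Adverse events are MedDRA
preferred terms (PTs); each PT maps to one system organ class (SOC) through
a two-column dictionary supplied by the user (the licensed MedDRA dictionary
cannot be bundled; the synthetic generator emits a stand-in for its own
catalogue).

## Cleaning

Deduplication happens in two passes: exact duplicate `primaryid` records
collapse to one, then among several `primaryid`s sharing a `caseid` only the
numerically largest is kept.  FAERS emits a new, larger `primaryid` for each
revision of a case and FDA guidance recommends using the latest version;
both pass counts are logged separately because either pass alone is a
defensible reading of "removing duplicates by case id and primary id".

Study-drug selection keeps reports whose *primary suspect* (PS) drug matches
a keyword, case-insensitively, as a substring of either `drugname` or
`prodname` — free-text FAERS drug names carry salts, suffixes and dosage
text, so exact matching would silently drop reports.  Non-PS roles
(secondary suspect, concomitant, interacting) never qualify.  A report whose
PS drug matches two study drugs is logged as ambiguous and included in both
per-drug analyses.  Ages are normalised to years from the YR/MON/DY/DEC unit
codes; an unrecognised non-empty unit makes the age missing, while an empty
unit is assumed to be years (the dominant FAERS convention).

PTs absent from the dictionary stay in PT-level screening but contribute no
SOC, so SOC-level tables never contain a term of unknown parentage.

## Contingency tables and comparator

For drug *D* and term *t* in stratum *s*: `a` = reports of *D* in *s*
mentioning *t*; `c` = reports of *D* in *s* not mentioning *t*; `b`/`d` =
the same split over the comparator.  The comparator for each drug is **all
other deduplicated reports in the database**, including the other study
drug's reports ("all other drugs"); it is an explicit argument everywhere,
so a restricted universe can be substituted without code changes.
Sex strata restrict both the target and the comparator to that sex;
missing-sex reports belong to no stratum, hence `a(F)+a(M) ≤ a(overall)`
with equality when no sex is missing.

PT-level screening enumerates terms with `a ≥ 3` (the shared criterion
threshold); SOC tables are built for every observed SOC so sub-threshold
rows remain visible in the output, mirroring the usual presentation of
organ-class tables.

## Statistics

The four algorithms and their criteria are implemented exactly as closed
forms of the table cells (see the README for the formulas).  Numerical
choices:

* **No continuity or Yates correction anywhere.**  The χ² and CI formulas
  contain none; a zero cell makes ROR, PRR's CI and EBGM05 *undefined*
  (never positive) rather than corrected.  The `a ≥ 3` gate makes the a = 0
  case irrelevant to positivity anyway.
* **BCPNN variance prefactor** is `(1/ln 2)²`, the standard closed-form
  posterior variance of the information component on the log₂ scale; it is
  isolated in a single constant.  The IC criterion uses
  `IC025 = E(IC) − 2√V(IC)` only.
* **EBGM05 uses z = 1.96** by default although it is conventionally called a
  one-sided 95% bound (1.645); the z-value is a config field
  (`SignalCriteria.z_ebgm`) for users who prefer the conventional value.
* The MGPS side condition "at least one observed co-occurrence" is read as
  `a > 0`.
* Statistics are computed at full double precision and rounded to two
  decimals only when rendering tables (`"6.08 (5.56–6.64)"`).
* ROR and PRR increase strictly in `a` (margins fixed); EBGM and E(IC) are
  shrinkage estimates that saturate and eventually *decrease* once `a`
  dominates its margins, so monotonicity is only asserted — and only holds —
  in the sparse-signal regime.

Consensus positivity is the conjunction of the four flags.  All thresholds
(`min_a`, PRR ≥ 2, χ² ≥ 4, EBGM05 ≥ 2, IC025 > 0, CI lower > 1) live in
`SignalCriteria` and are recorded in the run manifest.

## Stratified log-ROR matrix

Rows are the union of PTs consensus-positive in *any* drug×sex stratum
(the alternative universe — overall-positive PTs only — is obtainable by
passing those tables instead); columns are the four strata.  Cell values are
log₁₀ of the stratum's ROR point estimate with two totality rules: a stratum
where the PT was never reported (a = 0) takes the substitute value 0.01,
i.e. exactly −2 after the log; a stratum with a > 0 but a zero `b` or `c`
cell (ROR undefined, not zero) is displayed with a Haldane 0.5-corrected
ROR.  Log base 10 makes the −2 floor and powers-of-ten scale readable; the
base is a config option.

Row and column orders come from agglomerative hierarchical clustering
(scipy, Euclidean distance, average linkage).  Rows are sorted by label
before linkage so the leaf order is invariant to input permutation and
deterministic across runs; heatmap rendering itself is delegated to
matplotlib and is not part of the tested artifact.

## Time to onset

TTO = `EVENT_DT − START_DT` in calendar days, where START_DT is the THER row
linked to the PS drug via `dsg_drug_seq` (earliest *full* date if several).
A report is excluded with the first applicable reason among: missing event
date, missing start date, partial/malformed date, negative interval, date
outside [1900-01-01, extraction date].  "Unreasonable" is defined here as
the last two reasons; a 0-day interval is kept because same-day infusion
reactions are clinically real.  Summaries report per-group inclusion and
per-reason exclusion tallies with median and quartiles; the even-n median is
the midpoint of the central order statistics, so half-day medians arise
naturally.

Group comparison defaults to a two-sided Mann–Whitney rank-sum test — exact
by exhaustive enumeration over all assignments (midranks, so ties are
handled) when both groups have n ≤ 8, the tie-corrected normal
approximation otherwise; an uncensored log-rank variant is available behind
`tto_test="logrank"`.  The test name is always carried in the output so
downstream text cannot misattribute it.

## Synthetic database generator

The generator emulates the structural features of a FAERS extract that the
pipeline must survive: multi-version cases (a duplicated case is re-emitted
under a larger `primaryid` with only reporter and country perturbed — never
the PT set, so dedup correctness is checkable against the manifest), one PS
drug per report plus 0–2 uniformly drawn concomitants, demographic
missingness, and YYYYMMDD dates that may be missing (empty string), partial
(4- or 6-digit) or inconsistent (therapy start after the event).

Event generation is the simplest mechanism with exactly known ground truth:
each PT is an independent Bernoulli draw per report at base probability
`background_pt_rate / n_PTs`, multiplied by the configured relative risk
(clipped to 1) when the report's PS drug and the PT form a planted pair.
A report may therefore carry no PT at all (it simply has no REAC rows); this
keeps both the planted RR and the marginal PT rate exact.  Time-to-onset is
drawn per PS drug as `median · exp(σZ)` (log-normal), so the planted median
is exact, and `START_DT = EVENT_DT − draw`.

Defaults describe the study conditions this package targets: 12 drugs of
which 2 are targets, a 31-PT catalogue over 7 SOCs weighted toward
nervous-system and administration-site terms, ~2 PTs per report, 5%
duplicated cases, 7%/26%/10%/5%/1% missing-sex/missing-age/missing-date/
partial-date/inconsistent-date rates (the demographic rates follow the
published characteristics table of the two-drug anti-Aβ safety study), an
event window of 2004-Q1 to 2024-Q2, and log-normal onset medians of 33 days
(lecanemab-like) and 146 days (aducanumab-like) with σ = 0.6.  Planted
relative risks (2.5–14) are bounded by the Bernoulli mechanism
(`base_p · RR ≤ 1`), so they are deliberately far below the extreme
disproportionality of real ARIA terms (ROR ~10⁴): the generator reproduces
the *qualitative* signal pattern and the screening behaviour, not the
magnitudes of a real extract.  What passing tests therefore show is that the
pipeline recovers known associations and calibrates correctly under clean
independence; they do not certify behaviour under real-world reporting
dynamics (stimulated reporting, duplicates that alter clinical content,
drug-name noise beyond brand/generic pairs), which the generator does not
model.

## Problem sizes used in validation

The test-suite and acceptance script exercise: formula equivalence on 1,000
random tables with cells in [0, 500] against an exact-rational oracle
(agreement ≲ 4·10⁻¹⁵); ROR CI null coverage on 2,000 binomial tables with
expected cells ≥ 10; planted-signal recovery on twenty 50,000-case databases
with one pair at RR = 10; the null consensus false-positive rate on twenty
20,000-case databases; stratum additivity and onset-median recovery on a
clean 6,000-case database (~500 reports per target drug).  These sizes give
stable Monte-Carlo behaviour while keeping a full validation run in the
low minutes on one core.

## Known limitations

* The MGPS implementation is the closed-form relative-reporting EBGM with a
  Wald-type lower bound, not DuMouchel's full two-component gamma-Poisson
  prior fit; the two agree only loosely for small counts.
* The Wald ROR interval is undefined for zero cells by design; users wanting
  continuity-corrected estimates must pre-correct their tables.
* Date handling recognises full/partial/missing YYYYMMDD strings only; the
  many historical FAERS date quirks beyond that are out of scope.
* The generator plants associations at the report level with independent
  PTs; co-reported PT clusters (e.g. ARIA-oedema with concurrent
  microhaemorrhage) are not modelled, so PT–PT correlation structure in real
  data is untested.
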