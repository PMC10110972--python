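# Methods

## Problem and model

Spontaneous adverse-event databases collect voluntary reports, each naming
one or more drugs (with a reporter-assigned role) and one or more reaction
preferred terms (PTs). Disproportionality analysis asks whether a drug and an
event are reported together more often than the rest of the database would
suggest. For a drug of interest and an event scope, reports are
cross-classified as

|                   | drug of interest | other drugs |
|-------------------|------------------|-------------|
| event of interest | a                | b           |
| other events      | c                | d           |

and the reporting odds ratio is ROR = (a·d)/(b·c) with the Woolf log-normal
interval exp(ln ROR ± z·√(1/a + 1/b + 1/c + 1/d)), z = 1.96 hard-coded as
the conventional 95% quantile. A (drug, scope) pair is a *positive signal*
when the interval's lower bound is strictly above 1 and a ≥ 3. The ROR is a
measure of reporting disproportion, not of incidence or causal risk; no
multiple-testing adjustment is applied anywhere, and the output metadata says
so explicitly.

The event of interest is severe cutaneous adverse reactions, operationalised
as the SCAR SMQ (code 20000020): a report is in scope iff at least one
reaction matches one of the SMQ's 18 narrow-scope PTs (MedDRA 23.0). Each
culprit drug — any ingredient that is primary suspect in at least one SCAR
report — is evaluated at 19 scopes: the SMQ level (any narrow PT) plus each
PT individually.

## Conventions and tunable parameters

- **Counting unit**: the report. A report is "with drug" iff any
  primary-suspect mention normalizes to the drug; roles 2 (concomitant) and
  3 (interacting) never contribute. Each report falls in exactly one cell.
- **Background set** (`background`): by default the full deduplicated report
  collection, SCAR and non-SCAR alike (`faers_background`) — the comparator
  is "all other drugs in the database". A `scar_only` alternative restricts
  all four cells to the SCAR subset.
- **Zero cells** (`zero_cell`): a table with any empty cell is *not
  evaluable* (hence negative) by default. The optional `haldane` mode adds
  0.5 to all four cells of such tables and flags the result `corrected`; the
  a ≥ 3 gate always uses the raw a.
- **PT matching** is by normalized name (case-folded, whitespace collapsed,
  hyphen/en-dash unified), because the openFDA reaction field carries PT
  strings; the MedDRA code table ships alongside for documentation and for
  substituting other SMQs.
- **Name normalization**: lowercase, trim, collapse whitespace, then an
  optional ingredient map integrating same-active-ingredient forms (the
  configurable replacement for manual pharmacist curation); entries may map
  to an AMBIGUOUS marker to exclude a name. Unmapped names pass through
  unchanged so nothing silently disappears; every exclusion (missing generic
  name, ambiguous, within-report duplicate) is tallied in the run manifest.
- **Deduplication**: the source database revises reports, so duplicates share
  a report id; we keep the copy with the latest receive date, breaking exact
  ties by input order. This rule is this package's own documented choice.
- **Rounding** in printed tables: proportions to one decimal, outcome
  percentages to the nearest integer, always half away from zero, computed
  in exact decimal arithmetic from the count cells.
- **ATC classes**: second level = first three characters of a 7-character
  code. A drug with several codes counts in each of its classes; class
  reporting proportions use distinct reports (two same-class suspects in one
  report count once). Unmapped ingredients stay in the totals as
  unclassified.

## Synthetic-data generator

The generator emulates the *structure* of openFDA drug-event data with a
fully known association model. Per report: one primary-suspect drug drawn
from a catalog; each SCAR PT included independently with odds
`baseline × multiplier(drug, PT)` (an SMQ-scope effect multiplies all 18 PT
odds); independent filler reactions, with a guaranteed filler so no report is
empty; demographics drawn independently of drugs and reactions; optional
concomitant mentions, blanked generic names, and exact-copy duplicates
sharing the report id.

Multiplying *odds* rather than probabilities makes the per-PT report-level
odds ratio exactly equal to the configured multiplier, so the ROR estimand is
known without simulation; SMQ-level (any-PT) ground truth is the enumerated
marginal odds ratio of the model, flagged `induced` in `ground_truth` output
because it is derived rather than directly configured. Closed-form expected
case counts (`expected_case_counts`) support power and gating calculations.

Reference study conditions (`default_study_config`): 20 ingredients with
realistic ATC classes and use shares of 3–7.5%; per-PT baseline odds from
4·10⁻⁴ to 3·10⁻³ (SJS most frequent), putting the SCAR fraction near 1.5% of
reports — a rare-event regime comparable to real spontaneous databases; 5%
missing generic names; 2% duplicates; 30% concomitant decorations;
demographic marginals matching large pharmacovigilance datasets (78%
health-professional reporters, more female than male patients, ages centred
in the sixth and seventh decades, ~10% fatal outcomes, reporting volume
growing over 2004–2021).

What the generator deliberately does **not** emulate: confounding by
indication, channeling, the Weber effect, notoriety bias, drug–drug
interactions, or any dependence between demographics and reporting. Passing
tests therefore demonstrate that the pipeline recovers the reporting
associations present in the data, not that the ROR is robust to the biases
of real spontaneous reporting.

## Operating characteristics

`scarsignal.study` runs two repeated-seed experiments at the reference
conditions (n = 200,000 reports, 20 seeds), each executing the *full*
pipeline per seed:

- **Null calibration**: with every multiplier 1, the positive-signal rate
  among (drug, scope) pairs whose expected a ≥ 3 should sit at or below ~5%
  — the rule is a one-sided 2.5% test plus the case-count gate, which can
  only lower the rate. Sparser pairs are excluded because the gate, not the
  CI, decides them.
- **Effect recovery**: an SMQ-scope odds multiplier of 5 on one drug
  (expected a in the hundreds) should be flagged in ≥ 95% of seeds.

## Numerical and degenerate-input choices

- CI arithmetic in plain double precision; the log-scale symmetry
  |ln(hi/ROR) − ln(ROR/lo)| holds to 1e-12.
- Empty report sets, drugs absent from every report (a + b = 0), and scopes
  never co-occurring with a drug are all well-defined: tables stay
  non-negative, results become not-evaluable rather than raising.
- Sort orders are total (count descending, then label ascending) so all
  outputs are deterministic; the run manifest contains no timestamps, making
  identical config + seed byte-identical.
- Records with no reactions are skipped and counted, not errors, because
  real extracts contain them.

## Known limitations

- The ingredient map ships empty by default; without a curated table,
  distinct salt-form spellings count as distinct ingredients.
- Name matching has no spelling correction; openFDA generic names are
  already normalized upstream, raw product names are not used for counting.
- The openFDA dialect cannot represent an explicit "unknown" outcome marker;
  absence of seriousness flags reads back as an empty outcome set.
- `scar_only` background at the SMQ scope is degenerate by construction
  (every in-scope report has the event); it exists for PT-level sensitivity
  analyses.
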