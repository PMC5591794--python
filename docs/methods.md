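# Methods

## The model

Drug-induced sedation endoscopy (DISE) examines the collapsing upper
airway during sedated sleep.  Findings here are recorded on a unified
grid of seven anatomical sites — nose (N), velum (V), tonsils (Ts),
lateral pharyngeal wall/oropharynx (O), tongue base (Tb), epiglottis (E)
and larynx (L) — each graded by a degree of obstruction

| degree | label    | airway narrowing |
|--------|----------|------------------|
| 0      | none     | <50% (no vibration) |
| 1      | partial  | 50–75% (vibration) |
| 2      | complete | >75% (collapse) |

and, where anatomy allows, a configuration of collapse: anteroposterior
(AP), lateral (L) or concentric (C).  The allowed configurations are
fixed per site: the nose (a static obstruction) and larynx carry none,
tonsils and lateral pharyngeal wall collapse laterally only, the
epiglottis folds AP or laterally, and velum, oropharynx and tongue base
admit all three.  A full examination is one finding per site, written in
canonical order as a score string such as `N0V1APTs0O0Tb0E0L0` (simple
palatal snoring).  The **severity index** is the sum of the seven
degrees, 0–14; it is additive in degree and invariant under
configuration changes.

Respiratory phase (inspiration vs expiration), sedation depth and
laryngeal sub-sites (supraglottis vs glottis) are deliberately not
modelled.  Percent-narrowing bands are labels only; no numeric narrowing
is computed.

### Notation choices

* Configuration is mandatory at degree ≥ 1, optional at degree 0, and
  omitted from canonical strings at degree 0.  Degree-0 findings may
  still carry a configuration internally because the crosswalk's
  reference grid enumerates degree-0 cells per configuration; a finding
  without one simply matches *every* configuration variant of the
  relevant rules (widening).
* The larynx site code `L` coincides with the lateral-configuration
  letter.  Internally the larynx is a distinct enum member, so there is
  no ambiguity; in score strings the parser is anchored on the fixed
  site order (N, V, Ts, O, Tb, E, L) and backtracks over the optional
  configuration, which resolves strings like `…E0L0` (larynx) against
  `…E2APL0` (epiglottis AP).  Permuted site order is an error, not
  silently reordered — with arbitrary order the `E`/`L`/lateral
  ambiguity would be unresolvable.

## The crosswalk

Four published DISE systems are mapped: the Pringle–Croft whole-exam
grades G1–G5, VOTE (velum/oropharynx/tongue base/epiglottis, degrees
0–2, configurations AP/L/C), NOHL (nose/oropharynx/hypopharynx grades
1–4 in AP/transversal/concentric direction, larynx negative/positive,
plus a tonsil grade), and P-T-L-Tb-E (five sites, grades 1–3).

Every mapping is a declarative, **direction-specific** record in
`src/udise/data/rules.yaml`; ranges and per-grade buckets are expanded
at load time into explicit rules with stable ids (`NOHL.OT.4`,
`U2NOHL.V.AP.1`, …), each carrying the source equation as an anchor
string that conversion results surface as provenance.  Mappings are
set-valued: a candidate set has size 1 only when a one-to-one rule
fires; anything else is reported as ambiguity, never collapsed to a
guess.  Conversions therefore support a severity *range* rather than a
point value.

Decisions taken where the published material is ambiguous or asymmetric:

* **Directional asymmetry is preserved verbatim.**  uDISE velum maps
  forward to the NOHL palatal oropharynx level (`V1AP → O_V AP 3`),
  while NOHL's transversal/concentric oropharynx maps back to the uDISE
  oropharynx.  No symmetric closure is invented; the round-trip check
  reports the resulting non-containment honestly.
* **NOHL concentric hypopharynx maps to *lateral* tongue base** in the
  forward direction, exactly as the published equations print it, even
  though it looks like a typo; the uDISE→NOHL direction keeps the
  table's concentric entries.  Rule ids `NOHL.HC.*` / `U2NOHL.TB.C.*`
  carry the anchors.
* **NOHL tonsil grades 1–2 have no published mapping** and convert to
  no constraint at all, flagged `unmapped_grade`, rather than an
  invented degree.  Likewise NOHL oropharynx AP tokens.
* **Pringle G3 and G4 both denote complete oropharyngeal collapse**
  (their inspiration/expiration split is outside the model), so
  uDISE `O2` returns the candidate set {G3, G4}.
* **The VOTE oropharynx equation is a union** — oropharynx *or*
  tonsils, both lateral.  It is represented as candidates at both sites
  sharing a disjunction group ("at least one member site takes the
  mapped pair; a non-selected member is unobstructed"), so each
  member's candidate set also contains the degree-0 cell and the result
  is ambiguous for degree ≥ 1.
* **NOHL transversal** is internally `T`; the published equations write
  `t` at the oropharynx and `L` at the hypopharynx for the same
  direction, and both are accepted as input aliases.

Multi-token input is combined by per-site intersection (one exam yields
one finding per site); an empty intersection raises a contradiction
error naming the site and rules, never an average.

### Severity bounds

`severity_range` reports the min/max severity index over all profiles
consistent with a foreign→uDISE result, with unconstrained sites
contributing 0–2.  It is computed analytically from per-site extrema,
except that sites bound by disjunction groups are enumerated jointly
(the groups touch at most two sites, so this is exact and cheap).  The
test suite checks it against an independent brute-force enumeration of
all degree vectors over the candidate product space for the complete
single-token space of all four systems.

### Coverage markers and the reference table

Per system, a uDISE cell is *covered* when some uDISE→foreign rule
matches it.  Uncovered cells at sites a system does not consider
anatomically (nose and larynx for Pringle, VOTE and P-T-L-Tb-E) are
marked `X`; other uncovered cells are configuration exclusions, `-`.
The 42-row referential table (site order, configuration-major, degree
0–2) is regenerated purely from the rule base and diffed cell-by-cell
against the hand-encoded fixture `src/udise/data/reference_table.csv`,
so every uDISE→foreign rule is exercised at once.  Two typesetting
conflicts in the source table are resolved in favour of the explicit
equations (the velum rows' NOHL entries use the published reverse
equations `V AP → O_V AP`, `V L → O_V t`, `V C → O_V C`); the uDISE
oropharynx-AP rows, for which no equation exists, keep the table's
transversal entries as printed.

## Synthetic cohorts

The generator draws each site's degree independently from a categorical
triple (default 0.5/0.3/0.2 for none/partial/complete) and, at degree
≥ 1, a configuration uniformly from the site's allowed set, all from a
single seeded RNG (identical config ⇒ byte-identical cohort).  Expected
severity under the defaults is 7 × (0.3 + 2×0.2) = 4.9, which the test
suite checks at n = 10 000 within three standard errors.

Site independence is a simplification — real obstructive-sleep-apnea
cohorts show strong co-occurrence of multilevel collapse and
non-uniform configuration mixes — so passing tests demonstrate that the
scoring, notation, crosswalk and summary machinery is correct, not that
simulated cohorts resemble clinical case mix.

## Numerical and degenerate-input notes

* Probability triples must sum to 1 within 1e-9.
* Reference-table cell text sorts candidate tokens lexicographically,
  and row order is fixed, so output is byte-identical across runs.
* Empty cohorts, permuted score strings, mixed-system token lists,
  out-of-vocabulary grades and contradictory token sets all raise
  typed errors rather than degrading silently.

## Known limitations

* Only the four systems above are mapped; the many other published DISE
  scales are out of scope.
* The crosswalk transports *findings*, not clinical judgement: a
  Pringle grade constrains only the sites its definition mentions, and
  sites it is silent about are left unconstrained rather than assumed
  patent.
* No probabilistic weighting of candidates: the mappings define sets,
  not distributions.
* Treatment planning is out of scope beyond the library's ability to
  attach external lookups to score strings.
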