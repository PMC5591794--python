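# udise

Scoring and crosswalks for drug-induced sedation endoscopy (DISE)
findings.

DISE is the endoscopic examination of the collapsing upper airway during
sedated sleep, central to surgical planning for obstructive sleep apnea.
Many incompatible grading scales are in clinical use, so the same
examination can be reported — and acted on — differently depending on the
scale chosen.  This package implements a unified classification grid and
machine-checkable conversions between it and four established systems,
for clinicians and clinical-informatics pipelines that need to compare
DISE reports across scales.

## The model

An examination is one finding per anatomical site, over seven sites in
fixed order — nose (N), velum (V), tonsils (Ts), lateral pharyngeal
wall/oropharynx (O), tongue base (Tb), epiglottis (E), larynx (L).  Each
finding is a degree of obstruction *d* ∈ {0 none (<50%), 1 partial
(50–75%), 2 complete (>75%)} plus, where anatomy allows, a configuration
of collapse ∈ {AP anteroposterior, L lateral, C concentric}.  A profile
serializes to a score string, e.g. `N0V0Ts2LO0Tb2APE0L0` (complete
lateral tonsillar plus complete AP tongue-base collapse), and its
severity index is the sum of the seven degrees:

S = Σ_site d(site) ∈ [0, 14].

A declarative rule base maps findings in both directions between this
grid and the Pringle–Croft grades (G1–G5), VOTE, NOHL and P-T-L-Tb-E
systems.  Conversions are set-valued: one-to-many mappings surface as
candidate sets with `ambiguous` flags, sites a system does not consider
are flagged (`site_excluded` / `config_excluded`, the reference table's
`X` and `–` markers), and every fired rule is reported with the equation
it encodes.  See `docs/methods.md` for the full model and the design
decisions.

## Worked example

```sh
$ udise severity N0V0Ts2LO0Tb2APE0L0
<input>	4
```

The two complete obstructions (tonsils, tongue base) sum to a severity
index of 4.  Converting a VOTE oropharynx finding — complete lateral
collapse, `O2L` — into the unified grid:

```sh
$ udise convert O2L --from VOTE --to UDISE
```

```json
{
  "flags": {"O": "ambiguous", "Ts": "ambiguous"},
  "provenance": [
    {"rule": "VOTE.O.2", "anchor": "O_k 0-2, L -> {O_0-2, L} U {Ts_0-2, L}"}
  ],
  "candidates": {
    "O":  [{"degree": 0, "configuration": null},
           {"degree": 2, "configuration": "L"}],
    "Ts": [{"degree": 0, "configuration": null},
           {"degree": 2, "configuration": "L"}]
  }
}
```

(abridged) — VOTE's oropharynx level means "oropharynx *or* tonsils",
so the engine offers complete lateral collapse at either site, tied by a
disjunction so severity bounds stay honest:

```sh
$ udise severity G5 --system PRINGLE
<input>	0-14
```

a Pringle grade-5 exam (tongue-base level obstruction) constrains the
tongue base and epiglottis only to degree ranges, so any severity from 0
to 14 is consistent with it.

Other commands: `udise validate` (score strings or CSV/JSON cohorts),
`udise table` (regenerate the 42-row referential classification table),
`udise cohort` (per-site frequencies, severity histogram, multilevel
count), `udise simulate` (seeded synthetic cohorts).  The same
operations are available as library functions (`udise.parse_udise`,
`udise.to_udise`, `udise.severity_range`, …).

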