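"""Crosswalk engine: applies the rule base in either direction while
tracking ambiguity, lossiness, coverage gaps and rule provenance.

Conversions are set-valued.  A foreign finding maps to a *candidate set*
of (degree, configuration) cells per uDISE site — a singleton only when a
published one-to-one rule fires.  Multi-token input is combined by
per-site intersection (one DISE exam yields one finding per site), and a
contradiction is surfaced, never averaged away.  The VOTE oropharynx
union (oropharynx-or-tonsils) is carried as an explicit disjunction
group so that severity bounds respect "one of these sites, not
necessarily both".
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import (
    Configuration,
    SiteFinding,
    Structure,
    UdiseProfile,
)
from .notation import ForeignToken, format_foreign, validate_foreign
from .rules import (
    CONFIG_EXCLUDED,
    COVERED,
    FOREIGN_TO_UDISE,
    SITE_EXCLUDED,
    UDISE_TO_FOREIGN,
    Cell,
    RuleBase,
)

# per-site result flags
EXACT = "exact"
AMBIGUOUS = "ambiguous"
FLAG_SITE_EXCLUDED = "site_excluded"
FLAG_CONFIG_EXCLUDED = "config_excluded"
UNMAPPED_GRADE = "unmapped_grade"


class ConversionError(ValueError):
    pass


class ContradictionError(ConversionError):
    """Tokens jointly constrain a site to an empty candidate set."""


#: Which uDISE site a foreign site naturally reports on (used to attach
#: the unmapped_grade flag when no rule fires for a token).
_DEFAULT_SITE = {
    "VOTE": {"V": Structure.VELUM, "O": Structure.OROPHARYNX,
             "T": Structure.TONGUE_BASE, "E": Structure.EPIGLOTTIS},
    "NOHL": {"N": Structure.NOSE, "O": Structure.OROPHARYNX,
             "H": Structure.TONGUE_BASE, "TS": Structure.TONSILS,
             "L": Structure.EPIGLOTTIS},
    "PTLTBE": {"P": Structure.VELUM, "T": Structure.TONSILS,
               "L": Structure.OROPHARYNX, "Tb": Structure.TONGUE_BASE,
               "E": Structure.EPIGLOTTIS},
}


def _cells_compatible(a: Cell, b: Cell) -> bool:
    """Two cells denote the same finding; a missing configuration at
    degree 0 is a wildcard."""
    da, ca = a
    db, cb = b
    if da != db:
        return False
    if ca is None or cb is None:
        return True
    return ca == cb


def _intersect(a: frozenset[Cell], b: frozenset[Cell]) -> frozenset[Cell]:
    out = set()
    for x in a:
        for y in b:
            if _cells_compatible(x, y):
                # keep the more specific (configuration-bearing) cell
                out.add(x if x[1] is not None else y)
    return frozenset(out)


@dataclass(frozen=True)
class DisjunctionGroup:
    """"At least one of these (site, cell) members holds"."""

    rule_id: str
    members: tuple[tuple[Structure, Cell], ...]


@dataclass
class ConversionResult:
    """Outcome of a crosswalk in either direction.

    ``candidates`` (foreign->uDISE) maps each constrained site to its
    admissible cells; ``foreign_candidates`` (uDISE->foreign) maps each
    source site to its candidate foreign tokens.  ``flags`` classifies
    every touched site; ``provenance`` lists the rule ids that fired.
    """

    direction: str
    system: str
    candidates: dict[Structure, frozenset[Cell]] = field(default_factory=dict)
    unconstrained: frozenset[Structure] = frozenset()
    disjunctions: tuple[DisjunctionGroup, ...] = ()
    foreign_candidates: dict[Structure, frozenset[ForeignToken]] = field(
        default_factory=dict
    )
    flags: dict[Structure, str] = field(default_factory=dict)
    provenance: tuple[str, ...] = ()

    def to_json(self, rule_base: Optional[RuleBase] = None) -> dict:
        def cell(c: Cell) -> dict:
            return {"degree": c[0],
                    "configuration": c[1].code if c[1] else None}

        doc = {
            "direction": self.direction,
            "system": self.system,
            "flags": {s.code: f for s, f in self.flags.items()},
            "provenance": [
                {"rule": rid,
                 "anchor": rule_base.by_id[rid].anchor if rule_base else None}
                for rid in self.provenance
            ],
        }
        if self.direction == FOREIGN_TO_UDISE:
            doc["candidates"] = {
                s.code: sorted((cell(c) for c in cs),
                               key=lambda d: (d["degree"],
                                              d["configuration"] or ""))
                for s, cs in self.candidates.items()
            }
            doc["unconstrained_sites"] = sorted(
                s.code for s in self.unconstrained
            )
            doc["disjunctions"] = [
                {"rule": g.rule_id,
                 "members": [{"site": s.code, **cell(c)}
                             for s, c in g.members]}
                for g in self.disjunctions
            ]
        else:
            doc["foreign_candidates"] = {
                s.code: sorted(format_foreign(t) for t in ts)
                for s, ts in self.foreign_candidates.items()
            }
        return doc

    def to_json_str(self, rule_base: Optional[RuleBase] = None) -> str:
        return json.dumps(self.to_json(rule_base), indent=2)


def to_udise(
    tokens: Sequence[ForeignToken], rule_base: RuleBase
) -> ConversionResult:
    """Convert validated foreign tokens (all from one system) to per-site
    uDISE candidate sets.

    Constraints from distinct tokens touching the same site are
    intersected; an empty intersection raises :class:`ContradictionError`
    naming the site and the rules involved.  Tokens no rule covers (e.g.
    NOHL tonsil grades 1-2) are flagged ``unmapped_grade`` and constrain
    nothing.
    """
    if not tokens:
        raise ConversionError("no tokens to convert")
    systems = {t.system for t in tokens}
    if len(systems) > 1:
        raise ConversionError(f"mixed systems in one conversion: {systems}")
    system = tokens[0].system
    for t in tokens:
        errs = validate_foreign(t)
        if errs:
            raise ConversionError("; ".join(errs))

    candidates: dict[Structure, frozenset[Cell]] = {}
    contributors: dict[Structure, list[str]] = {}
    disjunctions: list[DisjunctionGroup] = []
    flags: dict[Structure, str] = {}
    provenance: list[str] = []

    for token in tokens:
        matched = rule_base.match_token(token)
        if not matched:
            site = _DEFAULT_SITE.get(system, {}).get(token.site)
            if site is not None:
                flags.setdefault(site, UNMAPPED_GRADE)
            continue
        # several rules can match one token only through configuration
        # widening; their constraints are alternative readings -> union
        token_cells: dict[Structure, set[Cell]] = {}
        token_rules: list[str] = []
        for rule in matched:
            token_rules.append(rule.id)
            if rule.disjunction:
                members = []
                for constraint in rule.constraints:
                    for c in constraint.allowed:
                        members.append((constraint.structure, c))
                        token_cells.setdefault(
                            constraint.structure, set()
                        ).update({c, (0, None)})
                disjunctions.append(
                    DisjunctionGroup(rule.id, tuple(members))
                )
            else:
                for constraint in rule.constraints:
                    token_cells.setdefault(
                        constraint.structure, set()
                    ).update(constraint.allowed)
        provenance.extend(token_rules)
        for structure, cells in token_cells.items():
            contributors.setdefault(structure, []).extend(token_rules)
            if structure in candidates:
                merged = _intersect(candidates[structure], frozenset(cells))
                if not merged:
                    raise ContradictionError(
                        f"contradictory constraints at "
                        f"{structure.code} from rules "
                        f"{sorted(set(contributors[structure]))}"
                    )
                candidates[structure] = merged
            else:
                candidates[structure] = frozenset(cells)

    for structure, cells in candidates.items():
        flags[structure] = EXACT if len(cells) == 1 else AMBIGUOUS
    return ConversionResult(
        direction=FOREIGN_TO_UDISE,
        system=system,
        candidates=candidates,
        unconstrained=frozenset(s for s in Structure if s not in candidates),
        disjunctions=tuple(disjunctions),
        flags=flags,
        provenance=tuple(provenance),
    )


def convert_finding(
    finding: SiteFinding, system: str, rule_base: RuleBase
) -> tuple[frozenset[ForeignToken], str, tuple[str, ...]]:
    """Foreign candidate tokens for one uDISE finding, with its flag and
    the rule ids fired.  Used site-wise by :func:`from_udise` and by the
    reference-table generator."""
    marker = rule_base.coverage(
        system, finding.structure, finding.degree, finding.configuration
    )
    if marker == SITE_EXCLUDED:
        return frozenset(), FLAG_SITE_EXCLUDED, ()
    if marker == CONFIG_EXCLUDED:
        return frozenset(), FLAG_CONFIG_EXCLUDED, ()
    rules = rule_base.match_cell(
        system, finding.structure, finding.degree, finding.configuration
    )
    tokens = frozenset(t for r in rules for t in r.targets)
    flag = EXACT if len(tokens) == 1 else AMBIGUOUS
    return tokens, flag, tuple(r.id for r in rules)


def from_udise(
    profile: UdiseProfile, system: str, rule_base: RuleBase
) -> ConversionResult:
    """Convert a uDISE profile to candidate tokens of a foreign system.

    Sites the system does not consider anatomically are flagged
    ``site_excluded`` (the reference table's "X"); covered sites whose
    configuration the system lacks are ``config_excluded`` ("-").  A
    degree-0 finding without configuration matches every configuration
    variant of the relevant rules, widening its candidate set.
    """
    if system not in rule_base.systems:
        raise ConversionError(f"unknown system {system!r}")
    foreign: dict[Structure, frozenset[ForeignToken]] = {}
    flags: dict[Structure, str] = {}
    provenance: list[str] = []
    for finding in profile:
        tokens, flag, rule_ids = convert_finding(finding, system, rule_base)
        flags[finding.structure] = flag
        if tokens:
            foreign[finding.structure] = tokens
        provenance.extend(rule_ids)
    return ConversionResult(
        direction=UDISE_TO_FOREIGN,
        system=system,
        foreign_candidates=foreign,
        flags=flags,
        provenance=tuple(provenance),
    )


def _degree_options(result: ConversionResult) -> dict[Structure, set[int]]:
    options: dict[Structure, set[int]] = {}
    for s in Structure:
        if s in result.candidates:
            options[s] = {d for d, _ in result.candidates[s]}
        else:
            options[s] = {0, 1, 2}
    return options


def severity_range(result: ConversionResult) -> tuple[int, int]:
    """Minimum and maximum severity index over every uDISE profile
    consistent with a foreign->uDISE result.

    Unconstrained sites contribute the full 0-2 range.  Computed
    analytically from per-site extrema; sites bound by disjunction
    groups are enumerated jointly so "oropharynx or tonsils" style
    unions are honoured exactly.
    """
    if result.direction != FOREIGN_TO_UDISE:
        raise ConversionError("severity_range needs a foreign->uDISE result")
    options = _degree_options(result)
    group_sites: set[Structure] = set()
    for g in result.disjunctions:
        group_sites.update(s for s, _ in g.members)
    free_min = sum(min(options[s]) for s in Structure if s not in group_sites)
    free_max = sum(max(options[s]) for s in Structure if s not in group_sites)
    if not group_sites:
        return free_min, free_max
    ordered = sorted(group_sites, key=lambda s: s.canonical_order)
    feasible: list[int] = []
    for combo in itertools.product(*(sorted(options[s]) for s in ordered)):
        assign = dict(zip(ordered, combo))
        ok = all(
            any(assign[s] == cell[0] for s, cell in g.members)
            for g in result.disjunctions
        )
        if ok:
            feasible.append(sum(combo))
    if not feasible:
        raise ContradictionError(
            "no site assignment satisfies the disjunction groups"
        )
    return free_min + min(feasible), free_max + max(feasible)


@dataclass
class RoundTripVerdict:
    """Per-site containment of a profile in its own round-trip image."""

    contained: bool
    per_site: dict[Structure, str]  # "contained" | "not_contained" | marker

    def __bool__(self) -> bool:
        return self.contained


def round_trip_containment(
    profile: UdiseProfile, system: str, rule_base: RuleBase
) -> RoundTripVerdict:
    """Does each covered site's finding survive uDISE -> foreign -> uDISE?

    Restricted to sites the system covers with a matching configuration;
    excluded sites are reported with their coverage marker and do not
    affect the verdict.  Published one-way mappings (e.g. uDISE velum ->
    NOHL palatal level, with no forward rule back to the velum) yield
    honest non-containments.
    """
    forward = from_udise(profile, system, rule_base)
    per_site: dict[Structure, str] = {}
    contained = True
    for finding in profile:
        flag = forward.flags[finding.structure]
        if flag in (FLAG_SITE_EXCLUDED, FLAG_CONFIG_EXCLUDED):
            per_site[finding.structure] = flag
            continue
        original = (finding.degree, finding.configuration)
        back_cells: set[Cell] = set()
        for token in forward.foreign_candidates.get(finding.structure, ()):
            back = to_udise([token], rule_base)
            back_cells.update(back.candidates.get(finding.structure, ()))
        hit = any(_cells_compatible(original, c) for c in back_cells)
        per_site[finding.structure] = "contained" if hit else "not_contained"
        contained = contained and hit
    return RoundTripVerdict(contained, per_site)
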