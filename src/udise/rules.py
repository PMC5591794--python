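"""Declarative crosswalk rule base.

Every mapping between uDISE and the four foreign systems (Pringle/Croft,
VOTE, NOHL, P-T-L-Tb-E) is a direction-specific record in a versioned YAML
file (``data/rules.yaml``), one record per published mapping equation or
reference-table row group.  Records may carry grade/degree sets and
per-grade buckets; :func:`load_rule_base` expands them into fully explicit
:class:`MappingRule` instances, validating every constraint against the
core vocabulary and every target token against its system's vocabulary.

Rule ids are stable (e.g. ``NOHL.OT.4``, ``U2NOHL.V.AP.1``) and each rule
carries the anchor text of the equation it encodes, so conversion results
can report provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import yaml

from .core import (
    Configuration,
    SiteFinding,
    Structure,
    allowed_configurations,
)
from .notation import SYSTEMS, ForeignToken, validate_foreign

FOREIGN_TO_UDISE = "foreign_to_udise"
UDISE_TO_FOREIGN = "udise_to_foreign"

#: A uDISE cell: (degree, optional configuration).
Cell = tuple[int, Optional[Configuration]]

COVERED = "covered"
SITE_EXCLUDED = "X"
CONFIG_EXCLUDED = "-"


class RuleBaseError(ValueError):
    """Rule file fails schema or vocabulary validation."""


@dataclass(frozen=True)
class SiteConstraint:
    """Admissible (degree, configuration) pairs at one uDISE site."""

    structure: Structure
    allowed: frozenset[Cell]

    def __post_init__(self):
        if not self.allowed:
            raise RuleBaseError(f"empty constraint for {self.structure.code}")
        for degree, cfg in self.allowed:
            errs = SiteFinding(self.structure, degree, cfg).violations()
            # degree-0 findings may legitimately omit configuration
            if errs:
                raise RuleBaseError(
                    f"invalid cell ({self.structure.code},{degree},"
                    f"{cfg.code if cfg else None}): {'; '.join(errs)}"
                )


@dataclass(frozen=True)
class MappingRule:
    """One fully expanded, direction-specific mapping rule."""

    id: str
    system: str
    direction: str
    lossy: bool
    anchor: str
    # foreign -> uDISE
    source_token: Optional[ForeignToken] = None
    constraints: tuple[SiteConstraint, ...] = ()
    disjunction: bool = False
    # uDISE -> foreign
    source_cell: Optional[tuple[Structure, int, Optional[Configuration]]] = None
    targets: tuple[ForeignToken, ...] = ()

    def matches_token(self, token: ForeignToken) -> bool:
        """Does this foreign->uDISE rule apply to *token*?

        A token without configuration matches any configuration variant of
        its site's rules (degree-0 widening).
        """
        if self.direction != FOREIGN_TO_UDISE or self.system != token.system:
            return False
        src = self.source_token
        assert src is not None
        if src.site != token.site or src.grade != token.grade:
            return False
        if token.configuration is None:
            return True  # widening: match every configuration variant
        return src.configuration == token.configuration

    def matches_cell(
        self, structure: Structure, degree: int, cfg: Optional[Configuration]
    ) -> bool:
        """Does this uDISE->foreign rule apply to the given uDISE cell?

        A degree-0 finding without configuration matches every
        configuration variant (widened candidate set).
        """
        if self.direction != UDISE_TO_FOREIGN:
            return False
        s, d, c = self.source_cell
        if s is not structure or d != degree:
            return False
        if cfg is None:
            return True  # degree-0 widening: match every variant
        return c == cfg


@dataclass
class RuleBase:
    """Expanded rules plus per-system coverage of the uDISE cell grid."""

    version: int
    rules: tuple[MappingRule, ...]
    site_excluded: dict[str, frozenset[Structure]]
    by_id: dict[str, MappingRule] = field(default_factory=dict)

    def __post_init__(self):
        for rule in self.rules:
            if rule.id in self.by_id:
                raise RuleBaseError(f"duplicate rule id {rule.id}")
            self.by_id[rule.id] = rule

    @property
    def systems(self) -> tuple[str, ...]:
        return SYSTEMS

    def rules_for(self, system: str, direction: str) -> list[MappingRule]:
        if system not in SYSTEMS:
            raise RuleBaseError(f"unknown system {system!r}")
        if direction not in (FOREIGN_TO_UDISE, UDISE_TO_FOREIGN):
            raise RuleBaseError(f"unknown direction {direction!r}")
        return [r for r in self.rules
                if r.system == system and r.direction == direction]

    def match_token(self, token: ForeignToken) -> list[MappingRule]:
        return [r for r in self.rules if r.matches_token(token)]

    def match_cell(
        self, system: str, structure: Structure, degree: int,
        cfg: Optional[Configuration],
    ) -> list[MappingRule]:
        return [
            r for r in self.rules_for(system, UDISE_TO_FOREIGN)
            if r.matches_cell(structure, degree, cfg)
        ]

    def coverage(
        self, system: str, structure: Structure, degree: int,
        cfg: Optional[Configuration],
    ) -> str:
        """COVERED, "X" (site not considered) or "-" (configuration not
        considered) for one uDISE cell, derived from the rules."""
        if self.match_cell(system, structure, degree, cfg):
            return COVERED
        if structure in self.site_excluded.get(system, frozenset()):
            return SITE_EXCLUDED
        return CONFIG_EXCLUDED


def all_cells() -> list[tuple[Structure, int, Optional[Configuration]]]:
    """The 42 uDISE cells in reference-table order: canonical site order,
    configuration-major (AP, L, C), degree 0-2 within a configuration."""
    cells = []
    for s in sorted(Structure, key=lambda s: s.canonical_order):
        allowed = allowed_configurations(s)
        if not allowed:
            cells.extend((s, d, None) for d in range(3))
        else:
            for cfg in Configuration:
                if cfg in allowed:
                    cells.extend((s, d, cfg) for d in range(3))
    return cells


# ---------------------------------------------------------------------------
# Loading and expansion
# ---------------------------------------------------------------------------

_GradeSpec = Union[int, str, list, dict, None]


def _as_list(x) -> list:
    return x if isinstance(x, list) else [x]


def _pick(spec: _GradeSpec, key) -> list:
    """Resolve a per-grade/per-degree bucketed spec to an explicit list."""
    if isinstance(spec, dict):
        if key not in spec:
            raise RuleBaseError(f"bucket spec {spec} missing key {key!r}")
        return _as_list(spec[key])
    return _as_list(spec)


def _expand_constraint(raw: dict, grade) -> SiteConstraint:
    structure = Structure.from_code(str(raw["structure"]))
    degrees_spec = raw["degrees"]
    if degrees_spec == "grade":
        degrees = [int(grade)]
    elif degrees_spec == "grade-1":
        degrees = [int(grade) - 1]
    else:
        degrees = [int(d) for d in _pick(degrees_spec, grade)]
    cfg_spec = raw.get("configurations")
    if cfg_spec is None:
        cfgs: list[Optional[Configuration]] = [None]
    elif cfg_spec == "same":
        raise RuleBaseError("'same' configuration needs a configured source")
    else:
        cfgs = [Configuration.from_code(str(c)) for c in _pick(cfg_spec, grade)]
    return SiteConstraint(
        structure, frozenset((d, c) for d in degrees for c in cfgs)
    )


def _expand_foreign_rule(rec: dict) -> list[MappingRule]:
    system = rec["system"]
    source = rec.get("source", {})
    site = source.get("site")
    grades = _as_list(source.get("grades"))
    cfg_codes = source.get("configurations")
    cfgs = [str(c) for c in cfg_codes] if cfg_codes else [None]
    multi = len(grades) > 1 or len(cfgs) > 1
    rules = []
    for cfg in cfgs:
        for grade in grades:
            token = ForeignToken(system, site, grade, cfg)
            errs = validate_foreign(token)
            if errs:
                raise RuleBaseError(f"{rec['id']}: bad source token: "
                                    + "; ".join(errs))
            constraints = []
            for raw in rec["target"]:
                c = dict(raw)
                if c.get("configurations") == "same":
                    if cfg is None:
                        raise RuleBaseError(
                            f"{rec['id']}: 'same' configuration without a "
                            f"source configuration"
                        )
                    c["configurations"] = [cfg]
                constraints.append(_expand_constraint(c, grade))
            suffix = ""
            if multi:
                suffix = f".{grade}" + (f".{cfg}" if len(cfgs) > 1 else "")
            rules.append(
                MappingRule(
                    id=rec["id"] + suffix,
                    system=system,
                    direction=FOREIGN_TO_UDISE,
                    lossy=bool(rec.get("lossy", False)),
                    anchor=rec.get("anchor", ""),
                    source_token=token,
                    constraints=tuple(constraints),
                    disjunction=bool(rec.get("disjunction", False)),
                )
            )
    return rules


def _expand_udise_rule(rec: dict) -> list[MappingRule]:
    system = rec["system"]
    source = rec["source"]
    structure = Structure.from_code(str(source["structure"]))
    degrees = [int(d) for d in _as_list(source["degrees"])]
    cfg_codes = source.get("configurations")
    cfgs: list[Optional[Configuration]] = (
        [Configuration.from_code(str(c)) for c in cfg_codes]
        if cfg_codes else [None]
    )
    multi = len(degrees) > 1 or len(cfgs) > 1
    rules = []
    for cfg in cfgs:
        for degree in degrees:
            if cfg is not None and cfg not in allowed_configurations(structure):
                raise RuleBaseError(
                    f"{rec['id']}: configuration {cfg.code} invalid for "
                    f"{structure.code}"
                )
            tokens = []
            for raw in rec["target"]:
                grade_spec = raw.get("grade")
                if grade_spec == "degree":
                    grades = [degree]
                elif grade_spec == "degree+1":
                    grades = [degree + 1]
                else:
                    grades = _pick(grade_spec, degree)
                tcfg_spec = raw.get("configuration")
                if tcfg_spec == "same":
                    if cfg is None:
                        raise RuleBaseError(
                            f"{rec['id']}: 'same' target configuration "
                            f"without source configuration"
                        )
                    tcfg = cfg.code
                else:
                    tcfg = str(tcfg_spec) if tcfg_spec is not None else None
                for g in grades:
                    token = ForeignToken(system, raw.get("site"), g, tcfg)
                    errs = validate_foreign(token)
                    if errs:
                        raise RuleBaseError(
                            f"{rec['id']}: bad target token: " + "; ".join(errs)
                        )
                    tokens.append(token)
            suffix = ""
            if multi:
                suffix = f".{degree}" + (f".{cfg.code}" if len(cfgs) > 1 else "")
            rules.append(
                MappingRule(
                    id=rec["id"] + suffix,
                    system=system,
                    direction=UDISE_TO_FOREIGN,
                    lossy=bool(rec.get("lossy", False)),
                    anchor=rec.get("anchor", ""),
                    source_cell=(structure, degree, cfg),
                    targets=tuple(tokens),
                )
            )
    return rules


def default_rules_path() -> Path:
    return Path(resources.files("udise") / "data" / "rules.yaml")


def load_rule_base(path: Union[str, Path, None] = None) -> RuleBase:
    """Load and expand a rule file; fails loudly on any schema violation,
    unknown vocabulary code, invalid constraint or duplicate rule id."""
    path = Path(path) if path is not None else default_rules_path()
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict) or "rules" not in doc:
        raise RuleBaseError(f"{path}: not a rule file (missing 'rules')")
    systems = doc.get("systems", [])
    if sorted(systems) != sorted(SYSTEMS):
        raise RuleBaseError(f"{path}: systems {systems} != {list(SYSTEMS)}")
    site_excluded = {
        sys: frozenset(Structure.from_code(str(c)) for c in codes)
        for sys, codes in doc.get("site_excluded", {}).items()
    }
    rules: list[MappingRule] = []
    for rec in doc["rules"]:
        try:
            if rec.get("system") not in SYSTEMS:
                raise RuleBaseError(f"unknown system {rec.get('system')!r}")
            direction = rec.get("direction")
            if direction == FOREIGN_TO_UDISE:
                rules.extend(_expand_foreign_rule(rec))
            elif direction == UDISE_TO_FOREIGN:
                rules.extend(_expand_udise_rule(rec))
            else:
                raise RuleBaseError(f"unknown direction {direction!r}")
        except (KeyError, TypeError) as err:
            raise RuleBaseError(
                f"{path}: malformed rule {rec.get('id', '?')}: {err!r}"
            ) from err
        except RuleBaseError as err:
            raise RuleBaseError(
                f"{path}: rule {rec.get('id', '?')}: {err}"
            ) from err
    return RuleBase(
        version=int(doc.get("version", 1)),
        rules=tuple(rules),
        site_excluded=site_excluded,
    )
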