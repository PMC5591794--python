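"""Core vocabulary and data model for the uDISE classification of
drug-induced sedation endoscopy (DISE) findings.

The model grades upper-airway obstruction at seven anatomical sites
(nose, velum, tonsils, lateral pharyngeal wall/oropharynx, tongue base,
epiglottis, larynx), each with a degree of obstruction (0 none, 1 partial,
2 complete) and, where anatomically meaningful, a configuration of collapse
(anteroposterior, lateral, concentric).  A complete examination is a
:class:`UdiseProfile` — exactly one finding per site — and its severity
index is the sum of the seven degrees (0–14).
"""

from __future__ import annotations

import enum
import json
from dataclasses import dataclass
from typing import Iterable, Optional


class Structure(enum.Enum):
    """The seven anatomical sites, in canonical reporting order."""

    NOSE = ("N", "nose", 1)
    VELUM = ("V", "velum", 2)
    TONSILS = ("Ts", "tonsils", 3)
    OROPHARYNX = ("O", "lateral pharyngeal wall/oropharynx", 4)
    TONGUE_BASE = ("Tb", "tongue base", 5)
    EPIGLOTTIS = ("E", "epiglottis", 6)
    LARYNX = ("L", "larynx", 7)

    def __init__(self, code: str, label: str, canonical_order: int):
        self.code = code
        self.label = label
        self.canonical_order = canonical_order

    @classmethod
    def from_code(cls, code: str) -> "Structure":
        for member in cls:
            if member.code == code:
                return member
        raise VocabularyError(f"unknown structure code {code!r}")

    def __repr__(self) -> str:  # compact in test output
        return f"Structure.{self.name}"


class Configuration(enum.Enum):
    """Configuration (direction) of airway collapse."""

    AP = ("AP", "anteroposterior")
    L = ("L", "lateral")
    C = ("C", "concentric")

    def __init__(self, code: str, label: str):
        self.code = code
        self.label = label

    @classmethod
    def from_code(cls, code: str) -> "Configuration":
        for member in cls:
            if member.code == code:
                return member
        raise VocabularyError(f"unknown configuration code {code!r}")

    def __repr__(self) -> str:
        return f"Configuration.{self.name}"


#: Degree value -> (label, percent band of airway narrowing).
DEGREES: dict[int, tuple[str, str]] = {
    0: ("none", "<50%"),
    1: ("partial", "50-75%"),
    2: ("complete", ">75%"),
}

#: Configurations in which each site is observed to collapse.  The nose
#: (static obstruction) and larynx carry no configuration; the tonsils and
#: lateral pharyngeal wall collapse laterally only; the epiglottis folds
#: anteroposteriorly or laterally.
_ALLOWED: dict[Structure, frozenset[Configuration]] = {
    Structure.NOSE: frozenset(),
    Structure.VELUM: frozenset({Configuration.AP, Configuration.L, Configuration.C}),
    Structure.TONSILS: frozenset({Configuration.L}),
    Structure.OROPHARYNX: frozenset({Configuration.AP, Configuration.L, Configuration.C}),
    Structure.TONGUE_BASE: frozenset({Configuration.AP, Configuration.L, Configuration.C}),
    Structure.EPIGLOTTIS: frozenset({Configuration.AP, Configuration.L}),
    Structure.LARYNX: frozenset(),
}


class VocabularyError(ValueError):
    """An unknown structure/degree/configuration code."""


class ProfileError(ValueError):
    """A profile that is not exactly one valid finding per site."""


def allowed_configurations(structure: Structure) -> frozenset[Configuration]:
    """Configurations a site may collapse in (empty for nose and larynx)."""
    if not isinstance(structure, Structure):
        raise VocabularyError(f"unknown structure {structure!r}")
    return _ALLOWED[structure]


@dataclass(frozen=True, order=False)
class SiteFinding:
    """One site's finding: degree of obstruction plus optional configuration.

    Configuration is mandatory at degree >= 1 for sites that admit one,
    optional at degree 0 (canonical notation omits it there; the crosswalk
    keeps it when a source system supplies it), and forbidden for the nose
    and larynx.
    """

    structure: Structure
    degree: int
    configuration: Optional[Configuration] = None

    def violations(self) -> list[str]:
        errs: list[str] = []
        if self.degree not in DEGREES:
            errs.append(f"{self.structure.code}: degree {self.degree} not in 0..2")
            return errs
        allowed = allowed_configurations(self.structure)
        if self.configuration is not None:
            if not allowed:
                errs.append(
                    f"{self.structure.code}: site carries no configuration "
                    f"(got {self.configuration.code})"
                )
            elif self.configuration not in allowed:
                errs.append(
                    f"{self.structure.code}: configuration {self.configuration.code} "
                    f"not allowed (allowed: "
                    f"{sorted(c.code for c in allowed)})"
                )
        elif self.degree >= 1 and allowed:
            errs.append(
                f"{self.structure.code}: configuration required at degree "
                f"{self.degree}"
            )
        return errs

    @property
    def is_valid(self) -> bool:
        return not self.violations()


def validate_finding(finding: SiteFinding) -> list[str]:
    """Return the list of broken invariants (empty list means valid)."""
    return finding.violations()


class UdiseProfile:
    """A full examination: exactly one valid finding per anatomical site."""

    __slots__ = ("_findings",)

    def __init__(self, findings: Iterable[SiteFinding]):
        by_site: dict[Structure, SiteFinding] = {}
        problems: list[str] = []
        for f in findings:
            if f.structure in by_site:
                problems.append(f"duplicate: {f.structure.code}")
                continue
            by_site[f.structure] = f
            problems.extend(f.violations())
        for s in Structure:
            if s not in by_site:
                problems.append(f"missing: {s.code}")
        if problems:
            raise ProfileError("; ".join(problems))
        self._findings = tuple(
            by_site[s] for s in sorted(Structure, key=lambda s: s.canonical_order)
        )

    @property
    def findings(self) -> tuple[SiteFinding, ...]:
        return self._findings

    def __getitem__(self, structure: Structure) -> SiteFinding:
        return self._findings[structure.canonical_order - 1]

    def __iter__(self):
        return iter(self._findings)

    def __eq__(self, other) -> bool:
        return isinstance(other, UdiseProfile) and self._findings == other._findings

    def __hash__(self) -> int:
        return hash(self._findings)

    def __repr__(self) -> str:
        parts = ", ".join(
            f"{f.structure.code}={f.degree}"
            + (f.configuration.code if f.configuration else "")
            for f in self._findings
        )
        return f"UdiseProfile({parts})"

    @property
    def severity_index(self) -> int:
        return sum(f.degree for f in self._findings)


def make_profile(findings: Iterable[SiteFinding]) -> UdiseProfile:
    """Build a canonical-ordered profile; raises ProfileError naming every
    missing/duplicate/invalid site."""
    return UdiseProfile(findings)


def severity_index(profile: UdiseProfile) -> int:
    """Severity index: the sum of the seven per-site obstruction degrees.

    Ranges from 0 (patent airway) to 14 (complete obstruction everywhere);
    configuration does not contribute.
    """
    return profile.severity_index


def normal_profile() -> UdiseProfile:
    """The all-degree-0 (patent airway) profile."""
    return UdiseProfile(SiteFinding(s, 0) for s in Structure)


def vocabulary() -> dict:
    """The model vocabulary as a JSON-serializable document.

    Single source of truth for the rule file and cohort I/O schemas.
    """
    return {
        "structures": [
            {
                "code": s.code,
                "label": s.label,
                "canonical_order": s.canonical_order,
                "allowed_configurations": sorted(
                    c.code for c in allowed_configurations(s)
                ),
            }
            for s in sorted(Structure, key=lambda s: s.canonical_order)
        ],
        "degrees": [
            {"value": v, "label": label, "band": band}
            for v, (label, band) in DEGREES.items()
        ],
        "configurations": [{"code": c.code, "label": c.label} for c in Configuration],
    }


def vocabulary_json(indent: int = 2) -> str:
    return json.dumps(vocabulary(), indent=indent)
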