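"""Synthetic cohorts and packaged worked-example fixtures.

The cohort generator draws each site's obstruction degree independently
from a configurable categorical distribution and, at degree >= 1, a
configuration from the site's allowed set.  Site independence is a
deliberate simplification: no joint prevalence data exist for the model,
so simulated cohorts exercise the scoring and crosswalk machinery rather
than emulate real obstructive-sleep-apnea case mix.

Defaults put half the patients at degree 0 per site (p = 0.5/0.3/0.2 for
none/partial/complete) with configurations uniform over each site's
allowed set, giving an expected severity index of 7 x 0.7 = 4.9.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from importlib import resources

from .core import (
    Configuration,
    SiteFinding,
    Structure,
    UdiseProfile,
    allowed_configurations,
)

DEFAULT_DEGREE_PROBS = (0.5, 0.3, 0.2)

_TOL = 1e-9


def _uniform_config_probs(structure: Structure) -> dict[Configuration, float]:
    allowed = sorted(allowed_configurations(structure), key=lambda c: c.code)
    if not allowed:
        return {}
    return {c: 1.0 / len(allowed) for c in allowed}


@dataclass
class SimulationConfig:
    """Seeded cohort parameters; probability triples must each sum to 1."""

    n_patients: int = 100
    seed: int = 0
    degree_probs: dict[Structure, tuple[float, float, float]] = field(
        default_factory=lambda: {s: DEFAULT_DEGREE_PROBS for s in Structure}
    )
    config_probs: dict[Structure, dict[Configuration, float]] = field(
        default_factory=lambda: {
            s: _uniform_config_probs(s) for s in Structure
        }
    )

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        for s in Structure:
            triple = self.degree_probs.get(s)
            if triple is None or len(triple) != 3:
                raise ValueError(f"{s.code}: need a (p0,p1,p2) triple")
            if any(p < 0 for p in triple) or abs(sum(triple) - 1.0) > _TOL:
                raise ValueError(f"{s.code}: degree probabilities {triple} "
                                 f"do not sum to 1")
            allowed = allowed_configurations(s)
            cmap = self.config_probs.get(s, {})
            if allowed:
                if set(cmap) - allowed:
                    raise ValueError(f"{s.code}: configuration probabilities "
                                     f"outside allowed set")
                if abs(sum(cmap.values()) - 1.0) > _TOL:
                    raise ValueError(f"{s.code}: configuration probabilities "
                                     f"do not sum to 1")
            elif cmap:
                raise ValueError(f"{s.code}: site carries no configuration")


def simulate_cohort(config: SimulationConfig) -> list[UdiseProfile]:
    """Draw a seeded cohort of valid profiles (same config => identical
    cohort)."""
    config.validate()
    rng = random.Random(config.seed)
    cohort = []
    sites = sorted(Structure, key=lambda s: s.canonical_order)
    for _ in range(config.n_patients):
        findings = []
        for s in sites:
            degree = rng.choices((0, 1, 2), weights=config.degree_probs[s])[0]
            cfg = None
            cmap = config.config_probs.get(s, {})
            if degree >= 1 and cmap:
                codes = sorted(cmap, key=lambda c: c.code)
                cfg = rng.choices(codes, weights=[cmap[c] for c in codes])[0]
            findings.append(SiteFinding(s, degree, cfg))
        cohort.append(UdiseProfile(findings))
    return cohort


#: Worked score strings with their severity indices.
WORKED_EXAMPLES: dict[str, tuple[str, int]] = {
    "normal": ("N0V0Ts0O0Tb0E0L0", 0),
    "tonsillar": ("N0V0Ts1LO0Tb0E0L0", 1),
    "palatal_snoring": ("N0V1APTs0O0Tb0E0L0", 1),
    "epiglottic": ("N0V0Ts0O0Tb0E2APL0", 2),
    "multilevel": ("N0V0Ts2LO0Tb2APE0L0", 4),
}


def reference_table_fixture() -> list[dict]:
    """The hand-encoded referential classification table, one dict per
    uDISE cell with the four systems' entries."""
    import csv
    import io

    text = (resources.files("udise") / "data" / "reference_table.csv") \
        .read_text(encoding="utf-8")
    return list(csv.DictReader(io.StringIO(text)))


def paper_fixtures() -> dict:
    """Named worked examples: score strings with expected severities, and
    the hand-encoded reference-table grid."""
    return {
        "worked_examples": dict(WORKED_EXAMPLES),
        "reference_table": reference_table_fixture(),
    }
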