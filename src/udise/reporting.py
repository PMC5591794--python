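"""Reference-table regeneration and cohort-level summaries.

The referential classification table lists every uDISE cell (42 rows:
site x degree x configuration, configuration-major within a site) against
its candidate findings in each of the four foreign systems, with "X"
marking sites a system does not consider anatomically and "-" marking
configurations it does not consider.  The table is a pure function of the
rule base, so regenerating it and diffing against the packaged
hand-encoded fixture exercises every uDISE->foreign rule at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .core import Configuration, SiteFinding, Structure, UdiseProfile
from .engine import FLAG_CONFIG_EXCLUDED, FLAG_SITE_EXCLUDED, convert_finding
from .notation import SYSTEMS, format_foreign
from .rules import CONFIG_EXCLUDED, SITE_EXCLUDED, RuleBase, all_cells


@dataclass(frozen=True)
class ReferenceTableRow:
    structure: Structure
    degree: int
    configuration: Optional[Configuration]
    entries: dict  # system -> cell text ("G3/G4", "X" or "-")

    @property
    def udise_label(self) -> str:
        cfg = self.configuration.code if self.configuration else ""
        return f"{self.structure.code}{self.degree}{cfg}"


def generate_reference_table(rule_base: RuleBase) -> list[ReferenceTableRow]:
    """Derive the full referential table from the rule base (deterministic;
    byte-identical across runs)."""
    rows = []
    for structure, degree, cfg in all_cells():
        finding = SiteFinding(structure, degree, cfg)
        entries = {}
        for system in SYSTEMS:
            tokens, flag, _ = convert_finding(finding, system, rule_base)
            if flag == FLAG_SITE_EXCLUDED:
                entries[system] = SITE_EXCLUDED
            elif flag == FLAG_CONFIG_EXCLUDED:
                entries[system] = CONFIG_EXCLUDED
            else:
                entries[system] = "/".join(
                    sorted(format_foreign(t) for t in tokens)
                )
        rows.append(ReferenceTableRow(structure, degree, cfg, entries))
    return rows


def table_to_frame(rows: list[ReferenceTableRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"udise": r.udise_label, **r.entries} for r in rows],
        columns=["udise", *SYSTEMS],
    )


def table_to_csv(rows: list[ReferenceTableRow]) -> str:
    return table_to_frame(rows).to_csv(index=False)


def table_to_text(rows: list[ReferenceTableRow]) -> str:
    """Aligned plain-text rendering."""
    frame = table_to_frame(rows)
    widths = {
        col: max(len(col), int(frame[col].str.len().max()))
        for col in frame.columns
    }
    lines = ["  ".join(col.ljust(widths[col]) for col in frame.columns)]
    for _, row in frame.iterrows():
        lines.append("  ".join(str(row[c]).ljust(widths[c])
                               for c in frame.columns))
    return "\n".join(lines) + "\n"


def cohort_summary(profiles: list[UdiseProfile]) -> dict:
    """Per-site degree frequencies, severity distribution and the count of
    multilevel obstructions (>= 2 sites at degree >= 1)."""
    if not profiles:
        raise ValueError("empty cohort")
    n = len(profiles)
    site_freq = {
        s.code: {d: 0 for d in range(3)}
        for s in sorted(Structure, key=lambda s: s.canonical_order)
    }
    severities = []
    multilevel = 0
    for p in profiles:
        for f in p:
            site_freq[f.structure.code][f.degree] += 1
        severities.append(p.severity_index)
        if sum(1 for f in p if f.degree >= 1) >= 2:
            multilevel += 1
    hist: dict[int, int] = {}
    for s in severities:
        hist[s] = hist.get(s, 0) + 1
    return {
        "n": n,
        "site_degree_frequencies": site_freq,
        "severity": {
            "min": min(severities),
            "max": max(severities),
            "mean": sum(severities) / n,
            "histogram": dict(sorted(hist.items())),
        },
        "multilevel_count": multilevel,
    }
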