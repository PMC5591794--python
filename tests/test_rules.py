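"""Rule-base loading, expansion and structural properties."""

import textwrap

import pytest
import yaml

from udise.core import Configuration, Structure
from udise.notation import SYSTEMS, ForeignToken
from udise.rules import (
    FOREIGN_TO_UDISE,
    UDISE_TO_FOREIGN,
    RuleBaseError,
    all_cells,
    load_rule_base,
)


def test_default_rule_base_covers_four_systems(rule_base):
    assert set(rule_base.systems) == set(SYSTEMS)
    for system in SYSTEMS:
        assert rule_base.rules_for(system, FOREIGN_TO_UDISE)
        assert rule_base.rules_for(system, UDISE_TO_FOREIGN)


def test_cell_grid_enumeration():
    cells = all_cells()
    assert len(cells) == 42
    # configuration-major within a site: V AP degrees before V L degrees
    v_rows = [(d, c.code if c else None) for s, d, c in cells
              if s is Structure.VELUM]
    assert v_rows == [(0, "AP"), (1, "AP"), (2, "AP"),
                      (0, "L"), (1, "L"), (2, "L"),
                      (0, "C"), (1, "C"), (2, "C")]


def test_rules_for_contains_published_equations(rule_base):
    vote = {r.id for r in rule_base.rules_for("VOTE", FOREIGN_TO_UDISE)}
    assert {"VOTE.O.0", "VOTE.O.1", "VOTE.O.2"} <= vote

    nohl_rev = rule_base.by_id["U2NOHL.V.AP.1"]
    assert nohl_rev.source_cell == (Structure.VELUM, 1, Configuration.AP)
    assert [str(t) for t in nohl_rev.targets] == ["OAP3"]

    veer = rule_base.by_id["PTLTBE.P.3"]
    cells = next(iter(veer.constraints)).allowed
    assert {(d, c.code) for d, c in cells} == {(1, "C"), (2, "C")}


def test_every_expanded_rule_is_model_valid(rule_base):
    from udise.core import SiteFinding
    from udise.notation import validate_foreign

    for rule in rule_base.rules:
        if rule.direction == FOREIGN_TO_UDISE:
            assert validate_foreign(rule.source_token) == []
            for constraint in rule.constraints:
                assert constraint.allowed
                for degree, cfg in constraint.allowed:
                    assert SiteFinding(
                        constraint.structure, degree, cfg
                    ).is_valid
        else:
            s, d, c = rule.source_cell
            assert SiteFinding(s, d, c).is_valid
            assert rule.targets
            for token in rule.targets:
                assert validate_foreign(token) == []


def test_rule_ids_unique(rule_base):
    ids = [r.id for r in rule_base.rules]
    assert len(ids) == len(set(ids))


def test_vote_one_to_one_except_oropharynx(rule_base):
    """VOTE velum, tongue base and epiglottis rules are one-to-one on
    (degree, configuration); only the oropharynx rule is one-to-many."""
    for rule in rule_base.rules_for("VOTE", FOREIGN_TO_UDISE):
        token = rule.source_token
        if token.site == "O":
            sites = {c.structure for c in rule.constraints}
            assert sites == {Structure.OROPHARYNX, Structure.TONSILS}
            assert rule.disjunction
        else:
            assert len(rule.constraints) == 1
            [constraint] = rule.constraints
            assert constraint.allowed == {
                (token.grade, Configuration.from_code(token.configuration))
            }


def test_nohl_grade_bucketing_is_monotone(rule_base):
    """For fixed NOHL site/configuration, a higher grade never maps to a
    lower uDISE degree."""
    combos = {}
    for rule in rule_base.rules_for("NOHL", FOREIGN_TO_UDISE):
        t = rule.source_token
        if not isinstance(t.grade, int):
            continue
        degrees = {d for c in rule.constraints for d, _ in c.allowed}
        combos.setdefault((t.site, t.configuration), {})[t.grade] = degrees
    assert combos  # N, O(T/C), H(AP/T/C), TS
    for (site, cfg), by_grade in combos.items():
        grades = sorted(by_grade)
        for g1, g2 in zip(grades, grades[1:]):
            assert min(by_grade[g2]) >= min(by_grade[g1]), (site, cfg)
            assert max(by_grade[g2]) >= max(by_grade[g1]), (site, cfg)


def _write_rules(tmp_path, body: str):
    path = tmp_path / "rules.yaml"
    path.write_text(
        textwrap.dedent(
            """\
            version: 1
            systems: [PRINGLE, VOTE, NOHL, PTLTBE]
            site_excluded: {}
            rules:
            """
        )
        + textwrap.dedent(body)
    )
    return path


def test_load_rejects_out_of_vocabulary_grade(tmp_path):
    path = _write_rules(
        tmp_path,
        """\
          - id: VOTE.BAD
            system: VOTE
            direction: foreign_to_udise
            source: {site: "V", grades: [5], configurations: [AP]}
            target:
              - {structure: "V", degrees: grade, configurations: same}
        """,
    )
    with pytest.raises(RuleBaseError, match="out of range"):
        load_rule_base(path)


def test_load_rejects_duplicate_ids(tmp_path):
    path = _write_rules(
        tmp_path,
        """\
          - id: PRINGLE.G3
            system: PRINGLE
            direction: foreign_to_udise
            source: {grades: [3]}
            target:
              - {structure: "O", degrees: [2], configurations: [AP, L, C]}
          - id: PRINGLE.G3
            system: PRINGLE
            direction: foreign_to_udise
            source: {grades: [3]}
            target:
              - {structure: "O", degrees: [2], configurations: [AP, L, C]}
        """,
    )
    with pytest.raises(RuleBaseError, match="duplicate rule id"):
        load_rule_base(path)


def test_load_rejects_invalid_constraint(tmp_path):
    path = _write_rules(
        tmp_path,
        """\
          - id: NOHL.BAD
            system: NOHL
            direction: foreign_to_udise
            source: {site: "TS", grades: [3]}
            target:
              - {structure: "Ts", degrees: [2], configurations: [AP]}
        """,
    )
    with pytest.raises(RuleBaseError, match="invalid cell"):
        load_rule_base(path)


def test_coverage_markers_distinguish_site_and_configuration(rule_base):
    assert rule_base.coverage("PRINGLE", Structure.NOSE, 1, None) == "X"
    assert rule_base.coverage(
        "PTLTBE", Structure.TONGUE_BASE, 2, Configuration.L) == "-"
    assert rule_base.coverage("NOHL", Structure.TONSILS, 0, Configuration.L) == "-"
    assert rule_base.coverage("NOHL", Structure.NOSE, 0, None) == "covered"
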