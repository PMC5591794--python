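"""Crosswalk engine: set-valued conversion, severity bounds, round trips."""

import pytest

from conftest import all_foreign_tokens, brute_force_severity_range

from udise.core import (
    Configuration,
    SiteFinding,
    Structure,
    make_profile,
    normal_profile,
)
from udise.engine import (
    AMBIGUOUS,
    EXACT,
    FLAG_CONFIG_EXCLUDED,
    FLAG_SITE_EXCLUDED,
    UNMAPPED_GRADE,
    ContradictionError,
    ConversionError,
    ConversionResult,
    from_udise,
    round_trip_containment,
    severity_range,
    to_udise,
)
from udise.notation import ForeignToken, parse_foreign
from udise.rules import FOREIGN_TO_UDISE


def cellset(result, code):
    s = Structure.from_code(code)
    return {(d, c.code if c else None) for d, c in result.candidates[s]}


def one_site_profile(code, degree, cfg=None):
    s = Structure.from_code(code)
    findings = [
        SiteFinding(s, degree, Configuration.from_code(cfg) if cfg else None)
        if x is s else SiteFinding(x, 0)
        for x in Structure
    ]
    return make_profile(findings)


class TestToUdise:
    def test_vote_oropharynx_union_is_ambiguous(self, rule_base):
        result = to_udise(parse_foreign("VOTE", "O2L"), rule_base)
        assert cellset(result, "O") == {(2, "L"), (0, None)}
        assert cellset(result, "Ts") == {(2, "L"), (0, None)}
        assert result.flags[Structure.OROPHARYNX] == AMBIGUOUS
        assert result.flags[Structure.TONSILS] == AMBIGUOUS
        [group] = result.disjunctions
        assert {s.code for s, _ in group.members} == {"O", "Ts"}

    def test_nohl_transversal_grade4_is_exact(self, rule_base):
        result = to_udise(parse_foreign("NOHL", "Ot4"), rule_base)
        assert cellset(result, "O") == {(2, "L")}
        assert result.flags[Structure.OROPHARYNX] == EXACT
        assert "NOHL.OT.4" in result.provenance

    def test_nohl_nose_grade3_is_exact(self, rule_base):
        result = to_udise(parse_foreign("NOHL", "N3"), rule_base)
        assert cellset(result, "N") == {(1, None)}
        assert result.flags[Structure.NOSE] == EXACT

    def test_pringle_g5_spans_tongue_base_and_epiglottis(self, rule_base):
        result = to_udise(parse_foreign("PRINGLE", "G5"), rule_base)
        assert cellset(result, "Tb") == {
            (d, c) for d in range(3) for c in ("AP", "L", "C")
        }
        assert cellset(result, "E") == {
            (d, c) for d in range(3) for c in ("AP", "L")
        }
        assert result.flags[Structure.TONGUE_BASE] == AMBIGUOUS
        assert Structure.VELUM in result.unconstrained

    def test_ptltbe_epiglottis_grade2_is_ambiguous(self, rule_base):
        result = to_udise(parse_foreign("PTLTBE", "E2"), rule_base)
        assert cellset(result, "E") == {(1, "AP"), (2, "AP")}
        assert result.flags[Structure.EPIGLOTTIS] == AMBIGUOUS

    def test_nohl_unmapped_tonsil_grades_constrain_nothing(self, rule_base):
        result = to_udise(parse_foreign("NOHL", "Ts2"), rule_base)
        assert result.candidates == {}
        assert result.flags[Structure.TONSILS] == UNMAPPED_GRADE

    def test_mixed_systems_rejected(self, rule_base):
        tokens = [ForeignToken("VOTE", "V", 1, "AP"),
                  ForeignToken("PRINGLE", None, 1)]
        with pytest.raises(ConversionError, match="mixed systems"):
            to_udise(tokens, rule_base)

    def test_contradictory_tokens_name_site_and_rules(self, rule_base):
        tokens = parse_foreign("VOTE", "V1AP V2AP")
        with pytest.raises(ContradictionError, match="V"):
            to_udise(tokens, rule_base)

    def test_all_tokens_produce_model_valid_candidates(self, rule_base):
        for token in all_foreign_tokens():
            result = to_udise([token], rule_base)
            for s, cells in result.candidates.items():
                for degree, cfg in cells:
                    assert SiteFinding(s, degree, cfg).is_valid, (token, s)


class TestFromUdise:
    def test_velum_to_vote_is_exact(self, rule_base):
        result = from_udise(one_site_profile("V", 1, "AP"), "VOTE", rule_base)
        assert {str(t) for t in result.foreign_candidates[Structure.VELUM]} \
            == {"V1AP"}
        assert result.flags[Structure.VELUM] == EXACT

    def test_complete_oropharynx_to_pringle_is_g3_or_g4(self, rule_base):
        result = from_udise(one_site_profile("O", 2, "L"), "PRINGLE", rule_base)
        assert {str(t) for t in result.foreign_candidates[Structure.OROPHARYNX]} \
            == {"G3", "G4"}
        assert result.flags[Structure.OROPHARYNX] == AMBIGUOUS

    def test_velum_to_nohl_uses_reverse_equation(self, rule_base):
        result = from_udise(one_site_profile("V", 1, "AP"), "NOHL", rule_base)
        assert {str(t) for t in result.foreign_candidates[Structure.VELUM]} \
            == {"OAP3"}

    def test_nose_is_site_excluded_for_pringle(self, rule_base):
        result = from_udise(one_site_profile("N", 1), "PRINGLE", rule_base)
        assert result.flags[Structure.NOSE] == FLAG_SITE_EXCLUDED
        assert Structure.NOSE not in result.foreign_candidates

    def test_lateral_tongue_base_is_config_excluded_for_ptltbe(self, rule_base):
        result = from_udise(one_site_profile("Tb", 2, "L"), "PTLTBE", rule_base)
        assert result.flags[Structure.TONGUE_BASE] == FLAG_CONFIG_EXCLUDED

    def test_degree_zero_without_configuration_widens(self, rule_base):
        result = from_udise(normal_profile(), "VOTE", rule_base)
        assert {str(t) for t in result.foreign_candidates[Structure.VELUM]} \
            == {"V0AP", "V0L", "V0C"}
        assert result.flags[Structure.VELUM] == AMBIGUOUS

    def test_unknown_system_rejected(self, rule_base):
        with pytest.raises(ConversionError, match="unknown system"):
            from_udise(normal_profile(), "BOGUS", rule_base)


class TestSeverityRange:
    def test_fully_constrained_exact_result(self, rule_base):
        result = ConversionResult(
            direction=FOREIGN_TO_UDISE,
            system="NOHL",
            candidates={
                s: frozenset({(2, Configuration.L)})
                if s is Structure.OROPHARYNX else frozenset({(0, None)})
                for s in Structure
            },
        )
        assert severity_range(result) == (2, 2)

    def test_pringle_g5_spans_full_range(self, rule_base):
        result = to_udise(parse_foreign("PRINGLE", "G5"), rule_base)
        assert severity_range(result) == (0, 14)

    def test_vote_union_with_other_sites_zero(self, rule_base):
        """O_k 2 L means oropharynx or tonsils (not necessarily both)
        collapse completely: severity 2 to 4 when all else is patent."""
        converted = to_udise(parse_foreign("VOTE", "O2L"), rule_base)
        result = ConversionResult(
            direction=FOREIGN_TO_UDISE,
            system="VOTE",
            candidates={
                **{s: frozenset({(0, None)}) for s in Structure},
                Structure.OROPHARYNX: converted.candidates[Structure.OROPHARYNX],
                Structure.TONSILS: converted.candidates[Structure.TONSILS],
            },
            disjunctions=converted.disjunctions,
        )
        assert severity_range(result) == (2, 4)
        assert brute_force_severity_range(result) == (2, 4)

    def test_wrong_direction_rejected(self, rule_base):
        result = from_udise(normal_profile(), "VOTE", rule_base)
        with pytest.raises(ConversionError):
            severity_range(result)

    def test_matches_brute_force_on_every_single_token(self, rule_base):
        for token in all_foreign_tokens():
            result = to_udise([token], rule_base)
            assert severity_range(result) == \
                brute_force_severity_range(result), token


class TestRoundTrip:
    def test_vote_round_trip_contains_every_covered_cell(self, rule_base):
        for code, degree, cfg in [("V", d, c) for d in range(3)
                                  for c in ("AP", "L", "C")] + \
                [("Ts", d, "L") for d in range(3)] + \
                [("O", d, "L") for d in range(3)] + \
                [("Tb", d, "AP") for d in range(3)] + \
                [("E", d, c) for d in range(3) for c in ("AP", "L")]:
            profile = one_site_profile(code, degree, cfg)
            verdict = round_trip_containment(profile, "VOTE", rule_base)
            assert verdict.per_site[Structure.from_code(code)] == "contained"

    def test_nohl_velum_asymmetry_is_not_contained(self, rule_base):
        """uDISE velum maps forward to the NOHL palatal oropharynx level,
        but no NOHL equation maps that level back to the velum."""
        profile = one_site_profile("V", 1, "AP")
        verdict = round_trip_containment(profile, "NOHL", rule_base)
        assert verdict.per_site[Structure.VELUM] == "not_contained"
        assert not verdict

    def test_all_zero_profile_contained_via_ptltbe(self, rule_base):
        verdict = round_trip_containment(normal_profile(), "PTLTBE", rule_base)
        covered = [s for s, f in verdict.per_site.items()
                   if f in ("contained", "not_contained")]
        assert covered
        assert all(verdict.per_site[s] == "contained" for s in covered)


def test_result_serializes_to_json(rule_base):
    result = to_udise(parse_foreign("VOTE", "O2L"), rule_base)
    doc = result.to_json(rule_base)
    assert doc["direction"] == FOREIGN_TO_UDISE
    assert doc["candidates"]["O"] == [
        {"degree": 0, "configuration": None},
        {"degree": 2, "configuration": "L"},
    ]
    assert doc["provenance"][0]["rule"] == "VOTE.O.2"
    assert "O_k" in doc["provenance"][0]["anchor"]
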