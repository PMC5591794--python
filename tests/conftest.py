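import itertools

import pytest

from udise.core import Structure
from udise.notation import ForeignToken
from udise.rules import load_rule_base


@pytest.fixture(scope="session")
def rule_base():
    return load_rule_base()


def all_foreign_tokens() -> list[ForeignToken]:
    """The complete token space of the four systems (< 100 tokens)."""
    tokens = [ForeignToken("PRINGLE", None, g) for g in range(1, 6)]
    vote_cfgs = {"V": ["AP", "L", "C"], "O": ["L"], "T": ["AP"],
                 "E": ["AP", "L"]}
    for site, cfgs in vote_cfgs.items():
        for grade, cfg in itertools.product(range(3), cfgs):
            tokens.append(ForeignToken("VOTE", site, grade, cfg))
    for grade in range(1, 5):
        tokens.append(ForeignToken("NOHL", "N", grade))
        tokens.append(ForeignToken("NOHL", "TS", grade))
        for site, cfg in itertools.product("OH", ["AP", "T", "C"]):
            tokens.append(ForeignToken("NOHL", site, grade, cfg))
    tokens.append(ForeignToken("NOHL", "L", "N"))
    tokens.append(ForeignToken("NOHL", "L", "P"))
    for site in ("P", "T", "L", "Tb"):
        tokens.extend(ForeignToken("PTLTBE", site, g) for g in range(1, 4))
    tokens.extend(ForeignToken("PTLTBE", "E", g) for g in range(1, 3))
    return tokens


def brute_force_severity_range(result) -> tuple[int, int]:
    """Independent oracle: exhaustively enumerate degree vectors over the
    candidate product space (unconstrained sites range over 0-2), keep
    those satisfying every disjunction group, and report min/max sums."""
    sites = list(Structure)
    options = []
    for s in sites:
        if s in result.candidates:
            options.append(sorted({d for d, _ in result.candidates[s]}))
        else:
            options.append([0, 1, 2])
    feasible = []
    for combo in itertools.product(*options):
        assign = dict(zip(sites, combo))
        if all(
            any(assign[s] == cell[0] for s, cell in group.members)
            for group in result.disjunctions
        ):
            feasible.append(sum(combo))
    return min(feasible), max(feasible)
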