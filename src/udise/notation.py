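"""Score notation: uDISE score strings and foreign-system score tokens.

A uDISE score string lists the seven sites in canonical order, each as
site code + degree + configuration (configuration printed only at degree
>= 1), e.g. ``N0V1APTs0O0Tb0E0L0`` for simple palatal snoring.  The
separated form with ``_``, ``-`` or spaces between tokens is accepted on
input and normalised away.

Foreign tokens cover the four crosswalked systems:

* ``PRINGLE`` — a single whole-exam grade G1–G5.
* ``VOTE`` — sites V/O/T/E, degrees 0–2, configurations AP/L/C (the
  ``k`` subscript of the original notation, as in ``Vk2AP``, is accepted).
* ``NOHL`` — nose/oropharynx/hypopharynx grades 1–4 with configurations
  AP / transversal (T; ``t`` and ``L`` accepted as aliases) / C, a larynx
  N(egative)/P(ositive) flag, and a palatine tonsil grade ``TS1``–``TS4``.
* ``PTLTBE`` — palate/tonsils/lateral wall/tongue base/epiglottis,
  grades 1–3 (epiglottis 1–2), no configuration.

The one-line foreign token syntax is a convenience of this package (the
original publications print subscripted symbols, not machine strings);
the structured record form used in cohort files is authoritative.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Optional, Union

from .core import (
    Configuration,
    SiteFinding,
    Structure,
    UdiseProfile,
    allowed_configurations,
    make_profile,
)

SYSTEMS = ("PRINGLE", "VOTE", "NOHL", "PTLTBE")

_SITE_ORDER = tuple(sorted(Structure, key=lambda s: s.canonical_order))


class ScoreParseError(ValueError):
    """Malformed score string; carries the character offset of the fault."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at offset {offset})"
        super().__init__(message)


def _strip_separators(text: str) -> str:
    return re.sub(r"[\s_\-]+", "", text)


def parse_udise(text: str) -> UdiseProfile:
    """Parse a uDISE score string into a profile.

    Parsing is anchored on the fixed site order N, V, Ts, O, Tb, E, L;
    after each degree an optional configuration is matched greedily, with
    backtracking when the next site code would otherwise not follow (this
    resolves e.g. ``E0L0``, where ``L`` is the larynx site, against
    ``E2APL0``, where ``AP`` is the epiglottis configuration).
    """
    s = _strip_separators(text)
    if not s:
        raise ScoreParseError("empty score string", 0)

    def parse_site(idx: int, pos: int) -> list[SiteFinding]:
        if idx == len(_SITE_ORDER):
            if pos != len(s):
                raise ScoreParseError(f"trailing input {s[pos:]!r}", pos)
            return []
        site = _SITE_ORDER[idx]
        code = site.code
        if not s.startswith(code, pos):
            raise ScoreParseError(
                f"expected site {code!r} (sites must appear in canonical "
                f"order N,V,Ts,O,Tb,E,L)",
                pos,
            )
        pos += len(code)
        if pos >= len(s) or s[pos] not in "012":
            raise ScoreParseError(f"expected degree 0-2 after {code!r}", pos)
        degree = int(s[pos])
        pos += 1
        allowed = allowed_configurations(site)
        # Longest configuration code first so "AP" wins over a stray "A".
        options: list[Optional[Configuration]] = sorted(
            allowed, key=lambda c: -len(c.code)
        )
        if degree == 0 or not allowed:
            options.append(None)
        last_err: ScoreParseError | None = None
        for cfg in options:
            if cfg is not None and not s.startswith(cfg.code, pos):
                continue
            nxt = pos + (len(cfg.code) if cfg is not None else 0)
            try:
                rest = parse_site(idx + 1, nxt)
            except ScoreParseError as err:
                if last_err is None or (err.offset or 0) >= (last_err.offset or 0):
                    last_err = err
                continue
            return [SiteFinding(site, degree, cfg)] + rest
        if degree >= 1 and allowed and all(not s.startswith(c.code, pos) for c in allowed):
            raise ScoreParseError(
                f"configuration required for {code!r} at degree {degree}", pos
            )
        raise last_err or ScoreParseError(f"cannot parse after {code}{degree}", pos)

    return make_profile(parse_site(0, 0))


def format_udise(profile: UdiseProfile) -> str:
    """Canonical compact score string (configuration omitted at degree 0)."""
    parts = []
    for f in profile:
        token = f"{f.structure.code}{f.degree}"
        if f.degree >= 1 and f.configuration is not None:
            token += f.configuration.code
        parts.append(token)
    return "".join(parts)


# ---------------------------------------------------------------------------
# Foreign systems
# ---------------------------------------------------------------------------

Grade = Union[int, str]


@dataclass(frozen=True)
class ForeignToken:
    """One finding in a foreign classification system.

    ``site`` is None for Pringle whole-exam grades; ``grade`` is an int
    except for the NOHL larynx flag ("N"/"P"); ``configuration`` uses the
    system's own codes (NOHL transversal is "T").
    """

    system: str
    site: Optional[str]
    grade: Grade
    configuration: Optional[str] = None

    def __str__(self) -> str:
        return format_foreign(self)


class ForeignTokenError(ValueError):
    """Token outside its system's vocabulary."""


#: site -> (allowed configurations, allowed grades); None site key = whole exam
_VOTE_SITES = {
    "V": ({"AP", "L", "C"}, range(0, 3)),
    "O": ({"L"}, range(0, 3)),
    "T": ({"AP"}, range(0, 3)),
    "E": ({"AP", "L"}, range(0, 3)),
}
_NOHL_GRADED = {"N": set(), "O": {"AP", "T", "C"}, "H": {"AP", "T", "C"}, "TS": set()}
_PTLTBE_GRADES = {"P": range(1, 4), "T": range(1, 4), "L": range(1, 4),
                  "Tb": range(1, 4), "E": range(1, 3)}


def validate_foreign(token: ForeignToken) -> list[str]:
    """Violations of the token's system vocabulary (empty = valid)."""
    errs: list[str] = []
    sys = token.system
    if sys == "PRINGLE":
        if token.site is not None:
            errs.append("PRINGLE grades are whole-exam; no site allowed")
        if token.grade not in range(1, 6):
            errs.append(f"PRINGLE grade {token.grade!r} not in 1..5")
        if token.configuration is not None:
            errs.append("PRINGLE carries no configuration")
    elif sys == "VOTE":
        if token.site not in _VOTE_SITES:
            errs.append(f"VOTE site {token.site!r} not in V/O/T/E")
            return errs
        cfgs, grades = _VOTE_SITES[token.site]
        if token.grade not in grades:
            errs.append(f"VOTE grade {token.grade!r} out of range (0-2)")
        if token.configuration is not None and token.configuration not in cfgs:
            errs.append(
                f"VOTE configuration {token.configuration!r} not defined for "
                f"site {token.site} (allowed: {sorted(cfgs)})"
            )
        elif token.configuration is None and isinstance(token.grade, int) \
                and token.grade >= 1:
            errs.append(f"VOTE site {token.site}: configuration required at "
                        f"grade {token.grade}")
    elif sys == "NOHL":
        if token.site == "L":
            if token.grade not in ("N", "P"):
                errs.append(f"NOHL larynx flag {token.grade!r} not N/P")
            if token.configuration is not None:
                errs.append("NOHL larynx carries no configuration")
        elif token.site in _NOHL_GRADED:
            if token.grade not in range(1, 5):
                errs.append(f"NOHL grade {token.grade!r} out of range (1-4)")
            cfgs = _NOHL_GRADED[token.site]
            if cfgs and token.configuration not in cfgs:
                errs.append(
                    f"NOHL site {token.site}: configuration must be one of "
                    f"{sorted(cfgs)} (got {token.configuration!r})"
                )
            if not cfgs and token.configuration is not None:
                errs.append(f"NOHL site {token.site} carries no configuration")
        else:
            errs.append(f"NOHL site {token.site!r} not in N/O/H/TS/L")
    elif sys == "PTLTBE":
        if token.site not in _PTLTBE_GRADES:
            errs.append(f"PTLTBE site {token.site!r} not in P/T/L/Tb/E")
        elif token.grade not in _PTLTBE_GRADES[token.site]:
            errs.append(
                f"PTLTBE site {token.site}: grade {token.grade!r} out of range"
            )
        if token.configuration is not None:
            errs.append("PTLTBE carries no configuration")
    else:
        errs.append(f"unknown system {sys!r}")
    return errs


_NOHL_CFG_ALIASES = {"T": "T", "L": "T", "C": "C", "AP": "AP"}

_VOTE_RE = re.compile(r"^([VOTE])K?([0-9])(AP|L|C)?$")
_NOHL_RES = (
    re.compile(r"^(TS)()([1-4])$"),
    re.compile(r"^([OH])(AP|T|L|C)([1-4])$"),
    re.compile(r"^(L)()([NP])$"),
    re.compile(r"^(N)()([1-9])$"),
)
_PTLTBE_RE = re.compile(r"^(TB|P|T|L|E)([0-9])$")


def _parse_one(system: str, raw: str) -> ForeignToken:
    tok = raw.strip().upper()
    if system == "PRINGLE":
        m = re.match(r"^G([0-9])$", tok)
        if not m:
            raise ForeignTokenError(f"cannot parse PRINGLE token {raw!r}")
        return ForeignToken("PRINGLE", None, int(m.group(1)))
    if system == "VOTE":
        m = _VOTE_RE.match(tok)
        if not m:
            raise ForeignTokenError(f"cannot parse VOTE token {raw!r}")
        return ForeignToken("VOTE", m.group(1), int(m.group(2)), m.group(3))
    if system == "NOHL":
        for rx in _NOHL_RES:
            m = rx.match(tok)
            if m:
                site, cfg, grade = m.group(1), m.group(2) or None, m.group(3)
                if cfg is not None:
                    cfg = _NOHL_CFG_ALIASES[cfg]
                return ForeignToken(
                    "NOHL", site, grade if site == "L" else int(grade), cfg
                )
        raise ForeignTokenError(f"cannot parse NOHL token {raw!r}")
    if system == "PTLTBE":
        m = _PTLTBE_RE.match(tok)
        if not m:
            raise ForeignTokenError(f"cannot parse PTLTBE token {raw!r}")
        site = {"TB": "Tb"}.get(m.group(1), m.group(1))
        return ForeignToken("PTLTBE", site, int(m.group(2)))
    raise ForeignTokenError(f"unknown system {system!r}")


def parse_foreign(system: str, text: str) -> list[ForeignToken]:
    """Parse whitespace/comma-separated foreign tokens and validate them."""
    if system not in SYSTEMS:
        raise ForeignTokenError(
            f"unknown system {system!r}; expected one of {SYSTEMS}"
        )
    tokens = []
    for raw in re.split(r"[,\s]+", text.strip()):
        if not raw:
            continue
        token = _parse_one(system, raw)
        errs = validate_foreign(token)
        if errs:
            raise ForeignTokenError("; ".join(errs))
        tokens.append(token)
    if not tokens:
        raise ForeignTokenError("no tokens found")
    return tokens


def format_foreign(token: ForeignToken) -> str:
    """Canonical compact token string (e.g. ``G3``, ``V2AP``, ``OT4``)."""
    if token.system == "PRINGLE":
        return f"G{token.grade}"
    if token.system == "VOTE":
        return f"{token.site}{token.grade}{token.configuration or ''}"
    if token.system == "NOHL":
        return f"{token.site}{token.configuration or ''}{token.grade}"
    if token.system == "PTLTBE":
        return f"{token.site}{token.grade}"
    raise ForeignTokenError(f"unknown system {token.system!r}")
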