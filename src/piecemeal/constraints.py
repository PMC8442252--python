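"""Causal-structure constraints and the two-variable study-design schema.

A study result is encoded as a statement ``X dep Y | C || J`` or
``X indep Y | C || J``: the pair was found statistically (in)dependent, given
conditioning set ``C``, in an experiment that intervened on the variables in
``J``.  Each constraint carries a non-negative weight expressing confidence;
conflicting evidence is resolved by minimizing the summed weight of
unsatisfied constraints.

The research-map schema describes one published two-variable study by an
ordered variable pair plus one of four methodological symbols: an
intervention that raised or lowered the source (up / down), or a passive
observation in which the source rose or fell.  Direction of change and the
sign of the correlation (excitation vs. inhibition) are metadata only: both
correlation signs are treated as statistical dependence, and the up/down
variants of a method carry identical structural information.  For causal
inference a study therefore collapses to a *constraint-level design*: which
pair was studied and which of the pair (at most one) was intervened on.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from math import comb
from typing import Iterable, Mapping, Sequence

from .dag import canonical_pair
from .errors import ParseError


class Polarity(Enum):
    """Whether a statement asserts dependence or independence."""

    DEPENDENT = "dep"
    INDEPENDENT = "indep"

    def flipped(self) -> "Polarity":
        return (
            Polarity.INDEPENDENT if self is Polarity.DEPENDENT else Polarity.DEPENDENT
        )


class StudyMethod(Enum):
    """The four research-map methodological symbols."""

    INT_UP = "int_up"  # intervention raising the source
    INT_DOWN = "int_down"  # intervention lowering the source
    OBS_UP = "obs_up"  # observation; source seen to rise
    OBS_DOWN = "obs_down"  # observation; source seen to fall

    @property
    def is_intervention(self) -> bool:
        return self in (StudyMethod.INT_UP, StudyMethod.INT_DOWN)

    @property
    def symbol(self) -> str:
        return {
            StudyMethod.INT_UP: "↑",
            StudyMethod.INT_DOWN: "↓",
            StudyMethod.OBS_UP: "Ø↑",
            StudyMethod.OBS_DOWN: "Ø↓",
        }[self]


@dataclass(frozen=True)
class StudyDesign:
    """One research-map study: an ordered pair plus a methodological symbol."""

    source: str
    target: str
    method: StudyMethod

    def __post_init__(self) -> None:
        if self.source == self.target:
            raise ValueError("source and target must be distinct")
        if not isinstance(self.method, StudyMethod):
            raise ValueError(f"unknown study method {self.method!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return canonical_pair(self.source, self.target)

    def sort_key(self) -> tuple:
        return (self.source, self.target, self.method.value)

    def __str__(self) -> str:
        return f"{self.source}{self.method.symbol} {self.target}"


@dataclass(frozen=True)
class ConstraintLevelDesign:
    """A study design up to information content: pair + intervened subset.

    Exactly three exist per pair: observe, intervene on the first variable,
    intervene on the second.
    """

    pair: tuple[str, str]
    intervened: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair", canonical_pair(*self.pair))
        object.__setattr__(self, "intervened", frozenset(self.intervened))
        if len(self.intervened) > 1 or not self.intervened <= set(self.pair):
            raise ValueError(
                "at most one of the pair's variables may be intervened on"
            )

    @property
    def observational(self) -> bool:
        return not self.intervened

    def sort_key(self) -> tuple:
        return (self.pair, tuple(sorted(self.intervened)))

    def __str__(self) -> str:
        if self.observational:
            return f"observe {self.pair[0]}, {self.pair[1]}"
        (j,) = self.intervened
        other = self.pair[1] if j == self.pair[0] else self.pair[0]
        return f"intervene on {j}, observe {other}"


@dataclass(frozen=True)
class IndependenceConstraint:
    """A weighted (in)dependence statement ``x ? y | cond || intervened``.

    Stored in canonical form: the pair sorted, ``cond`` and ``intervened``
    as frozensets.  Equality ignores the original pair order.
    """

    x: str
    y: str
    polarity: Polarity
    cond: frozenset[str] = frozenset()
    intervened: frozenset[str] = frozenset()
    weight: float = 1.0

    def __post_init__(self) -> None:
        a, b = canonical_pair(self.x, self.y)
        object.__setattr__(self, "x", a)
        object.__setattr__(self, "y", b)
        object.__setattr__(self, "cond", frozenset(self.cond))
        object.__setattr__(self, "intervened", frozenset(self.intervened))
        if not isinstance(self.polarity, Polarity):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.x in self.cond or self.y in self.cond:
            raise ValueError("x and y may not appear in the conditioning set")
        if self.cond & self.intervened:
            raise ValueError("cond and intervened must be disjoint")
        if not self.weight >= 0:
            raise ValueError(f"weight must be non-negative, got {self.weight}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.x, self.y)

    def flipped(self) -> "IndependenceConstraint":
        return IndependenceConstraint(
            self.x, self.y, self.polarity.flipped(), self.cond, self.intervened,
            self.weight,
        )

    def reweighted(self, weight: float) -> "IndependenceConstraint":
        return IndependenceConstraint(
            self.x, self.y, self.polarity, self.cond, self.intervened, weight
        )

    def __str__(self) -> str:
        return serialize_constraint(self)


# ---------------------------------------------------------------------------
# Schema enumeration and conversion
# ---------------------------------------------------------------------------


def enumerate_study_designs(variables: Sequence[str]) -> list[StudyDesign]:
    """The full design pool: every ordered pair times the four methods,
    ``4 * N * (N-1)`` designs in deterministic order (48 for four variables).
    """
    vs = sorted(variables)
    if len(vs) < 2:
        raise ValueError("at least two variables are required")
    if len(set(vs)) != len(vs):
        raise ValueError("variable names must be distinct")
    return [
        StudyDesign(s, t, m)
        for s in vs
        for t in vs
        if s != t
        for m in StudyMethod
    ]


def enumerate_constraint_level_designs(
    variables: Sequence[str],
) -> list[ConstraintLevelDesign]:
    """The ``3 * C(N,2)`` distinct constraint-level designs."""
    vs = sorted(variables)
    out = []
    for i in range(len(vs)):
        for j in range(i + 1, len(vs)):
            pair = (vs[i], vs[j])
            out.append(ConstraintLevelDesign(pair))
            out.append(ConstraintLevelDesign(pair, frozenset({vs[i]})))
            out.append(ConstraintLevelDesign(pair, frozenset({vs[j]})))
    return out


def to_constraint_level(design: StudyDesign) -> ConstraintLevelDesign:
    """Collapse a study design to its information content: interventions
    intervene on the source; observations intervene on nothing."""
    intervened = frozenset({design.source}) if design.method.is_intervention else frozenset()
    return ConstraintLevelDesign(design.pair, intervened)


def study_result_to_constraint(
    design: StudyDesign, verdict: Polarity, weight: float = 1.0
) -> IndependenceConstraint:
    """The constraint a study's verdict imposes on causal structure.

    Only the two studied variables are observed, so the conditioning set is
    always empty; the intervention set follows the methodological symbol.
    """
    if not weight >= 0:
        raise ValueError(f"weight must be non-negative, got {weight}")
    level = to_constraint_level(design)
    return IndependenceConstraint(
        level.pair[0], level.pair[1], verdict, frozenset(), level.intervened, weight
    )


def variants_of(
    level: ConstraintLevelDesign, variables: Sequence[str] | None = None
) -> list[StudyDesign]:
    """The study designs collapsing to a constraint-level design: four
    observational variants (both orders x up/down) or two interventional
    variants (up/down on the intervened source)."""
    a, b = level.pair
    if level.observational:
        return [
            StudyDesign(s, t, m)
            for s, t in ((a, b), (b, a))
            for m in (StudyMethod.OBS_UP, StudyMethod.OBS_DOWN)
        ]
    (j,) = level.intervened
    other = b if j == a else a
    return [StudyDesign(j, other, m) for m in (StudyMethod.INT_UP, StudyMethod.INT_DOWN)]


def n_designs(n_vars: int) -> int:
    return 4 * n_vars * (n_vars - 1)


def n_constraint_level_designs(n_vars: int) -> int:
    return 3 * comb(n_vars, 2)


# ---------------------------------------------------------------------------
# Text notation
# ---------------------------------------------------------------------------

_NAME_RE = re.compile(r"^[A-Za-z_][A-Za-z0-9_.\-]*$")


def _check_name(name: str, text: str) -> str:
    name = name.strip()
    if not _NAME_RE.match(name):
        raise ParseError(
            f"invalid variable name {name!r} at position {text.find(name) if name else 0} "
            f"in {text!r}"
        )
    return name


def parse_constraint(text: str) -> IndependenceConstraint:
    """Parse the one-line notation
    ``<var> ("dep"|"indep") <var> [ "|" C... ] [ "||" J... ] [ ";" "w=" FLOAT ]``.
    """
    raw = text
    text = text.split("#", 1)[0].strip()
    if not text:
        raise ParseError(f"empty constraint line: {raw!r}")

    weight = 1.0
    if ";" in text:
        text, _, wpart = text.partition(";")
        wpart = wpart.strip()
        if not wpart.startswith("w="):
            raise ParseError(
                f"expected 'w=FLOAT' after ';' at position {raw.find(';')} in {raw!r}"
            )
        try:
            weight = float(wpart[2:])
        except ValueError:
            raise ParseError(f"bad weight {wpart[2:]!r} in {raw!r}") from None

    intervened: frozenset[str] = frozenset()
    if "||" in text:
        text, _, jpart = text.partition("||")
        names = [_check_name(v, raw) for v in jpart.split(",")]
        intervened = frozenset(names)

    cond: frozenset[str] = frozenset()
    if "|" in text:
        text, _, cpart = text.partition("|")
        names = [_check_name(v, raw) for v in cpart.split(",")]
        cond = frozenset(names)

    tokens = text.split()
    if len(tokens) != 3 or tokens[1] not in ("dep", "indep"):
        raise ParseError(
            f"expected '<var> dep|indep <var>' at position 0, got {raw!r}"
        )
    x = _check_name(tokens[0], raw)
    y = _check_name(tokens[2], raw)
    polarity = Polarity.DEPENDENT if tokens[1] == "dep" else Polarity.INDEPENDENT
    try:
        return IndependenceConstraint(x, y, polarity, cond, intervened, weight)
    except ValueError as exc:
        raise ParseError(f"{exc} (in {raw!r})") from None


def serialize_constraint(c: IndependenceConstraint) -> str:
    """Canonical one-line form; ``parse_constraint`` round-trips it."""
    out = f"{c.x} {c.polarity.value} {c.y}"
    if c.cond:
        out += " | " + ", ".join(sorted(c.cond))
    if c.intervened:
        out += " || " + ", ".join(sorted(c.intervened))
    if c.weight != 1.0:
        out += f" ; w={c.weight:g}"
    return out


def parse_constraint_lines(text: str) -> list[IndependenceConstraint]:
    """Parse a whole text file: one constraint per line, '#' comments."""
    out = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        stripped = line.split("#", 1)[0].strip()
        if not stripped:
            continue
        try:
            out.append(parse_constraint(stripped))
        except ParseError as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return out


# ---------------------------------------------------------------------------
# JSON interfaces
# ---------------------------------------------------------------------------


def constraints_to_json_dict(
    variables: Sequence[str], constraints: Iterable[IndependenceConstraint]
) -> dict:
    return {
        "variables": sorted(variables),
        "constraints": [
            {
                "x": c.x,
                "y": c.y,
                "polarity": c.polarity.value,
                "cond": sorted(c.cond),
                "intervene": sorted(c.intervened),
                "weight": c.weight,
            }
            for c in constraints
        ],
    }


def constraints_from_json_dict(
    doc: Mapping,
) -> tuple[list[str], list[IndependenceConstraint]]:
    try:
        variables = list(doc["variables"])
        constraints = [
            IndependenceConstraint(
                e["x"],
                e["y"],
                Polarity(e["polarity"]),
                frozenset(e.get("cond", ())),
                frozenset(e.get("intervene", ())),
                float(e.get("weight", 1.0)),
            )
            for e in doc["constraints"]
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed constraints JSON: {exc}") from None
    return variables, constraints


def load_constraints_file(path: str) -> tuple[list[str], list[IndependenceConstraint]]:
    """Read a constraints file: JSON if it parses as JSON, else line notation
    (variables inferred from the statements)."""
    with open(path) as fh:
        text = fh.read()
    stripped = text.lstrip()
    if stripped.startswith("{"):
        return constraints_from_json_dict(json.loads(text))
    constraints = parse_constraint_lines(text)
    variables = sorted({v for c in constraints for v in (c.x, c.y, *c.cond, *c.intervened)})
    return variables, constraints


# ---------------------------------------------------------------------------
# Research maps
# ---------------------------------------------------------------------------

_RELATION_POLARITY = {
    "excitation": Polarity.DEPENDENT,
    "inhibition": Polarity.DEPENDENT,
    "independence": Polarity.INDEPENDENT,
}


def research_map_to_constraints(
    doc: Mapping,
) -> tuple[list[str], list[IndependenceConstraint]]:
    """Convert a research-map annotation to constraints: one per recorded
    study, with the edge's ontological relation as the verdict (excitation
    and inhibition both mean dependence) and the edge's evidence score, if
    present, as the weight."""
    try:
        variables = [n["name"] for n in doc["nodes"]]
        constraints = []
        for edge in doc["edges"]:
            polarity = _RELATION_POLARITY[edge["relation"]]
            weight = float(edge.get("score", 1.0))
            for study in edge["studies"]:
                design = StudyDesign(
                    edge["source"], edge["target"], StudyMethod(study["method"])
                )
                constraints.append(study_result_to_constraint(design, polarity, weight))
    except (KeyError, TypeError, ValueError) as exc:
        raise ParseError(f"malformed research-map JSON: {exc}") from None
    return variables, constraints
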