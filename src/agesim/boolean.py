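"""Boolean model of the nutrient- and stress-signalling network.

The signalling layer (PKA-, Snf1-, TOR-like nutrient sensing plus the
Yap1/Sln1 oxidative-stress pathways) is represented as a synchronous
Boolean network.  Input components (glucose, H2O2, thioredoxin activity,
...) are set externally — in the multi-scale loop they are derived from
the metabolic fluxes — and the remaining components follow one logical
update rule each.  The network is iterated synchronously to a fixed
point; the steady-state activities of the transcription factors drive
the transcriptional regulation layer.

Rule files are plain UTF-8 text::

    # comment
    INPUT: Glucose, H2O2, Trx12
    PKA  = Glucose
    Yap1 = H2O2 & !Trx12

Operators are ``&`` (and), ``|`` (or), ``!`` (not) and parentheses, with
``!`` binding tightest and ``|`` loosest.  Component names may contain
letters, digits, ``_``, ``/``, ``.`` and ``-``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

__all__ = [
    "BooleanNetwork",
    "BooleanState",
    "RuleSyntaxError",
    "NoFixedPointError",
    "parse_rules",
    "steady_state",
    "knockout",
]


class RuleSyntaxError(ValueError):
    """A rule file could not be parsed; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class NoFixedPointError(RuntimeError):
    """Synchronous iteration entered a limit cycle instead of a fixed point.

    The states of the cycle are attached so callers can report it; the
    lifespan simulation treats this as "no steady state" and keeps the
    previous transcription-factor activities.
    """

    def __init__(self, cycle: list["BooleanState"]):
        self.cycle = cycle
        super().__init__(
            f"no fixed point: limit cycle of length {len(cycle)} detected"
        )


# ---------------------------------------------------------------------------
# expressions

_TOKEN_RE = re.compile(r"\s*(?:(\()|(\))|(&)|(\|)|(!)|([A-Za-z0-9_/.\-]+))")

#: expression AST: ("var", name) | ("not", e) | ("and", a, b) | ("or", a, b)
#: | ("const", 0/1)
Expr = tuple


def _tokenize(text: str, line: int) -> list[str]:
    tokens: list[str] = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if m is None or m.end() == pos:
            rest = text[pos:].strip()
            if not rest:
                break
            raise RuleSyntaxError(f"unexpected character {rest[0]!r}", line)
        tokens.append(m.group(0).strip())
        pos = m.end()
    return [t for t in tokens if t]


def _parse_expr(tokens: list[str], line: int) -> Expr:
    expr, rest = _parse_or(tokens, line)
    if rest:
        raise RuleSyntaxError(f"unexpected token {rest[0]!r}", line)
    return expr


def _parse_or(tokens, line):
    left, tokens = _parse_and(tokens, line)
    while tokens and tokens[0] == "|":
        right, tokens = _parse_and(tokens[1:], line)
        left = ("or", left, right)
    return left, tokens


def _parse_and(tokens, line):
    left, tokens = _parse_atom(tokens, line)
    while tokens and tokens[0] == "&":
        right, tokens = _parse_atom(tokens[1:], line)
        left = ("and", left, right)
    return left, tokens


def _parse_atom(tokens, line):
    if not tokens:
        raise RuleSyntaxError("empty expression", line)
    tok = tokens[0]
    if tok == "!":
        inner, rest = _parse_atom(tokens[1:], line)
        return ("not", inner), rest
    if tok == "(":
        expr, rest = _parse_or(tokens[1:], line)
        if not rest or rest[0] != ")":
            raise RuleSyntaxError("unbalanced parenthesis", line)
        return expr, rest[1:]
    if tok in {")", "&", "|"}:
        raise RuleSyntaxError(f"unexpected token {tok!r}", line)
    if tok in {"0", "1"}:
        return ("const", int(tok)), tokens[1:]
    return ("var", tok), tokens[1:]


def eval_expr(expr: Expr, state: Mapping[str, int]) -> int:
    op = expr[0]
    if op == "var":
        return state[expr[1]]
    if op == "const":
        return expr[1]
    if op == "not":
        return 1 - eval_expr(expr[1], state)
    if op == "and":
        return eval_expr(expr[1], state) & eval_expr(expr[2], state)
    if op == "or":
        return eval_expr(expr[1], state) | eval_expr(expr[2], state)
    raise ValueError(f"bad expression node {op!r}")


def _expr_symbols(expr: Expr) -> set[str]:
    op = expr[0]
    if op == "var":
        return {expr[1]}
    if op == "const":
        return set()
    if op == "not":
        return _expr_symbols(expr[1])
    return _expr_symbols(expr[1]) | _expr_symbols(expr[2])


# ---------------------------------------------------------------------------
# network and state


@dataclass(frozen=True)
class BooleanState:
    """Binary activity of every component of a :class:`BooleanNetwork`."""

    activity: Mapping[str, int]

    def __post_init__(self):
        for name, value in self.activity.items():
            if value not in (0, 1):
                raise ValueError(f"non-binary activity {value!r} for {name!r}")
        object.__setattr__(self, "activity", dict(self.activity))

    def __getitem__(self, name: str) -> int:
        return self.activity[name]

    def replace(self, **updates: int) -> "BooleanState":
        new = dict(self.activity)
        for name, value in updates.items():
            if name not in new:
                raise KeyError(name)
            new[name] = value
        return BooleanState(new)

    def as_tuple(self, order: Iterable[str]) -> tuple[int, ...]:
        return tuple(self.activity[c] for c in order)


@dataclass(frozen=True)
class BooleanNetwork:
    """Components, one update rule per non-input component, declared inputs."""

    components: tuple[str, ...]
    rules: Mapping[str, Expr]
    inputs: frozenset[str]
    #: optional provenance tag per component/rule target (used by the model
    #: summary to count extensions, e.g. the oxidative-stress pathway block)
    tags: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self):
        comp = set(self.components)
        if len(comp) != len(self.components):
            raise ValueError("duplicate component names")
        for target, expr in self.rules.items():
            if target not in comp:
                raise ValueError(f"rule target {target!r} is not a component")
            if target in self.inputs:
                raise ValueError(f"rule given for input component {target!r}")
            for sym in _expr_symbols(expr):
                if sym not in comp:
                    raise ValueError(
                        f"undeclared symbol {sym!r} in rule for {target!r}"
                    )
        for c in self.components:
            if c not in self.inputs and c not in self.rules:
                raise ValueError(f"non-input component {c!r} has no rule")
        object.__setattr__(self, "rules", dict(self.rules))
        object.__setattr__(self, "inputs", frozenset(self.inputs))
        object.__setattr__(self, "tags", dict(self.tags))

    def zero_state(self, **overrides: int) -> BooleanState:
        state = {c: 0 for c in self.components}
        for name, value in overrides.items():
            if name not in state:
                raise KeyError(name)
            state[name] = value
        return BooleanState(state)

    def update(self, state: BooleanState,
               clamped: Mapping[str, int] | None = None) -> BooleanState:
        """One synchronous update; clamped components keep their clamp value."""
        clamped = clamped or {}
        new = {}
        for c in self.components:
            if c in clamped:
                new[c] = clamped[c]
            elif c in self.inputs:
                new[c] = state[c]
            else:
                new[c] = eval_expr(self.rules[c], state.activity)
        return BooleanState(new)


def parse_rules(text: str) -> BooleanNetwork:
    """Parse a rule file into a validated :class:`BooleanNetwork`.

    The whole file is consumed or a :class:`RuleSyntaxError` with a line
    number is raised.  ``#tag name`` comment lines set the provenance tag
    applied to subsequently declared inputs and rule targets.
    """
    inputs: list[str] = []
    rules: dict[str, Expr] = {}
    order: list[str] = []
    tags: dict[str, str] = {}
    current_tag = "core"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if line.startswith("#tag"):
            current_tag = line[4:].strip() or "core"
            continue
        if not line or line.startswith("#"):
            continue
        if line.upper().startswith("INPUT:"):
            for name in line[len("INPUT:"):].split(","):
                name = name.strip()
                if not name:
                    continue
                if not re.fullmatch(r"[A-Za-z0-9_/.\-]+", name):
                    raise RuleSyntaxError(f"bad component name {name!r}", lineno)
                if name in inputs:
                    raise RuleSyntaxError(f"duplicate input {name!r}", lineno)
                inputs.append(name)
                order.append(name)
                tags[name] = current_tag
            continue
        if "=" not in line:
            raise RuleSyntaxError("expected 'target = expression'", lineno)
        target, body = line.split("=", 1)
        target = target.strip()
        if not re.fullmatch(r"[A-Za-z0-9_/.\-]+", target):
            raise RuleSyntaxError(f"bad rule target {target!r}", lineno)
        if target in rules:
            raise RuleSyntaxError(f"duplicate rule for {target!r}", lineno)
        if target in inputs:
            raise RuleSyntaxError(
                f"rule given for input component {target!r}", lineno)
        if not body.strip():
            raise RuleSyntaxError("empty rule body", lineno)
        rules[target] = _parse_expr(_tokenize(body, lineno), lineno)
        order.append(target)
        tags[target] = current_tag
    # symbols used before/never declared
    declared = set(order)
    for target, expr in rules.items():
        for sym in _expr_symbols(expr):
            if sym not in declared:
                raise RuleSyntaxError(
                    f"undeclared symbol {sym!r} in rule for {target!r}")
    return BooleanNetwork(tuple(order), rules, frozenset(inputs), tags)


def steady_state(net: BooleanNetwork, init: BooleanState,
                 clamped: Mapping[str, int] | None = None,
                 max_iter: int | None = None) -> BooleanState:
    """Synchronous fixed point reached from ``init``.

    Clamped components override their rules (and their input values).
    Raises :class:`NoFixedPointError` carrying the limit cycle if the
    trajectory does not reach a fixed point within ``max_iter`` steps
    (default ``4 * n_components``).
    """
    clamped = dict(clamped or {})
    for name, value in clamped.items():
        if name not in set(net.components):
            raise KeyError(f"unknown component {name!r}")
        if value not in (0, 1):
            raise ValueError(f"non-binary clamp for {name!r}")
    if max_iter is None:
        max_iter = 4 * len(net.components)
    state = BooleanState({**init.activity, **clamped})
    seen: dict[tuple[int, ...], int] = {state.as_tuple(net.components): 0}
    trajectory = [state]
    for _ in range(max_iter):
        nxt = net.update(state, clamped)
        if nxt.activity == state.activity:
            return state
        key = nxt.as_tuple(net.components)
        if key in seen:
            cycle = trajectory[seen[key]:]
            raise NoFixedPointError(cycle)
        seen[key] = len(trajectory)
        trajectory.append(nxt)
        state = nxt
    raise NoFixedPointError(trajectory[-2:])


def knockout(net: BooleanNetwork, targets: Iterable[str]) -> BooleanNetwork:
    """Return a network with each target permanently clamped to 0.

    The target's rule is replaced by the constant 0; knocked-out input
    components become constant-0 rule components.
    """
    targets = set(targets)
    comp = set(net.components)
    for t in targets:
        if t not in comp:
            raise KeyError(f"unknown component {t!r}")
    if not targets:
        return net
    rules = dict(net.rules)
    inputs = set(net.inputs)
    for t in targets:
        rules[t] = ("const", 0)
        inputs.discard(t)
    return BooleanNetwork(net.components, rules, frozenset(inputs), net.tags)
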