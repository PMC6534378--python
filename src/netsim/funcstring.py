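"""Safe arithmetic expression strings for model parameters.

Connection probability, weight, delay and density-map expressions may be
given as strings ("func strings") over a fixed vocabulary of pre-/
post-synaptic variables.  The grammar is parsed with a hand-written
recursive-descent parser into a small AST -- the host language ``eval``
is never used -- so a spec document can never execute arbitrary code,
and evaluation is deterministic given the supplied random stream.

Grammar (standard precedence, left associative):

    expr   := term (("+" | "-") term)*
    term   := unary (("*" | "/") unary)*
    unary  := ("+" | "-") unary | power
    power  := atom (("^" | "**") unary)?
    atom   := NUMBER | VAR | FUNC "(" expr ("," expr)* ")" | "(" expr ")"

Deterministic functions: exp, log, sqrt, abs, sin, cos, min, max.
Stochastic terms: uniform(a, b), normal(mu, sd); these draw from the
random stream passed to :meth:`FuncString.eval` (the stream scoped to
the connection being generated), never from global state.

Evaluation is *totalized*: partial functions are guarded (log and sqrt
clamp their argument domain, division clamps the divisor away from
zero) and every intermediate result is clipped to a large finite bound,
so any accepted expression yields a finite float for finite inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "FuncString",
    "FuncStringError",
    "parse_func_string",
    "DEFAULT_VARIABLES",
]

#: Variables available to connectivity expressions.  Coordinates are in
#: micrometres; *_ynorm are normalized depth in [0, 1]; dist_3D is the
#: Euclidean pre-post distance, dist_2D its projection on the xz plane
#: (lateral distance) and dist_y the absolute depth difference.
DEFAULT_VARIABLES = frozenset(
    {
        "pre_x", "pre_y", "pre_z",
        "post_x", "post_y", "post_z",
        "pre_xnorm", "pre_ynorm", "pre_znorm",
        "post_xnorm", "post_ynorm", "post_znorm",
        "dist_3D", "dist_2D", "dist_y",
    }
)

_HUGE = 1e150          # clip bound applied after every operation
_EXP_ARG_MAX = 345.0   # exp argument clamp; exp(345) < _HUGE


class FuncStringError(ValueError):
    """Parse failure; carries the offending token and its position."""

    def __init__(self, message, token=None, pos=None):
        self.token = token
        self.pos = pos
        loc = f" at position {pos}" if pos is not None else ""
        tok = f" (token {token!r})" if token is not None else ""
        super().__init__(f"{message}{loc}{tok}")


# ---------------------------------------------------------------------------
# tokenizer

_OPS = ("**", "+", "-", "*", "/", "^", "(", ")", ",")


def _tokenize(src):
    tokens = []
    i, n = 0, len(src)
    while i < n:
        c = src[i]
        if c.isspace():
            i += 1
            continue
        if c.isdigit() or (c == "." and i + 1 < n and src[i + 1].isdigit()):
            j = i
            while j < n and (src[j].isdigit() or src[j] == "."):
                j += 1
            # exponent part
            if j < n and src[j] in "eE":
                k = j + 1
                if k < n and src[k] in "+-":
                    k += 1
                if k < n and src[k].isdigit():
                    j = k
                    while j < n and src[j].isdigit():
                        j += 1
            try:
                val = float(src[i:j])
            except ValueError:
                raise FuncStringError("malformed number", src[i:j], i)
            tokens.append(("num", val, i))
            i = j
            continue
        if c.isalpha() or c == "_":
            j = i
            while j < n and (src[j].isalnum() or src[j] == "_"):
                j += 1
            tokens.append(("name", src[i:j], i))
            i = j
            continue
        if src.startswith("**", i):
            tokens.append(("op", "**", i))
            i += 2
            continue
        if c in "+-*/^(),":
            tokens.append(("op", c, i))
            i += 1
            continue
        raise FuncStringError("illegal character", c, i)
    tokens.append(("end", None, n))
    return tokens


# ---------------------------------------------------------------------------
# AST and guarded numerics

def _clip(x):
    return np.clip(x, -_HUGE, _HUGE)


def _safe_div(a, b):
    b = np.where(np.abs(b) < 1e-300, np.where(b < 0, -1e-300, 1e-300), b)
    return a / b


def _safe_exp(x):
    return np.exp(np.clip(x, -_EXP_ARG_MAX, _EXP_ARG_MAX))


def _safe_log(x):
    return np.log(np.maximum(x, 1e-300))


def _safe_sqrt(x):
    return np.sqrt(np.maximum(x, 0.0))


def _safe_pow(a, b):
    # negative base with fractional exponent has no real value; use |a|
    # (an odd integer exponent keeps the sign); overflow clips to the
    # finite bound
    with np.errstate(over="ignore"):
        mag = np.power(np.maximum(np.abs(a), 1e-300),
                       np.clip(b, -500.0, 500.0))
    sign = np.where((a < 0) & (np.mod(b, 2) == 1), -1.0, 1.0)
    return _clip(np.nan_to_num(mag * sign, posinf=_HUGE, neginf=-_HUGE))


_FUNCS = {
    "exp": (1, _safe_exp),
    "log": (1, _safe_log),
    "sqrt": (1, _safe_sqrt),
    "abs": (1, np.abs),
    "sin": (1, np.sin),
    "cos": (1, np.cos),
    "min": (None, None),   # variadic, handled specially
    "max": (None, None),
}

_STOCHASTIC = {"uniform": 2, "normal": 2}


@dataclass(frozen=True)
class _Num:
    value: float

    def eval(self, env, rng):
        return self.value


@dataclass(frozen=True)
class _Var:
    name: str

    def eval(self, env, rng):
        return env[self.name]


@dataclass(frozen=True)
class _Bin:
    op: str
    left: object
    right: object

    def eval(self, env, rng):
        a = self.left.eval(env, rng)
        b = self.right.eval(env, rng)
        if self.op == "+":
            return _clip(a + b)
        if self.op == "-":
            return _clip(a - b)
        if self.op == "*":
            return _clip(a * b)
        if self.op == "/":
            return _clip(_safe_div(a, b))
        return _safe_pow(a, b)


@dataclass(frozen=True)
class _Neg:
    arg: object

    def eval(self, env, rng):
        return -self.arg.eval(env, rng)


@dataclass(frozen=True)
class _Call:
    name: str
    args: tuple = field(default_factory=tuple)

    def eval(self, env, rng):
        vals = [a.eval(env, rng) for a in self.args]
        if self.name in _STOCHASTIC:
            if rng is None:
                raise ValueError(
                    f"stochastic term {self.name}() requires a random stream")
            if self.name == "uniform":
                lo, hi = vals
                lo, hi = min(lo, hi), max(lo, hi)
                return rng.uniform(lo, hi)
            mu, sd = vals
            return _clip(mu + abs(sd) * rng.standard_normal())
        if self.name == "min":
            return np.minimum.reduce(vals)
        if self.name == "max":
            return np.maximum.reduce(vals)
        return _clip(_FUNCS[self.name][1](vals[0]))


class _Parser:
    def __init__(self, tokens, variables):
        self.tokens = tokens
        self.i = 0
        self.variables = variables

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect_op(self, op):
        kind, val, pos = self.next()
        if kind != "op" or val != op:
            raise FuncStringError(f"expected {op!r}", val, pos)

    def parse(self):
        node = self.expr()
        kind, val, pos = self.peek()
        if kind != "end":
            raise FuncStringError("unexpected trailing input", val, pos)
        return node

    def expr(self):
        node = self.term()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("+", "-"):
                self.next()
                node = _Bin(val, node, self.term())
            else:
                return node

    def term(self):
        node = self.unary()
        while True:
            kind, val, _ = self.peek()
            if kind == "op" and val in ("*", "/"):
                self.next()
                node = _Bin(val, node, self.unary())
            else:
                return node

    def unary(self):
        kind, val, _ = self.peek()
        if kind == "op" and val in ("+", "-"):
            self.next()
            node = self.unary()
            return _Neg(node) if val == "-" else node
        return self.power()

    def power(self):
        node = self.atom()
        kind, val, _ = self.peek()
        if kind == "op" and val in ("^", "**"):
            self.next()
            node = _Bin("^", node, self.unary())
        return node

    def atom(self):
        kind, val, pos = self.next()
        if kind == "num":
            return _Num(val)
        if kind == "name":
            k2, v2, _ = self.peek()
            if k2 == "op" and v2 == "(":
                if val not in _FUNCS and val not in _STOCHASTIC:
                    raise FuncStringError("forbidden identifier", val, pos)
                self.next()  # consume (
                args = [self.expr()]
                while True:
                    k3, v3, p3 = self.peek()
                    if k3 == "op" and v3 == ",":
                        self.next()
                        args.append(self.expr())
                    else:
                        break
                self.expect_op(")")
                nargs = _STOCHASTIC.get(val) or _FUNCS[val][0]
                if nargs is None:  # min/max variadic, >= 2
                    if len(args) < 2:
                        raise FuncStringError(
                            f"{val}() needs at least two arguments", val, pos)
                elif len(args) != nargs:
                    raise FuncStringError(
                        f"{val}() takes {nargs} argument(s)", val, pos)
                return _Call(val, tuple(args))
            if val not in self.variables:
                raise FuncStringError("forbidden identifier", val, pos)
            return _Var(val)
        if kind == "op" and val == "(":
            node = self.expr()
            self.expect_op(")")
            return node
        raise FuncStringError("unexpected token", val, pos)


def _collect(node, cls, out):
    out.append(node) if isinstance(node, cls) else None
    for attr in ("left", "right", "arg"):
        child = getattr(node, attr, None)
        if child is not None:
            _collect(child, cls, out)
    for child in getattr(node, "args", ()):
        _collect(child, cls, out)


class FuncString:
    """A parsed expression; evaluate with :meth:`eval`.

    Serializes back to its source text so spec documents round-trip.
    """

    def __init__(self, source, ast, variables):
        self.source = source
        self._ast = ast
        self.variables = frozenset(variables)
        calls = []
        _collect(ast, _Call, calls)
        self.is_stochastic = any(c.name in _STOCHASTIC for c in calls)
        used = []
        _collect(ast, _Var, used)
        self.used_variables = frozenset(v.name for v in used)

    def eval(self, env=None, rng=None):
        value = self._ast.eval(env or {}, rng)
        return float(value) if np.isscalar(value) or getattr(value, "ndim", 1) == 0 else value

    def __eq__(self, other):
        return isinstance(other, FuncString) and other.source == self.source

    def __hash__(self):
        return hash(self.source)

    def __repr__(self):  # pragma: no cover - cosmetic
        return f"FuncString({self.source!r})"


import functools


@functools.lru_cache(maxsize=4096)
def _parse_cached(expr, variables):
    ast = _Parser(_tokenize(expr), variables).parse()
    return FuncString(expr, ast, variables)


def parse_func_string(expr, variables=DEFAULT_VARIABLES):
    """Parse ``expr`` into a :class:`FuncString`.

    Raises :class:`FuncStringError` on syntax errors or identifiers
    outside the variable/function whitelist.  Parsed expressions are
    cached (the AST is immutable, so sharing is safe).
    """
    if isinstance(expr, FuncString):
        return expr
    if not isinstance(expr, str):
        raise FuncStringError(f"expected a string, got {type(expr).__name__}")
    return _parse_cached(expr, frozenset(variables))
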