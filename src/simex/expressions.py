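"""Small expression ASTs shared by the model parsers, kernels and SED-ML layer.

Two expression families live here:

* :class:`MathExpression` — arithmetic trees over constants, identifiers,
  ``+ - * / ^`` and ``exp``.  This is the restricted MathML subset used for
  kinetic laws and SED-ML data-generator math.  Trees can be evaluated over
  scalar or :mod:`numpy` vector bindings, compiled to a fast callable for the
  integrator inner loops, and round-tripped to content MathML.
* :class:`BoolExpression` — boolean trees over node identifiers with
  ``! & |`` and parentheses, the update-rule dialect of BoolNet-style
  logical models.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable

import numpy as np
from lxml import etree

from ._errors import SimexError

MATHML_NS = "http://www.w3.org/1998/Math/MathML"

_OPS = {"plus", "minus", "times", "divide", "power", "exp"}


@dataclass(frozen=True)
class MathExpression:
    """Arithmetic expression tree.

    ``node`` is a nested tuple: ``('num', float)``, ``('sym', name)`` or
    ``('call', op, (MathExpression, ...))`` with ``op`` one of
    plus/minus/times/divide/power/exp.
    """

    node: tuple

    # -- constructors -------------------------------------------------
    @staticmethod
    def num(value: float) -> "MathExpression":
        return MathExpression(("num", float(value)))

    @staticmethod
    def sym(name: str) -> "MathExpression":
        return MathExpression(("sym", str(name)))

    @staticmethod
    def call(op: str, *args: "MathExpression") -> "MathExpression":
        if op not in _OPS:
            raise SimexError("UNSUPPORTED_CONSTRUCT", f"unknown operator {op!r}")
        return MathExpression(("call", op, tuple(args)))

    # -- queries ------------------------------------------------------
    def identifiers(self) -> set:
        kind = self.node[0]
        if kind == "num":
            return set()
        if kind == "sym":
            return {self.node[1]}
        out: set = set()
        for arg in self.node[2]:
            out |= arg.identifiers()
        return out

    def evaluate(self, env: dict):
        """Evaluate over a complete binding; values may be floats or arrays."""
        kind = self.node[0]
        if kind == "num":
            return self.node[1]
        if kind == "sym":
            name = self.node[1]
            if name not in env:
                raise SimexError("MISSING_VARIABLE", f"unbound identifier {name!r}")
            return env[name]
        op, args = self.node[1], [a.evaluate(env) for a in self.node[2]]
        if op == "plus":
            out = args[0]
            for a in args[1:]:
                out = out + a
            return out
        if op == "minus":
            if len(args) == 1:
                return -args[0]
            return args[0] - args[1]
        if op == "times":
            out = args[0]
            for a in args[1:]:
                out = out * a
            return out
        if op == "divide":
            return args[0] / args[1]
        if op == "power":
            return args[0] ** args[1]
        if op == "exp":
            return np.exp(args[0])
        raise SimexError("UNSUPPORTED_CONSTRUCT", f"operator {op!r}")  # pragma: no cover

    def compile(self):
        """Compile to ``f(env) -> value`` for tight integrator loops."""
        src = self._to_python()
        code = compile(src, "<math-expression>", "eval")

        def fn(env, _code=code, _exp=np.exp):
            return eval(_code, {"__builtins__": {}, "_exp": _exp}, {"env": env})

        return fn

    def _to_python(self) -> str:
        kind = self.node[0]
        if kind == "num":
            return repr(self.node[1])
        if kind == "sym":
            return f"env[{self.node[1]!r}]"
        op = self.node[1]
        parts = [a._to_python() for a in self.node[2]]
        if op == "plus":
            return "(" + "+".join(parts) + ")"
        if op == "minus":
            return f"(-{parts[0]})" if len(parts) == 1 else f"({parts[0]}-{parts[1]})"
        if op == "times":
            return "(" + "*".join(parts) + ")"
        if op == "divide":
            return f"({parts[0]}/{parts[1]})"
        if op == "power":
            return f"(({parts[0]})**({parts[1]}))"
        if op == "exp":
            return f"_exp({parts[0]})"
        raise SimexError("UNSUPPORTED_CONSTRUCT", f"operator {op!r}")  # pragma: no cover

    # -- MathML -------------------------------------------------------
    @staticmethod
    def from_mathml(element) -> "MathExpression":
        """Parse a content-MathML element (``<math>`` wrapper or bare node)."""
        tag = etree.QName(element).localname
        if tag == "math":
            children = [c for c in element if isinstance(c.tag, str)]
            if len(children) != 1:
                raise SimexError("UNSUPPORTED_CONSTRUCT", "math element must wrap one node")
            return MathExpression.from_mathml(children[0])
        if tag == "cn":
            try:
                return MathExpression.num(float(element.text.strip()))
            except (TypeError, ValueError, AttributeError):
                raise SimexError("MODEL_SYNTAX_ERROR", "cn element without numeric text")
        if tag == "ci":
            name = (element.text or "").strip()
            if not name:
                raise SimexError("MODEL_SYNTAX_ERROR", "ci element without identifier")
            return MathExpression.sym(name)
        if tag == "apply":
            children = [c for c in element if isinstance(c.tag, str)]
            if not children:
                raise SimexError("MODEL_SYNTAX_ERROR", "empty apply element")
            op = etree.QName(children[0]).localname
            if op not in _OPS:
                raise SimexError("UNSUPPORTED_CONSTRUCT", f"MathML operator {op!r} outside subset")
            args = tuple(MathExpression.from_mathml(c) for c in children[1:])
            if op in ("divide", "power") and len(args) != 2:
                raise SimexError("MODEL_SYNTAX_ERROR", f"{op} takes exactly two operands")
            if op == "exp" and len(args) != 1:
                raise SimexError("MODEL_SYNTAX_ERROR", "exp takes one operand")
            if op == "minus" and len(args) not in (1, 2):
                raise SimexError("MODEL_SYNTAX_ERROR", "minus takes one or two operands")
            if op in ("plus", "times") and len(args) < 1:
                raise SimexError("MODEL_SYNTAX_ERROR", f"{op} needs at least one operand")
            return MathExpression.call(op, *args)
        raise SimexError("UNSUPPORTED_CONSTRUCT", f"MathML node {tag!r} outside subset")

    def to_mathml(self):
        """Serialize to a ``<math>`` element in the MathML namespace."""
        math = etree.Element(f"{{{MATHML_NS}}}math", nsmap={None: MATHML_NS})
        math.append(self._to_mathml_node())
        return math

    def _to_mathml_node(self):
        kind = self.node[0]
        if kind == "num":
            el = etree.Element(f"{{{MATHML_NS}}}cn")
            value = self.node[1]
            el.text = repr(value)
            return el
        if kind == "sym":
            el = etree.Element(f"{{{MATHML_NS}}}ci")
            el.text = self.node[1]
            return el
        op, args = self.node[1], self.node[2]
        apply = etree.Element(f"{{{MATHML_NS}}}apply")
        apply.append(etree.Element(f"{{{MATHML_NS}}}{op}"))
        for a in args:
            apply.append(a._to_mathml_node())
        return apply

    # -- text form ----------------------------------------------------
    @staticmethod
    def parse(text: str) -> "MathExpression":
        """Parse infix text: numbers, identifiers, ``+ - * / ^``, ``exp(x)``."""
        return _MathParser(text).parse()


_TOKEN_RE = re.compile(
    r"\s*(?:(?P<num>\d+\.?\d*(?:[eE][+-]?\d+)?|\.\d+)|(?P<name>[A-Za-z_][A-Za-z0-9_]*)"
    r"|(?P<op>[-+*/^()]))"
)


class _MathParser:
    def __init__(self, text: str):
        self.tokens = []
        pos = 0
        while pos < len(text):
            m = _TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                if text[pos:].strip():
                    raise SimexError("MODEL_SYNTAX_ERROR", f"bad token at {text[pos:]!r}")
                break
            if m.lastgroup == "num":
                self.tokens.append(("num", float(m.group("num"))))
            elif m.lastgroup == "name":
                self.tokens.append(("name", m.group("name")))
            else:
                self.tokens.append(("op", m.group("op")))
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self) -> MathExpression:
        expr = self._sum()
        if self.i != len(self.tokens):
            raise SimexError("MODEL_SYNTAX_ERROR", "trailing tokens in expression")
        return expr

    def _sum(self):
        node = self._product()
        while self.peek() == ("op", "+") or self.peek() == ("op", "-"):
            op = self.take()[1]
            rhs = self._product()
            node = MathExpression.call("plus" if op == "+" else "minus", node, rhs)
        return node

    def _product(self):
        node = self._power()
        while self.peek() == ("op", "*") or self.peek() == ("op", "/"):
            op = self.take()[1]
            rhs = self._power()
            node = MathExpression.call("times" if op == "*" else "divide", node, rhs)
        return node

    def _power(self):
        node = self._atom()
        if self.peek() == ("op", "^"):
            self.take()
            return MathExpression.call("power", node, self._power())
        return node

    def _atom(self):
        kind, value = self.take()
        if kind == "num":
            return MathExpression.num(value)
        if kind == "name":
            if value == "exp" and self.peek() == ("op", "("):
                self.take()
                arg = self._sum()
                if self.take() != ("op", ")"):
                    raise SimexError("MODEL_SYNTAX_ERROR", "unbalanced parentheses")
                return MathExpression.call("exp", arg)
            return MathExpression.sym(value)
        if (kind, value) == ("op", "("):
            node = self._sum()
            if self.take() != ("op", ")"):
                raise SimexError("MODEL_SYNTAX_ERROR", "unbalanced parentheses")
            return node
        if (kind, value) == ("op", "-"):
            return MathExpression.call("minus", self._atom())
        raise SimexError("MODEL_SYNTAX_ERROR", f"unexpected token {value!r}")


# ---------------------------------------------------------------------------
# Boolean expressions


@dataclass(frozen=True)
class BoolExpression:
    """Boolean update rule: ``('sym', id) | ('const', 0/1) | ('not'|'and'|'or', ...)``."""

    node: tuple

    @staticmethod
    def sym(name: str) -> "BoolExpression":
        return BoolExpression(("sym", name))

    @staticmethod
    def const(value: int) -> "BoolExpression":
        return BoolExpression(("const", 1 if value else 0))

    def identifiers(self) -> set:
        kind = self.node[0]
        if kind == "sym":
            return {self.node[1]}
        if kind == "const":
            return set()
        out: set = set()
        for arg in self.node[1:]:
            out |= arg.identifiers()
        return out

    def evaluate(self, env: dict) -> int:
        kind = self.node[0]
        if kind == "sym":
            name = self.node[1]
            if name not in env:
                raise SimexError("MISSING_VARIABLE", f"unbound node {name!r}")
            return 1 if env[name] else 0
        if kind == "const":
            return self.node[1]
        if kind == "not":
            return 1 - self.node[1].evaluate(env)
        if kind == "and":
            return self.node[1].evaluate(env) & self.node[2].evaluate(env)
        return self.node[1].evaluate(env) | self.node[2].evaluate(env)

    def to_text(self) -> str:
        kind = self.node[0]
        if kind == "sym":
            return self.node[1]
        if kind == "const":
            return str(self.node[1])
        if kind == "not":
            return f"!({self.node[1].to_text()})"
        op = " & " if kind == "and" else " | "
        return f"({self.node[1].to_text()}{op}{self.node[2].to_text()})"

    @staticmethod
    def parse(text: str) -> "BoolExpression":
        return _BoolParser(text).parse()


_BOOL_TOKEN_RE = re.compile(r"\s*(?:(?P<name>[A-Za-z_][A-Za-z0-9_]*)|(?P<op>[!&|()01]))")


class _BoolParser:
    def __init__(self, text: str):
        self.tokens = []
        pos = 0
        while pos < len(text):
            m = _BOOL_TOKEN_RE.match(text, pos)
            if not m or m.end() == pos:
                if text[pos:].strip():
                    raise SimexError("MODEL_SYNTAX_ERROR", f"bad token at {text[pos:]!r}")
                break
            if m.lastgroup == "name":
                self.tokens.append(("name", m.group("name")))
            else:
                self.tokens.append(("op", m.group("op")))
            pos = m.end()
        self.i = 0

    def peek(self):
        return self.tokens[self.i] if self.i < len(self.tokens) else (None, None)

    def take(self):
        tok = self.peek()
        self.i += 1
        return tok

    def parse(self) -> BoolExpression:
        node = self._or()
        if self.i != len(self.tokens):
            raise SimexError("MODEL_SYNTAX_ERROR", "trailing tokens in boolean expression")
        return node

    def _or(self):
        node = self._and()
        while self.peek() == ("op", "|"):
            self.take()
            node = BoolExpression(("or", node, self._and()))
        return node

    def _and(self):
        node = self._atom()
        while self.peek() == ("op", "&"):
            self.take()
            node = BoolExpression(("and", node, self._atom()))
        return node

    def _atom(self):
        kind, value = self.take()
        if kind == "name":
            return BoolExpression.sym(value)
        if (kind, value) == ("op", "!"):
            return BoolExpression(("not", self._atom()))
        if (kind, value) in (("op", "0"), ("op", "1")):
            return BoolExpression.const(int(value))
        if (kind, value) == ("op", "("):
            node = self._or()
            if self.take() != ("op", ")"):
                raise SimexError("MODEL_SYNTAX_ERROR", "unbalanced parentheses")
            return node
        raise SimexError("MODEL_SYNTAX_ERROR", f"unexpected token {value!r}")


def iter_local(element, name: str) -> Iterable:
    """Children of ``element`` whose local (namespace-stripped) tag is ``name``."""
    for child in element:
        if isinstance(child.tag, str) and etree.QName(child).localname == name:
            yield child
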