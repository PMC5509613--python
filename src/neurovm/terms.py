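"""Symbolic terms and unification.

Terms are the circuit language's atoms of meaning: thread names
(``sense(cs)``), signals, guards, cached values and weight keys are all
first-order terms with a Prolog-flavoured surface syntax.  Atoms and
functors start with a lowercase letter, variables with an uppercase letter
or underscore, and ``[a, b]`` is sugar for a cons chain.  Unification
against a dynamic set of such terms is the virtual machine's only
inference mechanism.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Mapping, Optional

__all__ = [
    "Term",
    "Var",
    "atom",
    "compound",
    "make_list",
    "list_items",
    "parse_term",
    "format_term",
    "unify",
    "substitute",
    "is_ground",
    "variables",
    "rename_vars",
    "TermSyntaxError",
]

NIL = "[]"
CONS = "."


@dataclass(frozen=True)
class Var:
    """A logic variable; distinct names are distinct variables."""

    name: str

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Var({self.name})"


@dataclass(frozen=True)
class Term:
    """A compound term ``functor(args...)``; zero arity makes an atom."""

    functor: str
    args: tuple = ()

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Term({format_term(self)})"


def atom(name: str) -> Term:
    return Term(name, ())


def compound(functor: str, *args) -> Term:
    return Term(functor, tuple(args))


def make_list(items) -> Term:
    out = atom(NIL)
    for it in reversed(list(items)):
        out = Term(CONS, (it, out))
    return out


def list_items(t: Term) -> Optional[list]:
    """Return the elements of a proper list term, or None if not a list."""
    items = []
    while True:
        if isinstance(t, Term) and t.functor == NIL and not t.args:
            return items
        if isinstance(t, Term) and t.functor == CONS and len(t.args) == 2:
            items.append(t.args[0])
            t = t.args[1]
        else:
            return None


# ---------------------------------------------------------------------------
# parsing


class TermSyntaxError(ValueError):
    def __init__(self, message: str, line: int = 1, column: int = 1):
        super().__init__(f"{message} (line {line}, column {column})")
        self.line = line
        self.column = column


_ATOM_START = "abcdefghijklmnopqrstuvwxyz"
_VAR_START = "ABCDEFGHIJKLMNOPQRSTUVWXYZ_"
_NAME_CHARS = set("abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ0123456789_")


class _Scanner:
    """Shared tokenizer for terms; the .nvm reader reuses it."""

    def __init__(self, text: str, line: int = 1, column: int = 1):
        self.text = text
        self.pos = 0
        self.line = line
        self.column = column

    def error(self, msg: str) -> TermSyntaxError:
        return TermSyntaxError(msg, self.line, self.column)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def advance(self) -> str:
        ch = self.text[self.pos]
        self.pos += 1
        if ch == "\n":
            self.line += 1
            self.column = 1
        else:
            self.column += 1
        return ch

    def skip_ws(self) -> None:
        while self.pos < len(self.text):
            ch = self.peek()
            if ch in " \t\r\n":
                self.advance()
            elif ch == "#":  # line comment
                while self.pos < len(self.text) and self.peek() != "\n":
                    self.advance()
            else:
                return

    def at_end(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def expect(self, ch: str) -> None:
        self.skip_ws()
        if self.peek() != ch:
            raise self.error(f"expected '{ch}', found {self.peek()!r}")
        self.advance()

    def try_consume(self, ch: str) -> bool:
        self.skip_ws()
        if self.peek() == ch:
            self.advance()
            return True
        return False

    def name(self) -> str:
        self.skip_ws()
        start = self.pos
        if self.peek() not in _NAME_CHARS:
            raise self.error(f"expected a name, found {self.peek()!r}")
        while self.pos < len(self.text) and self.peek() in _NAME_CHARS:
            self.advance()
        return self.text[start : self.pos]

    def term(self) -> Term | Var:
        self.skip_ws()
        ch = self.peek()
        if ch == "":
            raise self.error("unexpected end of input in term")
        if ch == "[":
            self.advance()
            items = []
            if self.try_consume("]"):
                return atom(NIL)
            while True:
                items.append(self.term())
                if self.try_consume("]"):
                    return make_list(items)
                self.expect(",")
        if ch == "-" or ch.isdigit():
            start = self.pos
            self.advance()
            while self.pos < len(self.text) and self.peek().isdigit():
                self.advance()
            text = self.text[start : self.pos]
            if text == "-":
                raise self.error("lone '-' is not a term")
            return atom(text)  # integers kept as atoms; weights parse them
        if ch in _VAR_START:
            return Var(self.name())
        if ch in _ATOM_START:
            fname = self.name()
            if self.try_consume("("):
                args = []
                if self.try_consume(")"):
                    raise self.error(f"empty argument list after {fname!r}")
                while True:
                    args.append(self.term())
                    if self.try_consume(")"):
                        return Term(fname, tuple(args))
                    self.expect(",")
            return atom(fname)
        raise self.error(f"unexpected character {ch!r} in term")


def parse_term(text: str) -> Term | Var:
    sc = _Scanner(text)
    t = sc.term()
    if not sc.at_end():
        raise sc.error("trailing input after term")
    return t


def format_term(t: Term | Var) -> str:
    if isinstance(t, Var):
        return t.name
    items = list_items(t)
    if items is not None:
        return "[" + ", ".join(format_term(i) for i in items) + "]"
    if not t.args:
        return t.functor
    return t.functor + "(" + ", ".join(format_term(a) for a in t.args) + ")"


# ---------------------------------------------------------------------------
# unification

Subst = Mapping[Var, "Term | Var"]


def walk(t, subst: Subst):
    while isinstance(t, Var) and t in subst:
        t = subst[t]
    return t


def _occurs(v: Var, t, subst) -> bool:
    t = walk(t, subst)
    if isinstance(t, Var):
        return t == v
    return any(_occurs(v, a, subst) for a in t.args)


def unify(a, b, subst: Optional[dict] = None) -> Optional[dict]:
    """Most general unifier of two terms, or None.

    Returns a (possibly extended copy of the) substitution dict.  Occurs
    check included: terms stay finite.
    """
    s = dict(subst) if subst else {}
    stack = [(a, b)]
    while stack:
        x, y = stack.pop()
        x, y = walk(x, s), walk(y, s)
        if x is y or x == y:
            continue
        if isinstance(x, Var):
            if _occurs(x, y, s):
                return None
            s[x] = y
        elif isinstance(y, Var):
            if _occurs(y, x, s):
                return None
            s[y] = x
        elif isinstance(x, Term) and isinstance(y, Term):
            if x.functor != y.functor or len(x.args) != len(y.args):
                return None
            stack.extend(zip(x.args, y.args))
        else:  # pragma: no cover - defensive
            return None
    return s


def substitute(t, subst: Subst):
    t = walk(t, subst)
    if isinstance(t, Var):
        return t
    if not t.args:
        return t
    return Term(t.functor, tuple(substitute(a, subst) for a in t.args))


def is_ground(t) -> bool:
    if isinstance(t, Var):
        return False
    return all(is_ground(a) for a in t.args)


def variables(t) -> Iterator[Var]:
    if isinstance(t, Var):
        yield t
    else:
        for a in t.args:
            yield from variables(a)


_rename_counter = [0]


def rename_vars(t, mapping: Optional[dict] = None, tag: Optional[str] = None):
    """Freshen the variables of a term (apart-renaming for instantiation).

    With `tag` the fresh names are ``X~tag`` — deterministic for a caller
    that manages its own sequence; otherwise a process-global counter is
    used.
    """
    if mapping is None:
        mapping = {}
    if isinstance(t, Var):
        if t not in mapping:
            if tag is None:
                _rename_counter[0] += 1
                suffix = str(_rename_counter[0])
            else:
                suffix = tag
            mapping[t] = Var(f"{t.name}~{suffix}")
        return mapping[t]
    if not t.args:
        return t
    return Term(
        t.functor, tuple(rename_vars(a, mapping, tag) for a in t.args)
    )
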