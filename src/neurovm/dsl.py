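"""The circuit description language (language S).

A model is a set of named fibers, each a disjoint set of threads; a thread
body is an *instruction tree* — either a sequence of virtual instructions
or an alternative of guarded branches.  Guards test the four internal
stimulus registers (fetch, catch, excite, inhibit).  Models additionally
declare initial synaptic weights for intra-fiber thread pairs, the
environment's accept set, and a sensor map routing external stimuli to
sensory threads.

Concrete `.nvm` syntax (UTF-8, ``#`` line comments)::

    model classical

    fiber net {
      thread sense(us): [fire(ltp(sense(cs), motor(cs))), fire(motor(us)), send(motor(us))]
      thread motor(cs): [receive(sense(cs)), emit(withdraw(cs))]
    }

    weights {
      net: sense(cs) -> motor(cs) = 0
    }

    accept {
      net: [mat, smooth]
    }

    sensors {
      cs -> net: sense(cs)
    }

Grammar for trees::

    Tree  ::= '[' Step (',' Step)* ']' | '[]'
    Step  ::= Instruction | '{' Guard '->' Tree (';' Guard '->' Tree)* '}'
    Guard ::= 'always' | Kind '(' Term ')'          Kind in {fetch, catch, excite, inhibit}

Parameterized thread names (``learn(accept(I))``) are templates,
instantiated lazily the first time a matching stimulus arrives or the
thread is fired with a ground argument.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Union

from .terms import (
    Term,
    Var,
    _Scanner,
    TermSyntaxError,
    format_term,
    is_ground,
    unify,
)

__all__ = [
    "STIMULUS_KINDS",
    "OPCODES",
    "BASIC_THREADS",
    "Guard",
    "ALWAYS",
    "Instr",
    "Seq",
    "Alt",
    "ThreadSpec",
    "FiberSpec",
    "SensorRoute",
    "WeightDecl",
    "ModelSpec",
    "Diagnostic",
    "parse_model",
    "serialize_model",
    "validate",
    "ModelValidationError",
]

#: the four internal-stimulus register names
STIMULUS_KINDS = ("fetch", "catch", "excite", "inhibit")

#: public instruction set with arities; internal plasticity opcodes
#: (potentiate/depress) are emitted only by the basic-thread templates and
#: are not part of the surface language.
OPCODES = {
    "fire": 1,
    "send": 1,
    "receive": 1,
    "join": 1,
    "merge": 1,
    "push": 2,
    "pull": 1,
    "reset": 1,
    "broadcast": 1,
    "lts": 1,
    "ltr": 3,
    "emit": 1,
}

#: functors resolvable as built-in protocol threads when fired
BASIC_THREADS = ("ltp", "ltd", "lts", "ltr")


@dataclass(frozen=True)
class Guard:
    """``always`` or ``kind(pattern)`` over an internal-stimulus register."""

    kind: str  # 'always' or one of STIMULUS_KINDS
    pattern: Optional[Union[Term, Var]] = None

    @property
    def is_always(self) -> bool:
        return self.kind == "always"

    def __str__(self) -> str:
        if self.is_always:
            return "always"
        return f"{self.kind}({format_term(self.pattern)})"


ALWAYS = Guard("always")


@dataclass(frozen=True)
class Instr:
    """A virtual instruction leaf; the term's functor is the opcode."""

    term: Term

    @property
    def opcode(self) -> str:
        return self.term.functor

    @property
    def args(self) -> tuple:
        return self.term.args

    def __str__(self) -> str:
        return format_term(self.term)


@dataclass(frozen=True)
class Seq:
    steps: tuple = ()  # of Instr | Alt


@dataclass(frozen=True)
class Alt:
    branches: tuple = ()  # of (Guard, Seq)


Tree = Union[Seq, Alt, Instr]


@dataclass(frozen=True)
class ThreadSpec:
    name: Term
    body: Seq


@dataclass(frozen=True)
class FiberSpec:
    name: str
    threads: tuple = ()  # of ThreadSpec


@dataclass(frozen=True)
class WeightDecl:
    fiber: str
    source: Term
    recipient: Term
    weight: int


@dataclass(frozen=True)
class SensorRoute:
    pattern: Term  # sensor term pattern, e.g. item(I)
    fiber: str
    thread: Term  # target sensory-thread pattern, e.g. sense(I)


@dataclass(frozen=True)
class ModelSpec:
    name: str
    fibers: tuple = ()  # of FiberSpec
    weights: tuple = ()  # of WeightDecl
    accept: tuple = ()  # of (fiber, Term)
    sensors: tuple = ()  # of SensorRoute

    def fiber(self, name: str) -> FiberSpec:
        for f in self.fibers:
            if f.name == name:
                return f
        raise KeyError(name)


# ---------------------------------------------------------------------------
# parsing


class ModelValidationError(ValueError):
    pass


def _parse_guard(sc: _Scanner) -> Guard:
    mark = (sc.pos, sc.line, sc.column)
    name = sc.name()
    if name == "always":
        return Guard("always")
    if name not in STIMULUS_KINDS:
        sc.pos, sc.line, sc.column = mark
        raise sc.error(
            f"guard kind must be 'always' or one of {STIMULUS_KINDS}, got {name!r}"
        )
    sc.expect("(")
    pat = sc.term()
    sc.expect(")")
    return Guard(name, pat)


def _parse_tree(sc: _Scanner) -> Seq:
    sc.expect("[")
    if sc.try_consume("]"):
        return Seq(())
    steps = []
    while True:
        sc.skip_ws()
        if sc.peek() == "{":
            sc.advance()
            branches = []
            while True:
                g = _parse_guard(sc)
                sc.skip_ws()
                sc.expect("-")
                sc.expect(">")
                t = _parse_tree(sc)
                branches.append((g, t))
                if sc.try_consume("}"):
                    break
                sc.expect(";")
            steps.append(Alt(tuple(branches)))
        else:
            t = sc.term()
            if isinstance(t, Var):
                raise sc.error("an instruction cannot be a bare variable")
            steps.append(Instr(t))
        if sc.try_consume("]"):
            return Seq(tuple(steps))
        sc.expect(",")


def parse_model(text: str) -> ModelSpec:
    """Parse `.nvm` source into a validated :class:`ModelSpec`.

    Raises :class:`~neurovm.terms.TermSyntaxError` with line/column on
    syntax errors and :class:`ModelValidationError` on invariant
    violations.
    """
    sc = _Scanner(text)
    sc.skip_ws()
    if sc.name() != "model":
        raise sc.error("a model file must start with 'model <name>'")
    model_name = sc.name()
    fibers: list[FiberSpec] = []
    weights: list[WeightDecl] = []
    accept: list[tuple] = []
    sensors: list[SensorRoute] = []
    while not sc.at_end():
        section = sc.name()
        if section == "fiber":
            fiber_name = sc.name()
            sc.expect("{")
            threads = []
            while not sc.try_consume("}"):
                kw = sc.name()
                if kw != "thread":
                    raise sc.error(f"expected 'thread' in fiber block, got {kw!r}")
                name = sc.term()
                if isinstance(name, Var):
                    raise sc.error("thread name cannot be a bare variable")
                sc.expect(":")
                body = _parse_tree(sc)
                threads.append(ThreadSpec(name, body))
            fibers.append(FiberSpec(fiber_name, tuple(threads)))
        elif section == "weights":
            sc.expect("{")
            while not sc.try_consume("}"):
                fiber = sc.name()
                sc.expect(":")
                src = sc.term()
                sc.expect("-")
                sc.expect(">")
                dst = sc.term()
                sc.expect("=")
                sc.skip_ws()
                neg = sc.try_consume("-")
                digits = sc.name()
                if not digits.isdigit():
                    raise sc.error(f"weight must be an integer, got {digits!r}")
                w = -int(digits) if neg else int(digits)
                weights.append(WeightDecl(fiber, src, dst, w))
        elif section == "accept":
            sc.expect("{")
            while not sc.try_consume("}"):
                fiber = sc.name()
                sc.expect(":")
                accept.append((fiber, sc.term()))
        elif section == "sensors":
            sc.expect("{")
            while not sc.try_consume("}"):
                pat = sc.term()
                sc.expect("-")
                sc.expect(">")
                fiber = sc.name()
                sc.expect(":")
                thread = sc.term()
                sensors.append(SensorRoute(pat, fiber, thread))
        else:
            raise sc.error(f"unknown section {section!r}")
    model = ModelSpec(
        model_name, tuple(fibers), tuple(weights), tuple(accept), tuple(sensors)
    )
    diags = validate(model)
    errors = [d for d in diags if d.severity == "error"]
    if errors:
        raise ModelValidationError(
            "; ".join(str(d) for d in errors)
        )
    return model


# ---------------------------------------------------------------------------
# serialization (canonical normal form; parse o serialize == identity)


def _fmt_tree(tree: Seq) -> str:
    parts = []
    for step in tree.steps:
        if isinstance(step, Instr):
            parts.append(format_term(step.term))
        else:
            branches = "; ".join(
                f"{g} -> {_fmt_tree(t)}" for g, t in step.branches
            )
            parts.append("{" + branches + "}")
    return "[" + ", ".join(parts) + "]"


def serialize_model(model: ModelSpec) -> str:
    out = [f"model {model.name}", ""]
    for f in model.fibers:
        out.append(f"fiber {f.name} {{")
        for th in f.threads:
            out.append(f"  thread {format_term(th.name)}: {_fmt_tree(th.body)}")
        out.append("}")
        out.append("")
    if model.weights:
        out.append("weights {")
        for w in model.weights:
            out.append(
                f"  {w.fiber}: {format_term(w.source)} -> "
                f"{format_term(w.recipient)} = {w.weight}"
            )
        out.append("}")
        out.append("")
    if model.accept:
        out.append("accept {")
        for fiber, t in model.accept:
            out.append(f"  {fiber}: {format_term(t)}")
        out.append("}")
        out.append("")
    if model.sensors:
        out.append("sensors {")
        for s in model.sensors:
            out.append(
                f"  {format_term(s.pattern)} -> {s.fiber}: {format_term(s.thread)}"
            )
        out.append("}")
        out.append("")
    return "\n".join(out).rstrip() + "\n"


# ---------------------------------------------------------------------------
# validation


@dataclass(frozen=True)
class Diagnostic:
    severity: str  # 'error' | 'warning'
    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity} at {self.location}: {self.message}"


def _iter_instrs(tree: Seq):
    for step in tree.steps:
        if isinstance(step, Instr):
            yield step
        else:
            for _, t in step.branches:
                yield from _iter_instrs(t)


def _matches_some_thread(target, fiber: FiberSpec) -> bool:
    if isinstance(target, Term) and target.functor in BASIC_THREADS:
        return True
    return any(unify(target, th.name) is not None for th in fiber.threads)


def validate(model: ModelSpec) -> list[Diagnostic]:
    """Check every structural invariant; empty list means the model is valid."""
    diags: list[Diagnostic] = []
    seen: dict[str, str] = {}  # canonical thread name -> fiber
    fiber_names = {f.name for f in model.fibers}
    for f in model.fibers:
        for th in f.threads:
            key = format_term(th.name)
            loc = f"fiber {f.name}, thread {key}"
            if key in seen:
                where = seen[key]
                msg = (
                    "duplicate thread name"
                    if where == f.name
                    else f"thread also declared in fiber {where}; fibers are disjoint"
                )
                diags.append(Diagnostic("error", loc, msg))
            seen[key] = f.name
            for ins in _iter_instrs(th.body):
                if ins.opcode not in OPCODES:
                    diags.append(
                        Diagnostic("error", loc, f"unknown opcode {ins.opcode!r}")
                    )
                elif len(ins.args) != OPCODES[ins.opcode]:
                    diags.append(
                        Diagnostic(
                            "error",
                            loc,
                            f"{ins.opcode} expects {OPCODES[ins.opcode]} args, "
                            f"got {len(ins.args)}",
                        )
                    )
                if ins.opcode in ("fire", "send") and not _matches_some_thread(
                    ins.args[0], f
                ):
                    diags.append(
                        Diagnostic(
                            "error",
                            loc,
                            f"unknown recipient {format_term(ins.args[0])} "
                            f"(no declared or basic thread matches)",
                        )
                    )
            diags.extend(_check_alternatives(th.body, loc))
    for w in model.weights:
        loc = f"weight {format_term(w.source)} -> {format_term(w.recipient)}"
        if w.fiber not in fiber_names:
            diags.append(Diagnostic("error", loc, f"unknown fiber {w.fiber!r}"))
            continue
        fiber = model.fiber(w.fiber)
        for end, role in ((w.source, "source"), (w.recipient, "recipient")):
            if not _matches_some_thread(end, fiber):
                diags.append(
                    Diagnostic(
                        "error",
                        loc,
                        f"{role} {format_term(end)} matches no thread of fiber "
                        f"{w.fiber!r}; weights are intra-fiber",
                    )
                )
    for s in model.sensors:
        loc = f"sensor {format_term(s.pattern)}"
        if s.fiber not in fiber_names:
            diags.append(Diagnostic("error", loc, f"unknown fiber {s.fiber!r}"))
        elif not any(
            unify(s.thread, th.name) is not None
            for th in model.fiber(s.fiber).threads
        ):
            diags.append(
                Diagnostic(
                    "error",
                    loc,
                    f"target {format_term(s.thread)} matches no thread of "
                    f"fiber {s.fiber!r}",
                )
            )
    for fiber, t in model.accept:
        if fiber not in fiber_names:
            diags.append(
                Diagnostic(
                    "error", f"accept {format_term(t)}", f"unknown fiber {fiber!r}"
                )
            )
        elif not is_ground(t):
            diags.append(
                Diagnostic(
                    "error",
                    f"accept {format_term(t)}",
                    "accept elements must be ground",
                )
            )
    return diags


def _check_alternatives(tree: Seq, loc: str) -> list[Diagnostic]:
    diags = []
    for step in tree.steps:
        if isinstance(step, Alt):
            n_always = sum(1 for g, _ in step.branches if g.is_always)
            if n_always > 1:
                diags.append(
                    Diagnostic(
                        "error", loc, "an alternative may have at most one "
                        "'always' (default) branch"
                    )
                )
            for _, t in step.branches:
                diags.extend(_check_alternatives(t, loc))
    return diags
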