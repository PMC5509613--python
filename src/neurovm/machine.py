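"""The virtual machine: state, contextual deduction, and the run cycle.

A loaded model is a content-addressable memory of compiled implications,
weights and accept elements, initially without any active thread.  A
*run* is a loop of interrupts: each cycle a ``sense`` step terminates the
interrupted stream (clearing its registers, queues and tokens — pending
coincidences vanish, which is what makes LTP a per-trial coincidence
detector), activates the sensory threads named by the interrupt, and
writes internal stimuli into registers; a ``react`` step then sweeps the
active threads, deducing and executing one instruction per thread per
sweep until quiescence.  A thread whose instruction fails simply retries
on the next sweep; its local clock advances only on success.

Weights, short-term caches and long-term memory persist across stream
terminations; registers, signal queues and modulation tokens do not.
Given (model, config, script) the machine is fully deterministic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional

from .compiler import CodeImplication, compile_thread, compile_tree
from .dsl import (
    ALWAYS,
    Alt,
    Guard,
    Instr,
    ModelSpec,
    Seq,
    ThreadSpec,
    STIMULUS_KINDS,
)
from .protocols import ExecError, LtmStore, WeightTable, execute
from .terms import (
    Term,
    Var,
    compound,
    format_term,
    is_ground,
    parse_term,
    rename_vars,
    substitute,
    unify,
)

__all__ = [
    "Context",
    "RunConfig",
    "Cycle",
    "TraceEvent",
    "MachineState",
    "LivelockError",
    "AmbiguousGuardError",
    "RunError",
    "ist",
    "load",
    "run",
]


class RunError(RuntimeError):
    pass


class LivelockError(RunError):
    pass


class AmbiguousGuardError(RunError):
    pass


# ---------------------------------------------------------------------------
# context: a dynamic set of terms under unification


class Context:
    """A dynamic set of symbolic terms; each instance is a non-logical axiom.

    set/get/delete under unification-based matching; this is the machine's
    model of both a content-addressable memory and a queue (buffers whose
    values can be accessed in any order).
    """

    def __init__(self, items: Iterable[Term] = ()):
        self._items: list[Term] = []
        for t in items:
            self.set(t)

    def set(self, t: Term) -> None:
        if is_ground(t) and any(x == t for x in self._items):
            return  # no duplicates of identical ground terms
        self._items.append(t)

    def get(self, pattern) -> Optional[dict]:
        for t in self._items:
            b = unify(pattern, t)
            if b is not None:
                return b
        return None

    def get_all(self, pattern) -> list[dict]:
        out = []
        for t in self._items:
            b = unify(pattern, t)
            if b is not None:
                out.append(b)
        return out

    def delete(self, pattern) -> bool:
        for i, t in enumerate(self._items):
            if unify(pattern, t) is not None:
                self._items.pop(i)
                return True
        return False

    def __len__(self) -> int:
        return len(self._items)

    def __iter__(self):
        return iter(self._items)


def ist(context: Context, query) -> bool:
    """'Is true in this context': a bare term holds iff the context
    contains a unifiable instance."""
    return context.get(query) is not None


# ---------------------------------------------------------------------------
# configuration and script


@dataclass
class RunConfig:
    """Machine parameters.  All dimensionless integers.

    theta   -- receive threshold: a synaptic pathway is open iff its
               weight >= theta (default 1).
    delta   -- LTP/LTD step size (default 1).
    w_min, w_max -- weight clamp bounds (default 0..5).
    sweep_cap -- livelock guard: max react sweeps per run cycle.
    seed    -- seed for the script generators; the machine itself draws
               no randomness.
    """

    theta: int = 1
    delta: int = 1
    w_min: int = 0
    w_max: int = 5
    sweep_cap: int = 1000
    seed: int = 0

    def __post_init__(self):
        if self.theta < 1 or self.delta < 1 or self.w_min > self.w_max:
            raise ValueError("require theta >= 1, delta >= 1, w_min <= w_max")


@dataclass(frozen=True)
class Cycle:
    """One interrupt: target stream, captured sensor terms, internal stimuli."""

    fiber: str
    sensors: tuple = ()
    stimuli: tuple = ()

    def to_json(self) -> str:
        return json.dumps(
            {
                "fiber": self.fiber,
                "sensors": [format_term(s) for s in self.sensors],
                "stimuli": [format_term(s) for s in self.stimuli],
            },
            sort_keys=True,
        )

    @staticmethod
    def from_json(line: str) -> "Cycle":
        d = json.loads(line)
        return Cycle(
            d["fiber"],
            tuple(parse_term(s) for s in d["sensors"]),
            tuple(parse_term(s) for s in d["stimuli"]),
        )


@dataclass(frozen=True)
class TraceEvent:
    cycle: int
    thread: str
    kind: str  # input | exec_ok | exec_retry | weight_change | emit | stream_start | stream_end
    payload: str
    data: dict = field(default_factory=dict)

    def to_json(self) -> str:
        d = {
            "cycle": self.cycle,
            "thread": self.thread,
            "kind": self.kind,
            "payload": self.payload,
        }
        if self.data:
            d["data"] = self.data
        return json.dumps(d, sort_keys=True)


# ---------------------------------------------------------------------------
# active threads


class ActiveThread:
    __slots__ = ("name", "key", "fiber", "clock", "registers", "chosen", "subst", "imps")

    def __init__(self, name: Term, fiber: str, imps: list[CodeImplication]):
        self.name = name
        self.key = format_term(name)
        self.fiber = fiber
        self.clock = 1
        self.registers: dict[str, Optional[Term]] = {k: None for k in STIMULUS_KINDS}
        self.chosen: dict[int, int] = {}  # alternative id -> branch index taken
        self.subst: dict = {}
        self.imps = imps

    def compatible(self, imp: CodeImplication) -> bool:
        return all(self.chosen.get(a, b) == b for a, b in imp.branch)


def _basic_templates() -> list[ThreadSpec]:
    """Built-in protocol threads loaded with every model.

    ltp/ltd are fired with the (source, recipient) pair whose weight they
    modulate; their join consumes a token from whichever thread merged for
    them, so the increment happens only on within-stream coincidence.
    """
    P, Q, R, S = Var("P"), Var("Q"), Var("R"), Var("S")

    def seq(*terms):
        return Seq(tuple(Instr(t) for t in terms))

    return [
        ThreadSpec(compound("ltp", P, Q), seq(compound("join", S), compound("potentiate", P, Q))),
        ThreadSpec(compound("ltd", P, Q), seq(compound("join", S), compound("depress", P, Q))),
        ThreadSpec(compound("ltr", P, Q, R), seq(compound("ltr", P, Q, R))),
        ThreadSpec(compound("lts", P), seq(compound("lts", P))),
    ]


# ---------------------------------------------------------------------------
# machine state


class MachineState:
    def __init__(self, model: ModelSpec, config: Optional[RunConfig] = None):
        self.model = model
        self.config = config or RunConfig()
        # compiled memory: per fiber, (name pattern, implications)
        self.templates: dict[str, list[tuple[Term, list[CodeImplication]]]] = {}
        for fiber in model.fibers:
            self.templates[fiber.name] = [
                (th.name, compile_thread(th)) for th in fiber.threads
            ]
        self.basics = [(t.name, compile_thread(t)) for t in _basic_templates()]
        self.weights = WeightTable(self.config.w_min, self.config.w_max)
        for w in model.weights:
            self.weights.declare(w.source, w.recipient, w.weight)
        self.accept: dict[str, Context] = {
            f.name: Context() for f in model.fibers
        }
        for fiber, t in model.accept:
            self.accept[fiber].set(t)
        self.ltm = LtmStore()
        self.caches: dict[str, tuple[Term, Term]] = {}
        self.signals: dict[str, list] = {f.name: [] for f in model.fibers}
        self.tokens: dict[str, list] = {f.name: [] for f in model.fibers}
        self.stim_buffer: dict[str, list] = {f.name: [] for f in model.fibers}
        self.active: list[ActiveThread] = []
        self._index: dict[tuple[str, str], ActiveThread] = {}
        self._act_seq = 0
        self.cycle = 0
        self.trace: list[TraceEvent] = []
        self.log_lines: list[str] = []

    # -- bookkeeping ---------------------------------------------------

    def stream_threads(self, fiber: str) -> list[ActiveThread]:
        return [t for t in self.active if t.fiber == fiber]

    def record(self, kind: str, thread: str, payload: str, **data) -> None:
        self.trace.append(TraceEvent(self.cycle, thread, kind, payload, data))

    def record_emit(self, thread: ActiveThread, term: Term) -> None:
        text = format_term(term)
        self.record("emit", thread.key, text)
        self.log_lines.append(f">>> {text}")

    def record_weight_change(self, thread, pair, old: int, new: int) -> None:
        p, q = (format_term(pair[0]), format_term(pair[1]))
        self.record(
            "weight_change", thread.key, f"{p} -> {q}",
            p=p, q=q, old=old, new=new,
        )

    # -- activation ----------------------------------------------------

    def _find_template(self, fiber: str, name: Term):
        for pattern, imps in self.templates[fiber]:
            b = unify(name, pattern)
            if b is not None:
                return pattern, imps, b, False
        for pattern, imps in self.basics:
            b = unify(name, pattern)
            if b is not None:
                return pattern, imps, b, True
        return None

    def activate(self, fiber: str, name: Term) -> ActiveThread:
        """(Re)activate a thread instance at clock 1 in the fiber's stream.

        Firing an already-active thread restarts it.  The body template is
        instantiated with the bindings of the name match, variables
        freshened apart; buffered internal stimuli of the current stream
        lifetime are delivered to the matching registers.  A user thread
        must be fired with a ground name; a basic thread may carry unbound
        arguments (an ltr's category is resolved at retrieval time).
        """
        found = self._find_template(fiber, name)
        if found is None:
            raise RunError(
                f"fire of undeclared thread {format_term(name)} in fiber {fiber}"
            )
        pattern, imps, binding, is_basic = found
        if not is_basic and not is_ground(name):
            raise RunError(
                f"fire of user thread {format_term(name)} with unbound "
                f"arguments in fiber {fiber}"
            )
        key = (fiber, format_term(name))
        self._act_seq += 1
        mapping: dict = {}
        tag = str(self._act_seq)
        inst = [
            CodeImplication(
                imp.guard
                if imp.guard.is_always
                else Guard(
                    imp.guard.kind,
                    rename_vars(
                        substitute(imp.guard.pattern, binding), mapping, tag
                    ),
                ),
                imp.clock,
                rename_vars(substitute(imp.instruction, binding), mapping, tag),
                imp.branch,
            )
            for imp in imps
        ]
        existing = self._index.get(key)
        if existing is not None:
            existing.clock = 1
            existing.chosen = {}
            existing.subst = {}
            existing.imps = inst
            thread = existing
        else:
            if not self.stream_threads(fiber):
                self.record("stream_start", "-", fiber)
            thread = ActiveThread(name, fiber, inst)
            self.active.append(thread)
            self._index[key] = thread
        for stim in self.stim_buffer[fiber]:
            self._deliver_register(thread, stim)
        return thread

    def deactivate(self, thread: ActiveThread) -> None:
        self.active.remove(thread)
        del self._index[(thread.fiber, thread.key)]
        if not self.stream_threads(thread.fiber):
            self.record("stream_end", "-", thread.fiber)

    def _deliver_register(self, thread: ActiveThread, stim: Term) -> bool:
        kind, payload = stim.functor, stim.args[0]
        for imp in thread.imps:
            if imp.guard.kind == kind and unify(imp.guard.pattern, payload) is not None:
                thread.registers[kind] = payload
                return True
        return False

    # -- sense ---------------------------------------------------------

    def sense(self, cycle: Cycle) -> None:
        if cycle.fiber not in self.signals:
            raise RunError(f"interrupt targets unknown fiber {cycle.fiber!r}")
        self.cycle += 1
        # terminate the interrupted stream: registers, queues, tokens and
        # buffered stimuli vanish; weights, caches and ltm persist.
        stream = self.stream_threads(cycle.fiber)
        for t in list(stream):
            self.active.remove(t)
            del self._index[(t.fiber, t.key)]
        if stream:
            self.record("stream_end", "-", cycle.fiber)
        self.signals[cycle.fiber].clear()
        self.tokens[cycle.fiber].clear()
        self.stim_buffer[cycle.fiber].clear()

        for s in cycle.sensors:
            self.record("input", "-", format_term(s), channel="sensor")
            self.log_lines.append(f"|: {format_term(s)}")
        for s in cycle.stimuli:
            self.record("input", "-", format_term(s), channel="stimulus")
            self.log_lines.append(f"|: {format_term(s)}")

        for s in cycle.sensors:
            self._route_sensor(cycle.fiber, s)
        for stim in cycle.stimuli:
            self._admit_stimulus(cycle.fiber, stim)

    def _route_sensor(self, fiber: str, sensor: Term) -> None:
        for route in self.model.sensors:
            if route.fiber != fiber:
                continue
            b = unify(route.pattern, sensor)
            if b is None:
                continue
            target = substitute(route.thread, b)
            if not is_ground(target):
                raise RunError(
                    f"sensor {format_term(sensor)} leaves target "
                    f"{format_term(target)} unbound"
                )
            self.activate(fiber, target)
            return
        raise RunError(f"unknown sensor term {format_term(sensor)}")

    def _admit_stimulus(self, fiber: str, stim: Term) -> None:
        if stim.functor not in STIMULUS_KINDS or len(stim.args) != 1:
            raise RunError(
                f"internal stimulus must be kind(term) with kind in "
                f"{STIMULUS_KINDS}: {format_term(stim)}"
            )
        self.stim_buffer[fiber].append(stim)
        kind, payload = stim.functor, stim.args[0]
        for t in self.stream_threads(fiber):
            self._deliver_register(t, stim)
        # lazy template instantiation: a parameterized thread is activated
        # the first time a stimulus matching one of its guards arrives.
        for pattern, imps in self.templates[fiber]:
            for imp in imps:
                if imp.guard.kind != kind:
                    continue
                mapping: dict = {}
                fresh_guard = rename_vars(imp.guard.pattern, mapping)
                fresh_name = rename_vars(pattern, mapping)
                b = unify(fresh_guard, payload)
                if b is None:
                    continue
                name = substitute(fresh_name, b)
                if not is_ground(name):
                    continue
                if (fiber, format_term(name)) not in self._index:
                    self.activate(fiber, name)
                break

    # -- contextual deduction ------------------------------------------

    def guard_holds(self, thread: ActiveThread, guard: Guard) -> Optional[dict]:
        """Binding under which the guard is true for this thread, else None."""
        if guard.is_always:
            return {}
        reg = thread.registers[guard.kind]
        if reg is None:
            return None
        return unify(substitute(guard.pattern, thread.subst), reg)

    def deduce(self, thread: ActiveThread):
        """Next instruction of an active thread, by its clock and guards.

        Returns ('exec', implication, binding), ('stall', None, None) when
        no guard at the current clock holds, or ('done', None, None) when
        the clock has run past every branch-compatible implication.
        """
        future = [i for i in thread.imps if thread.compatible(i) and i.clock >= thread.clock]
        if not future:
            return "done", None, None
        here = [i for i in future if i.clock == thread.clock]
        if not here:
            # a shorter branch rejoins the sequence after an alternative
            thread.clock = min(i.clock for i in future)
            here = [i for i in future if i.clock == thread.clock]
        guarded = []
        default = None
        for imp in here:
            b = self.guard_holds(thread, imp.guard)
            if b is None:
                continue
            if imp.guard.is_always:
                default = (imp, b)
            else:
                guarded.append((imp, b))
        if len(guarded) > 1:
            raise AmbiguousGuardError(
                f"{thread.key} at clock {thread.clock}: guards "
                + " and ".join(str(i.guard) for i, _ in guarded)
                + " both satisfiable"
            )
        if guarded:
            return "exec", *guarded[0]
        if default:
            return "exec", *default
        return "stall", None, None

    # -- react ---------------------------------------------------------

    def react(self, order: Optional[Callable[[list], list]] = None) -> None:
        """Sweep active threads until quiescence.

        Default schedule is activation order (FIFO); `order` may permute
        each sweep's snapshot (the final weight map must not depend on it
        — a tested property, not an assumption).  Threads activated during
        a sweep are first visited on the next sweep.
        """
        for sweep in range(self.config.sweep_cap):
            snapshot = list(self.active)
            if order is not None:
                snapshot = order(snapshot)
            progressed = False
            for thread in snapshot:
                if thread not in self.active:
                    continue  # deactivated or restarted bookkeeping
                status, imp, binding = self.deduce(thread)
                if status == "done":
                    self.deactivate(thread)
                    continue
                if status == "stall":
                    self.record(
                        "exec_retry", thread.key, "no satisfiable guard",
                        clock=thread.clock,
                    )
                    continue
                instr = substitute(imp.instruction, {**thread.subst, **binding})
                ok, new_bindings, detail = execute(self, thread, instr)
                if ok:
                    thread.subst.update(binding)
                    thread.subst.update(new_bindings)
                    for alt_id, idx in imp.branch:
                        thread.chosen[alt_id] = idx
                    thread.clock += 1
                    self.record(
                        "exec_ok", thread.key, format_term(instr),
                        clock=imp.clock, **detail,
                    )
                    progressed = True
                else:
                    self.record(
                        "exec_retry", thread.key, format_term(instr),
                        clock=imp.clock,
                    )
            if not progressed:
                return
        stalled = ", ".join(t.key for t in self.active)
        raise LivelockError(
            f"react did not quiesce within {self.config.sweep_cap} sweeps; "
            f"active: {stalled}"
        )

    # -- trace output --------------------------------------------------

    def trace_jsonl(self) -> str:
        return "\n".join(e.to_json() for e in self.trace) + ("\n" if self.trace else "")

    def weight_changes(self):
        return [e for e in self.trace if e.kind == "weight_change"]


# ---------------------------------------------------------------------------
# load and run


def load(model: ModelSpec, config: Optional[RunConfig] = None) -> MachineState:
    """Compile every thread of a model (plus the basic protocol threads)
    and load implications, weights and accept elements into a fresh
    machine with no active thread."""
    return MachineState(model, config)


def run(
    script: Iterable[Cycle],
    state: MachineState,
    order: Optional[Callable[[list], list]] = None,
) -> MachineState:
    """Interpret an interrupt script: sense then react, per cycle."""
    for cycle in script:
        state.sense(cycle)
        state.react(order)
    return state
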