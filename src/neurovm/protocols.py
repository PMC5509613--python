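"""The instruction set: microcircuit communication protocols.

Four protocol pairs abstract the synaptic machinery:

* ``send``/``receive`` — synaptic transmission.  Asynchronous and
  threshold-gated: the receiver proceeds only if a signal from the named
  sender is pending *and* the weight of the (sender, receiver) pair stands
  at or above the threshold θ.  No data is passed.
* ``join``/``merge`` — synapse modulation.  A merge posts a modulatory
  token for a recipient; a join consumes it.  Not weight-gated.  Because
  tokens die with their stream, a join only ever succeeds if the merge
  happened within the same stream lifetime — this makes the ltp thread a
  coincidence detector.
* ``push``/``pull``/``reset`` — a single-slot short-term cache per
  location.  push overwrites, pull reads non-destructively by
  unification, reset erases.  Caches persist across stream terminations.
* ``lts``/``ltr``/``broadcast`` — associative long-term memory.  lts lays
  down a trace {P}; broadcast posts a global path receivable from any
  stream; an ltr(P, Q, R) thread, fired by Q, waits for a path to ltm(P)
  over a stored trace and then fires the recall thread R.

``fire`` activates a thread in the caller's stream and ``emit`` drives an
effector (a ``>>>`` log line).  The internal opcodes ``potentiate`` and
``depress`` — the bodies of the built-in ltp/ltd threads — are the only
operations that may change a weight, by ±δ, clamped to [w_min, w_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .terms import Term, Var, compound, format_term, is_ground, substitute, unify

__all__ = ["WeightTable", "LtmStore", "execute", "ExecError"]


class ExecError(RuntimeError):
    pass


class WeightTable:
    """Integer synaptic weights on (source, recipient) thread pairs.

    Entries may be declared over parameterized thread-name patterns (e.g.
    ``match(a, I) -> peck(a)``); lookups and plasticity resolve a ground
    pair against the declared entries by unification, so a potentiation
    learned through one instantiation generalizes to every instance the
    pattern covers.  Ground entries keep learning pair-specific.
    """

    def __init__(self, w_min: int = 0, w_max: int = 5):
        self.w_min = w_min
        self.w_max = w_max
        self._entries: list[list] = []  # [source, recipient, weight]

    def declare(self, source: Term, recipient: Term, weight: int) -> None:
        for p, q, _ in self._entries:
            if p == source and q == recipient:
                raise ExecError(
                    f"duplicate weight declaration for "
                    f"{format_term(source)} -> {format_term(recipient)}"
                )
        self._entries.append([source, recipient, int(weight)])

    def _find(self, source: Term, recipient: Term) -> Optional[list]:
        for entry in self._entries:
            s = unify(entry[0], source)
            if s is not None and unify(entry[1], recipient, s) is not None:
                return entry
        return None

    def lookup(self, source: Term, recipient: Term) -> Optional[int]:
        entry = self._find(source, recipient)
        return entry[2] if entry else None

    def apply(self, source: Term, recipient: Term, delta: int):
        """Shift a weight by delta (clamped); returns (key_pair, old, new).

        A pair never declared gets an implicit entry at w_min first — an
        unconditioned synapse starts silent.
        """
        entry = self._find(source, recipient)
        if entry is None:
            entry = [source, recipient, self.w_min]
            self._entries.append(entry)
        old = entry[2]
        entry[2] = min(max(old + delta, self.w_min), self.w_max)
        return (entry[0], entry[1]), old, entry[2]

    def snapshot(self) -> dict:
        return {
            (format_term(p), format_term(q)): w for p, q, w in self._entries
        }

    def items(self):
        return [(p, q, w) for p, q, w in self._entries]


class LtmStore:
    """Long-term associative memory: stored traces plus broadcast paths.

    Both persist across stream terminations; the trace set only grows
    within a run.
    """

    def __init__(self):
        self.traces: list[tuple[Term, int]] = []  # (term, store cycle)
        self.paths: list[Term] = []

    def store(self, trace: Term, cycle: int) -> None:
        if any(t == trace for t, _ in self.traces):
            return
        self.traces.append((trace, cycle))

    def broadcast(self, path: Term) -> None:
        if path not in self.paths:
            self.paths.append(path)

    def retrieve(self, pattern, subst: dict) -> Optional[dict]:
        """Unify pattern against a path ltm(P) whose P has a stored trace."""
        for path in self.paths:
            b = unify(path, compound("ltm", pattern), dict(subst))
            if b is None:
                continue
            want = substitute(pattern, b)
            for trace, _ in self.traces:
                b2 = unify(want, trace, dict(b))
                if b2 is not None:
                    return b2
        return None


# ---------------------------------------------------------------------------
# instruction dispatch

_ALWAYS_OK = (
    "fire",
    "send",
    "merge",
    "push",
    "reset",
    "broadcast",
    "lts",
    "emit",
    "potentiate",
    "depress",
)


def execute(state, thread, instr: Term):
    """Run one instruction for `thread`; returns (ok, bindings, detail).

    ok=False is the documented retry path (receive/join/pull/ltr whose
    precondition is not yet met); the thread's clock is left untouched and
    the instruction is attempted again on the next sweep.
    """
    op = instr.functor
    args = instr.args
    if op == "fire":
        state.activate(thread.fiber, args[0])
        return True, {}, {}
    if op == "send":
        state.signals[thread.fiber].append((thread.name, args[0]))
        return True, {}, {}
    if op == "receive":
        pool = state.signals[thread.fiber]
        for i, (sender, addressee) in enumerate(pool):
            if unify(addressee, thread.name) is None:
                continue
            b = unify(args[0], sender)
            if b is None:
                continue
            w = state.weights.lookup(sender, thread.name)
            if w is None or w < state.config.theta:
                continue
            pool.pop(i)
            return True, b, {"sender": format_term(sender), "weight": w}
        return False, None, {}
    if op == "join":
        pool = state.tokens[thread.fiber]
        for i, (sender, addressee) in enumerate(pool):
            if unify(addressee, thread.name) is None:
                continue
            b = unify(args[0], sender)
            if b is None:
                continue
            pool.pop(i)
            return True, b, {"sender": format_term(sender)}
        return False, None, {}
    if op == "merge":
        state.tokens[thread.fiber].append((thread.name, args[0]))
        return True, {}, {}
    if op == "push":
        loc, val = args
        state.caches[format_term(loc)] = (loc, val)
        return True, {}, {}
    if op == "pull":
        for loc, val in state.caches.values():
            b = unify(args[0], val)
            if b is not None:
                return True, b, {"location": format_term(loc)}
        return False, None, {}
    if op == "reset":
        keys = [
            k
            for k, (loc, _) in state.caches.items()
            if unify(args[0], loc) is not None
        ]
        for k in keys:
            del state.caches[k]
        return True, {}, {}
    if op == "broadcast":
        state.ltm.broadcast(args[0])
        return True, {}, {}
    if op == "lts":
        state.ltm.store(args[0], state.cycle)
        return True, {}, {}
    if op == "ltr":
        p, q, r = args
        b = state.ltm.retrieve(p, {})
        if b is None:
            return False, None, {}
        target = substitute(r, b)
        if not is_ground(target):
            return False, None, {}
        state.activate(thread.fiber, target)
        return True, b, {"recalled": format_term(substitute(p, b))}
    if op == "emit":
        state.record_emit(thread, args[0])
        return True, {}, {}
    if op in ("potentiate", "depress"):
        delta = state.config.delta if op == "potentiate" else -state.config.delta
        pair, old, new = state.weights.apply(args[0], args[1], delta)
        state.record_weight_change(thread, pair, old, new)
        return True, {}, {}
    raise ExecError(f"{thread.key}: unknown opcode {op!r}")
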