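"""Machine state, contextual deduction, sense/react/run."""

import pytest

from neurovm.machine import (
    AmbiguousGuardError,
    Context,
    Cycle,
    LivelockError,
    RunConfig,
    RunError,
    ist,
    load,
    run,
)
from neurovm.terms import atom, compound, format_term, parse_term

from conftest import emits_by_cycle, make_model


def _cycle(fiber="main", sensors=(), stimuli=()):
    return Cycle(
        fiber,
        tuple(parse_term(s) for s in sensors),
        tuple(parse_term(s) for s in stimuli),
    )


# ---------------------------------------------------------------------------
# context and ist


def test_context_set_get_delete_under_unification():
    c = Context([parse_term("weight(p, q, 2)")])
    assert ist(c, parse_term("weight(p, Q, W)"))
    assert not ist(c, parse_term("weight(z, Q, W)"))
    # exhaustive enumeration yields exactly one binding
    assert len(c.get_all(parse_term("weight(p, Q, W)"))) == 1
    assert c.delete(parse_term("weight(p, Q, W)"))
    assert not ist(c, parse_term("weight(p, Q, W)"))


def test_context_rejects_duplicate_ground_terms():
    c = Context()
    c.set(parse_term("f(a)"))
    c.set(parse_term("f(a)"))
    assert len(c) == 1


def test_always_guard_holds_anywhere():
    from neurovm.dsl import ALWAYS

    state = load(make_model("thread t: [emit(x)]"))
    th = state.activate("main", atom("t"))
    assert state.guard_holds(th, ALWAYS) == {}


def test_stimulus_guard_reads_register_with_binding():
    state = load(make_model(
        "thread try: [{excite(accept(I)) -> [emit(ok(I))] ; "
        "inhibit(accept(I)) -> [emit(no(I))]}]"
    ))
    state.sense(_cycle(stimuli=["excite(accept([mat, smooth]))"]))
    state.react()
    assert emits_by_cycle(state.trace)[1] == ["ok([mat, smooth])"]


def test_deduce_selects_branch_by_register():
    # only the inhibit register set -> the inhibit branch's instruction
    state = load(make_model(
        "thread learn(accept(I)): [{excite(accept(I)) -> [emit(yes(I))] ; "
        "inhibit(accept(I)) -> [emit(no(I))]}]"
    ))
    state.sense(_cycle(stimuli=["inhibit(accept(v))"]))
    (th,) = state.active
    status, imp, binding = state.deduce(th)
    assert status == "exec" and imp.guard.kind == "inhibit"
    state.react()
    assert emits_by_cycle(state.trace)[1] == ["no(v)"]


def test_deduce_two_satisfiable_guards_is_ambiguous():
    state = load(make_model(
        "thread t: [{excite(p) -> [emit(a)] ; catch(p) -> [emit(b)]}]"
    ))
    th = state.activate("main", atom("t"))
    th.registers["excite"] = atom("p")
    th.registers["catch"] = atom("p")
    with pytest.raises(AmbiguousGuardError):
        state.deduce(th)


def test_completed_thread_leaves_active_set():
    state = load(make_model("thread t: [emit(a)]"))
    state.activate("main", atom("t"))
    state.react()
    assert state.active == []


# ---------------------------------------------------------------------------
# sense


def test_sense_activates_sensory_threads_at_clock_one(circuits):
    state = load(circuits["classical"])
    state.sense(Cycle("net", (atom("us"), atom("cs"))))
    keys = [t.key for t in state.active]
    assert keys == ["sense(us)", "sense(cs)"]
    assert all(t.clock == 1 for t in state.active)


def test_empty_interrupt_terminates_stream_without_activating(circuits):
    state = load(circuits["classical"])
    state.sense(Cycle("net", (atom("cs"),)))
    assert state.active
    state.sense(Cycle("net"))
    assert state.active == []
    ends = [e for e in state.trace if e.kind == "stream_end"]
    assert len(ends) == 1


def test_unknown_sensor_is_a_run_error(circuits):
    state = load(circuits["classical"])
    with pytest.raises(RunError, match="nonsense"):
        state.sense(Cycle("net", (atom("nonsense"),)))


def test_interrupt_on_one_fiber_preserves_other_fibers_caches():
    model = make_model(
        "thread w: [push(loc, datum)]",
        extra=(
            "fiber other { thread r: [pull(datum), emit(got)] }\n"
            "sensors { go -> main: w \n probe -> other: r }"
        ),
    )
    state = load(model)
    state.sense(_cycle("main", sensors=["go"]))
    state.react()
    # interrupt main again: its stream dies, the cache survives
    state.sense(_cycle("main"))
    state.sense(_cycle("other", sensors=["probe"]))
    state.react()
    assert "got" in emits_by_cycle(state.trace).get(3, [])


def test_sense_clears_pending_signals_and_tokens():
    model = make_model(
        "thread a: [send(b), merge(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 1 }\nsensors { go -> main: a }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert state.signals["main"] or True  # b never activated; signal pending
    state.sense(_cycle())
    assert state.signals["main"] == [] and state.tokens["main"] == []


# ---------------------------------------------------------------------------
# react


def test_linear_thread_clock_advances_one_per_success():
    state = load(make_model("thread t: [emit(a), emit(b), emit(c)]"))
    state.activate("main", atom("t"))
    state.react()
    clocks = [e.data["clock"] for e in state.trace if e.kind == "exec_ok"]
    assert clocks == [1, 2, 3]


def test_subthreshold_receive_retries_until_quiescence():
    model = make_model(
        "thread a: [fire(b), send(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 0 }\nsensors { go -> main: a }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()  # quiesces despite the stalled receive
    retries = [e for e in state.trace if e.kind == "exec_retry"
               and e.thread == "b"]
    assert retries and all(e.payload == "receive(a)" for e in retries)
    assert "ok" not in sum(emits_by_cycle(state.trace).values(), [])


def test_fire_without_send_stalls_then_cleared_by_next_interrupt():
    model = make_model(
        "thread a: [fire(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 1 }\nsensors { go -> main: a }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert [t.key for t in state.active] == ["b"]
    state.sense(_cycle())
    assert state.active == []


def test_independent_threads_confluent_under_visit_order():
    model = make_model(
        "thread a: [emit(x), emit(y)]\nthread b: [emit(z)]",
        extra="sensors { s1 -> main: a \n s2 -> main: b }",
    )

    def run_with(order):
        state = load(model)
        state.sense(_cycle(sensors=["s1", "s2"]))
        state.react(order)
        return state.weights.snapshot(), sorted(
            sum(emits_by_cycle(state.trace).values(), [])
        )

    assert run_with(None) == run_with(lambda snap: snap[::-1])


def test_livelock_hits_sweep_cap():
    model = make_model("thread a: [fire(b)]\nthread b: [fire(a)]")
    state = load(model, RunConfig(sweep_cap=50))
    state.activate("main", atom("a"))
    with pytest.raises(LivelockError, match="50 sweeps"):
        state.react()


# ---------------------------------------------------------------------------
# run


def test_empty_script_changes_nothing(circuits):
    state = load(circuits["classical"])
    before = state.weights.snapshot()
    run([], state)
    assert state.trace == [] and state.weights.snapshot() == before


def test_runs_are_deterministic(circuits):
    def one():
        state = load(circuits["classical"])
        run(
            [Cycle("net", (atom("cs"), atom("us"))) for _ in range(3)]
            + [Cycle("net", (atom("cs"),))],
            state,
        )
        return state.trace_jsonl()

    assert one() == one()


def test_cycle_json_roundtrip():
    cy = _cycle("net", sensors=["a(green)", "c(red)"], stimuli=["fetch(a)"])
    assert Cycle.from_json(cy.to_json()) == cy
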