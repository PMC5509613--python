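"""Instruction-set semantics: the four protocol pairs plus fire/emit."""

import pytest

from neurovm.machine import Cycle, RunConfig, load
from neurovm.terms import atom, parse_term

from conftest import emits_by_cycle, make_model


def _cycle(fiber="main", sensors=(), stimuli=()):
    return Cycle(
        fiber,
        tuple(parse_term(s) for s in sensors),
        tuple(parse_term(s) for s in stimuli),
    )


def _emits(state):
    return sum(emits_by_cycle(state.trace).values(), [])


# ---------------------------------------------------------------------------
# send / receive


def test_receive_succeeds_at_threshold_boundary():
    model = make_model(
        "thread a: [fire(b), send(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 2 }\nsensors { go -> main: a }",
    )
    state = load(model, RunConfig(theta=2))
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert _emits(state) == ["ok"]
    assert state.signals["main"] == []  # the signal was consumed


def test_receive_fails_one_below_threshold():
    model = make_model(
        "thread a: [fire(b), send(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 1 }\nsensors { go -> main: a }",
    )
    state = load(model, RunConfig(theta=2))
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert _emits(state) == []


def test_two_sends_one_receive_leaves_one_signal_queued():
    model = make_model(
        "thread a: [fire(b), send(b), send(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 1 }\nsensors { go -> main: a }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert _emits(state) == ["ok"]
    assert len(state.signals["main"]) == 1


# ---------------------------------------------------------------------------
# join / merge and ltp/ltd


PAIRING = (
    "thread s1: [fire(ltp(s1, m)), merge(ltp(s1, m)), fire(m), send(m)]\n"
    "thread m: [receive(s1), emit(go)]"
)


def test_ltp_fires_after_join_met_by_merge():
    model = make_model(
        PAIRING,
        extra="weights { main: s1 -> m = 0 }\nsensors { go -> main: s1 }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert state.weights.lookup(atom("s1"), atom("m")) == 1
    changes = state.weight_changes()
    assert len(changes) == 1 and changes[0].data == {
        "p": "s1", "q": "m", "old": 0, "new": 1,
    }


def test_ltp_without_merge_never_fires():
    model = make_model(
        "thread s1: [fire(ltp(s1, m)), fire(m), send(m)]\nthread m: [receive(s1)]",
        extra="weights { main: s1 -> m = 1 }\nsensors { go -> main: s1 }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert state.weight_changes() == []
    state.sense(_cycle())  # the stalled ltp is cleared by the interrupt
    assert state.active == []


def test_merge_without_ltp_leaves_token_cleared_at_interrupt():
    model = make_model(
        "thread s1: [merge(ltp(s1, m))]\nthread m: []",
        extra="weights { main: s1 -> m = 0 }\nsensors { go -> main: s1 }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert state.weight_changes() == []
    assert len(state.tokens["main"]) == 1
    state.sense(_cycle())
    assert state.tokens["main"] == []


def test_ltd_decrements_and_clamps_at_w_min():
    model = make_model(
        "thread s1: [fire(ltd(s1, m)), merge(ltd(s1, m))]\nthread m: []",
        extra="weights { main: s1 -> m = 0 }\nsensors { go -> main: s1 }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert state.weights.lookup(atom("s1"), atom("m")) == 0  # clamped


def test_repeated_pairings_accumulate_until_w_max():
    model = make_model(
        PAIRING,
        extra="weights { main: s1 -> m = 0 }\nsensors { go -> main: s1 }",
    )
    state = load(model, RunConfig(w_max=3))
    for _ in range(5):
        state.sense(_cycle(sensors=["go"]))
        state.react()
    traj = [e.data["new"] for e in state.weight_changes()]
    assert traj == [1, 2, 3, 3, 3]


# ---------------------------------------------------------------------------
# push / pull / reset (short-term cache)


def test_push_then_pull_unifies_cached_term():
    model = make_model(
        "thread w: [push(last, corner(left))]\n"
        "thread r: [pull(corner(X)), emit(seen(X))]",
        extra="sensors { s1 -> main: w \n s2 -> main: r }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["s1"]))
    state.react()
    state.sense(_cycle(sensors=["s2"]))  # cache survives the interrupt
    state.react()
    assert _emits(state) == ["seen(left)"]


def test_push_overwrites_single_slot():
    model = make_model(
        "thread w: [push(last, corner(left)), push(last, corner(right))]\n"
        "thread r: [pull(corner(X)), emit(seen(X))]",
        extra="sensors { s1 -> main: w \n s2 -> main: r }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["s1"]))
    state.react()
    state.sense(_cycle(sensors=["s2"]))
    state.react()
    assert _emits(state) == ["seen(right)"]


def test_pull_is_nonconsuming_and_reset_erases():
    model = make_model(
        "thread w: [push(last, v)]\n"
        "thread r: [pull(v), emit(first), pull(v), emit(second)]\n"
        "thread z: [reset(last)]\n"
        "thread r2: [pull(v), emit(third)]",
        extra="sensors { s1 -> main: w \n s2 -> main: r \n"
              " s3 -> main: z \n s4 -> main: r2 }",
    )
    state = load(model)
    for s in ("s1", "s2", "s3", "s4"):
        state.sense(_cycle(sensors=[s]))
        state.react()
    assert _emits(state) == ["first", "second"]  # third never fires


# ---------------------------------------------------------------------------
# lts / ltr / broadcast (long-term associative memory)


LTM_MODEL = (
    "thread store(X): [lts(food(X)), broadcast(ltm(food(X)))]\n"
    "thread ask(X): [fire(ltr(food(X), ask(X), hit(X)))]\n"
    "thread hit(X): [emit(recalled(X))]"
)


def test_stored_trace_retrieved_across_streams():
    model = make_model(
        LTM_MODEL,
        extra="sensors { put(X) -> main: store(X) \n get(X) -> main: ask(X) }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["put(cake)"]))
    state.react()
    state.sense(_cycle(sensors=["get(cake)"]))
    state.react()
    assert _emits(state) == ["recalled(cake)"]


def test_retrieval_before_storage_stalls_forever():
    model = make_model(
        LTM_MODEL,
        extra="sensors { put(X) -> main: store(X) \n get(X) -> main: ask(X) }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["get(cake)"]))
    state.react()
    assert _emits(state) == []
    state.sense(_cycle())
    assert state.active == []


def test_retrieval_unifies_only_matching_category():
    src = (
        "thread store(C, X): [lts(cat(C, X)), broadcast(ltm(cat(C, X)))]\n"
        "thread ask(X): [fire(ltr(cat(C, X), ask(X), hit(C, X)))]\n"
        "thread hit(C, X): [emit(sorted(C, X))]"
    )
    model = make_model(
        src,
        extra="sensors { put(C, X) -> main: store(C, X) \n"
              " get(X) -> main: ask(X) }",
    )
    state = load(model)
    for c, x in (("food", "cake"), ("food", "orange"),
                 ("toy", "key"), ("toy", "stick")):
        state.sense(_cycle(sensors=[f"put({c}, {x})"]))
        state.react()
    state.sense(_cycle(sensors=["get(orange)"]))
    state.react()
    state.sense(_cycle(sensors=["get(stick)"]))
    state.react()
    assert _emits(state) == ["sorted(food, orange)", "sorted(toy, stick)"]


def test_ltm_store_only_grows():
    model = make_model(
        LTM_MODEL,
        extra="sensors { put(X) -> main: store(X) \n get(X) -> main: ask(X) }",
    )
    state = load(model)
    sizes = []
    for x in ("cake", "orange", "cake"):
        state.sense(_cycle(sensors=[f"put({x})"]))
        state.react()
        sizes.append(len(state.ltm.traces))
    assert sizes == [1, 2, 2]  # monotone, no duplicate traces


# ---------------------------------------------------------------------------
# fire / emit


def test_fire_restarts_an_active_thread_at_clock_one():
    model = make_model(
        "thread a: [fire(b), fire(b)]\nthread b: [receive(a), emit(ok)]",
        extra="weights { main: a -> b = 1 }\nsensors { go -> main: a }",
    )
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    # b was restarted but no signal ever sent: it stalls at receive
    assert [t.key for t in state.active] == ["b"]
    assert state._index[("main", "b")].clock == 1


def test_emit_appears_once_in_trace_and_log():
    model = make_model("thread a: [emit(peck(a))]",
                       extra="sensors { go -> main: a }")
    state = load(model)
    state.sense(_cycle(sensors=["go"]))
    state.react()
    assert _emits(state) == ["peck(a)"]
    assert state.log_lines.count(">>> peck(a)") == 1
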