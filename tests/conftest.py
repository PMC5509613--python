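import pytest

from neurovm import build_experiment, load_circuit, parse_model
from neurovm.machine import load


@pytest.fixture(scope="session")
def circuits():
    """All shipped circuit fixtures, parsed."""
    names = (
        "classical",
        "operant_simple",
        "matching_to_sample",
        "win_stay_lose_shift",
        "categorize_sort",
    )
    return {n: load_circuit(n) for n in names}


@pytest.fixture()
def classical_state():
    return load(load_circuit("classical"))


def make_model(body: str, extra: str = ""):
    """A one-fiber toy model from a thread-block snippet."""
    return parse_model(f"model toy\n\nfiber main {{\n{body}\n}}\n{extra}\n")


def emits_by_cycle(trace):
    out = {}
    for e in trace:
        if e.kind == "emit":
            out.setdefault(e.cycle, []).append(e.payload)
    return out


def receives_ok(trace):
    return [
        e for e in trace
        if e.kind == "exec_ok" and e.payload.startswith("receive(")
    ]


def sends_ok(trace):
    return [
        e for e in trace
        if e.kind == "exec_ok" and e.payload.startswith("send(")
    ]
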