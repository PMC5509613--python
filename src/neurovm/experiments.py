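"""The five behavioral experiments, as runnable fixtures.

Each experiment bundles a circuit model, a seeded trial-script generator
and a success metric.  Scripts are closed-loop where the task demands it:
the generator reads the trace of trial t (which action was emitted),
judges it against the environment (the model's accept set, the matching
rule, the food corner, the object's category) and delivers the
excite/inhibit feedback stimulus in the interrupt that opens trial t+1.
Random choices (the pigeon's random pecking, the item or color drawn per
trial) come from a numpy Generator seeded per run, so a generated script
replays byte-identically and the machine itself stays deterministic.

Default parameters are the task conditions described for each circuit:
operant items grain=[mat, smooth] vs pebble=[shiny, smooth] with grain in
the accept set; matching-to-sample colors green/red with exactly one
green and one red button; hummingbird corners left/right; sorting
categories {cake, orange} edible vs {key, stick} inedible, trained on
{cake, key} only.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .dsl import ModelSpec, WeightDecl, parse_model
from .machine import Cycle, MachineState, RunConfig, TraceEvent, load
from .terms import Term, atom, compound, format_term, make_list, parse_term

__all__ = [
    "EXPERIMENTS",
    "Experiment",
    "ExperimentResult",
    "Metrics",
    "build_experiment",
    "generate_script",
    "run_experiment",
    "evaluate",
    "load_circuit",
]

EXPERIMENTS = (
    "classical",
    "operant_simple",
    "matching_to_sample",
    "win_stay_lose_shift",
    "categorize_sort",
)

_CIRCUIT_FILES = {
    "classical": "classical.nvm",
    "operant_simple": "operant.nvm",
    "matching_to_sample": "matching.nvm",
    "win_stay_lose_shift": "winstay.nvm",
    "categorize_sort": "sorting.nvm",
}

GRAIN = make_list([atom("mat"), atom("smooth")])
PEBBLE = make_list([atom("shiny"), atom("smooth")])


def load_circuit(name: str) -> ModelSpec:
    """Parse a shipped `.nvm` fixture by experiment name."""
    fname = _CIRCUIT_FILES[name]
    text = (
        importlib.resources.files("neurovm") / "circuits" / fname
    ).read_text(encoding="utf-8")
    return parse_model(text)


def _rescale_weights(model: ModelSpec, theta: int) -> ModelSpec:
    """Fixture weights are written for theta=1 (open=1, closed=0); map
    them to open=theta, closed=theta-1 for a custom threshold."""
    if theta == 1:
        return model
    weights = tuple(
        replace(w, weight=theta if w.weight >= 1 else theta - 1)
        for w in model.weights
    )
    return replace(model, weights=weights)


@dataclass
class Experiment:
    name: str
    model: ModelSpec
    config: RunConfig
    n_trials: int
    cycles_per_trial: int
    params: dict = field(default_factory=dict)


def build_experiment(name: str, theta: int = 1, **params) -> Experiment:
    """Fixture model + generator parameters for a named experiment.

    classical accepts ``mode`` in {'paired', 'us_only', 'cs_only'},
    ``probe_before`` and ``probe_after`` (booleans);
    win_stay_lose_shift accepts ``rule`` in {'win_stay', 'win_shift'} and
    ``swap_after`` (trial index at which the rule flips, or None);
    categorize_sort accepts ``train_items``/``test_items``.
    """
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; know {EXPERIMENTS}")
    model = _rescale_weights(load_circuit(name), theta)
    config = RunConfig(theta=theta, **{
        k: params.pop(k) for k in ("delta", "w_min", "w_max", "sweep_cap")
        if k in params
    })
    defaults = {
        "classical": dict(n_trials=5, cycles=1, mode="paired",
                          probe_before=False, probe_after=True),
        "operant_simple": dict(n_trials=12, cycles=1),
        "matching_to_sample": dict(n_trials=100, cycles=1),
        "win_stay_lose_shift": dict(n_trials=60, cycles=2,
                                    rule="win_stay", swap_after=None),
        "categorize_sort": dict(n_trials=30, cycles=1,
                                train_items=("cake", "key"),
                                test_items=("orange", "stick")),
    }[name]
    n_trials = params.pop("n_trials", defaults.pop("n_trials"))
    cycles = defaults.pop("cycles")
    merged = {**defaults, **params}
    return Experiment(name, model, config, n_trials, cycles, merged)


# ---------------------------------------------------------------------------
# result container and metrics


@dataclass
class ExperimentResult:
    experiment: Experiment
    script: list  # of Cycle, with feedback stimuli as delivered
    state: MachineState
    trials: pd.DataFrame  # one row per trial: trial, correct, emits, ...

    @property
    def trace(self) -> list[TraceEvent]:
        return self.state.trace

    @property
    def metrics(self) -> "Metrics":
        return evaluate(self.experiment, self.state.trace)


@dataclass
class Metrics:
    """Success measures computed solely from the trace event log."""

    trials: pd.DataFrame
    weight_changes: pd.DataFrame  # cycle, p, q, old, new
    trials_to_criterion: Optional[int]
    reward_rate: float

    def trailing_reward_rate(self, k: int) -> float:
        tail = self.trials.tail(k)
        return float(tail["correct"].mean()) if len(tail) else float("nan")

    def weight_trajectory(self, p: str, q: str) -> list[int]:
        """Weight values over time for a pair, starting at its initial value."""
        rows = self.weight_changes
        rows = rows[(rows["p"] == p) & (rows["q"] == q)]
        if rows.empty:
            return []
        return [int(rows.iloc[0]["old"])] + [int(v) for v in rows["new"]]


def _weight_change_frame(trace) -> pd.DataFrame:
    rows = [
        {
            "cycle": e.cycle,
            "p": e.data["p"],
            "q": e.data["q"],
            "old": e.data["old"],
            "new": e.data["new"],
        }
        for e in trace
        if e.kind == "weight_change"
    ]
    return pd.DataFrame(rows, columns=["cycle", "p", "q", "old", "new"])


def _trials_to_criterion(correct: list) -> Optional[int]:
    """1-based index of the first trial after which every trial (itself
    included) is correct; None if the run never settles."""
    vals = [bool(c) for c in correct if c is not None]
    if not vals or not vals[-1]:
        return None
    idx = len(vals)
    while idx > 1 and vals[idx - 2]:
        idx -= 1
    return idx


# ---------------------------------------------------------------------------
# per-trial environments (closed loop)


def _emits_in(trace, first_cycle: int, last_cycle: int) -> list[str]:
    return [
        e.payload
        for e in trace
        if e.kind == "emit" and first_cycle <= e.cycle <= last_cycle
    ]


def _grouped_cycles(trace) -> dict[int, dict]:
    """Reconstruct each cycle's inputs and emissions from the trace."""
    cycles: dict[int, dict] = {}
    for e in trace:
        c = cycles.setdefault(
            e.cycle, {"sensors": [], "stimuli": [], "emits": []}
        )
        if e.kind == "input":
            key = "sensors" if e.data["channel"] == "sensor" else "stimuli"
            c[key].append(e.payload)
        elif e.kind == "emit":
            c["emits"].append(e.payload)
    return cycles


class _Env:
    """One trial of interaction: draw a configuration, judge the emissions,
    produce the feedback stimuli for the next interrupt."""

    def draw(self, t: int, rng: np.random.Generator, exp: Experiment) -> dict:
        raise NotImplementedError

    def cycles(self, info: dict, exp: Experiment) -> list[Cycle]:
        raise NotImplementedError

    def judge(self, info: dict, emits: list[str], exp: Experiment) -> dict:
        raise NotImplementedError

    def feedback(self, info: dict, verdict: dict, exp: Experiment) -> list[Term]:
        return []


class _OperantEnv(_Env):
    items = (GRAIN, PEBBLE)

    def draw(self, t, rng, exp):
        return {"item": self.items[int(rng.integers(len(self.items)))]}

    def cycles(self, info, exp):
        return [Cycle("net", (compound("item", info["item"]),), ())]

    def judge(self, info, emits, exp):
        item = format_term(info["item"])
        accepted = f"accept({item})" in emits
        rejected = f"reject({item})" in emits
        probed = f"probe({item})" in emits
        in_accept_set = info["item"] in set(
            t for f, t in exp.model.accept if f == "net"
        )
        correct = (
            not probed
            and accepted == in_accept_set
            and rejected == (not in_accept_set)
        )
        return {
            "item": item,
            "probed": probed,
            "correct": correct,
            "edible": in_accept_set,
        }

    def feedback(self, info, verdict, exp):
        if not verdict["probed"]:
            return []
        kind = "excite" if verdict["edible"] else "inhibit"
        return [compound(kind, compound("accept", info["item"]))]


class _MatchingEnv(_Env):
    colors = (atom("green"), atom("red"))

    def draw(self, t, rng, exp):
        flip = bool(rng.integers(2))
        i, j = (self.colors if not flip else self.colors[::-1])
        k = self.colors[int(rng.integers(2))]
        fetch = ("a", "b")[int(rng.integers(2))]
        return {"i": i, "j": j, "k": k, "fetch": fetch}

    def cycles(self, info, exp):
        sensors = (
            compound("a", info["i"]),
            compound("b", info["j"]),
            compound("c", info["k"]),
        )
        return [Cycle("net", sensors, (compound("fetch", atom(info["fetch"])),))]

    @staticmethod
    def _match_button(info):
        return "a" if info["i"] == info["k"] else "b"

    def judge(self, info, emits, exp):
        pecked = {e[5:-1] for e in emits if e.startswith("peck(")}
        match = self._match_button(info)
        return {
            "config": f"{format_term(info['i'])}|{format_term(info['j'])}"
                      f"|{format_term(info['k'])}",
            "match": match,
            "pecked": ",".join(sorted(pecked)),
            "correct": pecked == {match},
        }

    def feedback(self, info, verdict, exp):
        if not verdict["correct"]:
            return []
        color = info["k"]
        return [
            compound("excite", compound("peck", atom(verdict["match"]), color))
        ]


class _WinStayEnv(_Env):
    corners = ("left", "right")

    def _rule(self, t, exp):
        rule = exp.params.get("rule", "win_stay")
        swap = exp.params.get("swap_after")
        if swap is not None and t >= swap:
            rule = "win_shift" if rule == "win_stay" else "win_stay"
        return rule

    def draw(self, t, rng, exp):
        info_corner = self.corners[int(rng.integers(2))]
        other = self.corners[1 - self.corners.index(info_corner)]
        food = info_corner if self._rule(t, exp) == "win_stay" else other
        fetch = self.corners[int(rng.integers(2))]
        return {"info_corner": info_corner, "food": food, "fetch": fetch}

    def cycles(self, info, exp):
        return [
            Cycle("net", (compound("info", atom(info["info_corner"])),), ()),
            Cycle(
                "net",
                (atom("choice"),),
                (compound("fetch", atom(info["fetch"])),),
            ),
        ]

    def judge(self, info, emits, exp):
        visits = {e[6:-1] for e in emits if e.startswith("visit(")}
        return {
            "info_corner": info["info_corner"],
            "food": info["food"],
            "visits": ",".join(sorted(visits)),
            "correct": visits == {info["food"]},
        }

    def feedback(self, info, verdict, exp):
        visits = set(verdict["visits"].split(",")) - {""}
        if verdict["correct"]:
            return [compound("excite", compound("visit", atom(info["food"])))]
        if len(visits) == 1:
            return [
                compound("inhibit", compound("visit", atom(visits.pop())))
            ]
        return []


class _SortEnv(_Env):
    edible = ("cake", "orange")
    bins = {"food": "a", "toy": "b"}

    def category(self, item: str) -> str:
        return "food" if item in self.edible else "toy"

    def draw(self, t, rng, exp):
        items = exp.params["train_items"]
        item = items[int(rng.integers(len(items)))]
        fetch = ("a", "b")[int(rng.integers(2))]
        return {"item": item, "fetch": fetch}

    def cycles(self, info, exp):
        return [
            Cycle(
                "sort",
                (compound("show", atom(info["item"])),),
                (compound("fetch", atom(info["fetch"])),),
            )
        ]

    def judge(self, info, emits, exp):
        item = info["item"]
        placements = {
            e[7:-1] for e in emits if e.startswith("put_in(")
        }  # "bin, item"
        want = {f"{self.bins[self.category(item)]}, {item}"}
        return {
            "item": item,
            "category": self.category(item),
            "placements": ";".join(sorted(placements)),
            "correct": placements == want,
        }

    def feedback(self, info, verdict, exp):
        if not verdict["correct"]:
            return []
        cat = verdict["category"]
        return [
            compound(
                "excite",
                compound("sorted", atom(cat), atom(info["item"]), atom(self.bins[cat])),
            )
        ]

    def familiarization_cycles(self, exp: Experiment) -> list[Cycle]:
        """Phase 1: present every object with its taste experience."""
        all_items = self.edible + ("key", "stick")
        out = []
        for item in all_items:
            kind = "excite" if item in self.edible else "inhibit"
            out.append(
                Cycle(
                    "memorize",
                    (compound("obj", atom(item)),),
                    (compound(kind, compound("eat", atom(item))),),
                )
            )
        return out

    def test_cycles(self, exp: Experiment) -> list[Cycle]:
        return [
            Cycle("sort", (compound("show", atom(item)),), ())
            for item in exp.params["test_items"]
        ]


_ENVS = {
    "operant_simple": _OperantEnv(),
    "matching_to_sample": _MatchingEnv(),
    "win_stay_lose_shift": _WinStayEnv(),
    "categorize_sort": _SortEnv(),
}


# ---------------------------------------------------------------------------
# drivers


def _classical_script(exp: Experiment, n_trials: int) -> list[Cycle]:
    mode = exp.params["mode"]
    sensors = {
        "paired": (atom("cs"), atom("us")),  # cs precedes us within a trial
        "us_only": (atom("us"),),
        "cs_only": (atom("cs"),),
    }[mode]
    script = []
    if exp.params["probe_before"]:
        script.append(Cycle("net", (atom("cs"),), ()))
    script.extend(Cycle("net", sensors, ()) for _ in range(n_trials))
    if exp.params["probe_after"]:
        script.append(Cycle("net", (atom("cs"),), ()))
    return script


def run_experiment(
    exp: Experiment,
    n_trials: Optional[int] = None,
    seed: int = 0,
    order: Optional[Callable[[list], list]] = None,
    state: Optional[MachineState] = None,
) -> ExperimentResult:
    """Run an experiment end to end, generating the script closed-loop.

    `order` optionally permutes the react schedule each sweep (used for
    confluence checks); `state` continues an earlier run (used for the
    environment-swap protocols).
    """
    n = exp.n_trials if n_trials is None else n_trials
    rng = np.random.default_rng(seed)
    if state is None:
        state = load(exp.model, exp.config)
    script: list[Cycle] = []
    records: list[dict] = []

    def play(cycles: list[Cycle]):
        first = state.cycle + 1
        for cy in cycles:
            state.sense(cy)
            state.react(order)
        script.extend(cycles)
        return _emits_in(state.trace, first, state.cycle)

    if exp.name == "classical":
        play(_classical_script(exp, n))
        trials = pd.DataFrame({"trial": range(1, n + 1)})
        return ExperimentResult(exp, script, state, trials)

    env = _ENVS[exp.name]
    if exp.name == "categorize_sort" and not state.ltm.traces:
        play(env.familiarization_cycles(exp))

    pending: list[Term] = []
    for t in range(n):
        info = env.draw(t, rng, exp)
        cycles = env.cycles(info, exp)
        if pending:
            cycles[0] = replace(
                cycles[0], stimuli=tuple(pending) + cycles[0].stimuli
            )
            pending = []
        emits = play(cycles)
        verdict = env.judge(info, emits, exp)
        pending = env.feedback(info, verdict, exp)
        records.append({"trial": t + 1, **verdict})

    if exp.name == "categorize_sort":
        for cy in env.test_cycles(exp):
            first = state.cycle + 1
            state.sense(cy)
            state.react(order)
            script.append(cy)
            emits = _emits_in(state.trace, first, state.cycle)
            item = format_term(cy.sensors[0].args[0])
            verdict = env.judge({"item": item}, emits, exp)
            records.append({"trial": len(records) + 1, "block": "test", **verdict})

    trials = pd.DataFrame(records)
    return ExperimentResult(exp, script, state, trials)


def generate_script(exp: Experiment, n_trials: int, seed: int) -> list[Cycle]:
    """The full interrupt script of a run, feedback events included.

    For the closed-loop experiments this simulates the run (the generator
    must consume the trace incrementally); the returned script replayed on
    a fresh machine reproduces the original trace exactly.
    """
    return run_experiment(exp, n_trials=n_trials, seed=seed).script


# ---------------------------------------------------------------------------
# evaluation from the trace alone


def evaluate(exp: Experiment, trace) -> Metrics:
    """Recompute the success metrics from a trace event log."""
    cycles = _grouped_cycles(trace)
    records: list[dict] = []
    if exp.name == "classical":
        trials_df = pd.DataFrame(
            {"trial": [], "correct": []}
        )
        wc = _weight_change_frame(trace)
        return Metrics(trials_df, wc, None, float("nan"))

    env = _ENVS[exp.name]
    keys = sorted(cycles)
    # group run cycles into trials, skipping non-trial blocks
    spans: list[tuple[int, int, dict]] = []
    if exp.name == "categorize_sort":
        trial_keys = [
            k for k in keys
            if any(s.startswith("show(") for s in cycles[k]["sensors"])
        ]
        for k in trial_keys:
            item = cycles[k]["sensors"][0][5:-1]
            spans.append((k, k, {"item": item}))
    elif exp.name == "win_stay_lose_shift":
        info_keys = [
            k for k in keys
            if any(s.startswith("info(") for s in cycles[k]["sensors"])
        ]
        for k in info_keys:
            if k + 1 not in cycles:
                continue
            corner = next(
                s[5:-1] for s in cycles[k]["sensors"] if s.startswith("info(")
            )
            spans.append((k, k + 1, {"info_corner": corner}))
    else:
        for k in keys:
            sensors = cycles[k]["sensors"]
            if exp.name == "operant_simple":
                items = [s for s in sensors if s.startswith("item(")]
                if items:
                    spans.append((k, k, {"item": parse_term(items[0][5:-1])}))
            else:  # matching_to_sample
                if len(sensors) == 3:
                    i, j, kk = (parse_term(s).args[0] for s in sensors)
                    spans.append((k, k, {"i": i, "j": j, "k": kk}))

    for n, (first, last, info) in enumerate(spans, start=1):
        emits = []
        for c in range(first, last + 1):
            emits.extend(cycles.get(c, {"emits": []})["emits"])
        if exp.name == "win_stay_lose_shift":
            info = dict(info)
            corners = ("left", "right")
            other = corners[1 - corners.index(info["info_corner"])]
            rule = env._rule(n - 1, exp)
            info["food"] = info["info_corner"] if rule == "win_stay" else other
        records.append({"trial": n, **env.judge(info, emits, exp)})

    trials_df = pd.DataFrame(records)
    wc = _weight_change_frame(trace)
    correct = trials_df["correct"].tolist() if len(trials_df) else []
    ttc = _trials_to_criterion(correct)
    rate = float(np.mean([bool(c) for c in correct])) if correct else float("nan")
    return Metrics(trials_df, wc, ttc, rate)
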