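# neurovm

A virtual machine for **neuro-symbolic thread circuits**: simple animal
behaviors — classical and operant conditioning up to the third level of
animal awareness — are written as circuits of asynchronously
communicating *threads* (standing for neurons or cell assemblies),
compiled into clocked, guarded virtual code, and interpreted by a machine
whose communication protocols embody synaptic plasticity.  The
quantitative output of every simulation is the modification of synapse
weights over time.

Who it is for: computational/cognitive-neuroscience researchers who want
executable, inspectable symbolic models of learning processes — the level
between spiking-neuron simulation and production-system cognitive
architectures.

## The model

A **thread** is a concurrent unit with a body written in a small circuit
language: a *sequence* of virtual instructions, or an *alternative* of
branches commanded by guards over four internal-stimulus registers
(`fetch`, `catch`, `excite`, `inhibit`).  Threads are grouped into
disjoint **fibers** (neural assemblies); intra-fiber thread pairs carry
discrete integer **weights**.  Compilation turns each body into
implications

```
Guard  =>  T : Instruction
```

interpreted when the thread's local clock reaches `T` and the guard holds
— a linear three-instruction body compiles to clocks 1, 2, 3.  There is
no central clock: each thread advances its own clock one step per
successful instruction and simply retries on failure.

Communication is by four protocol pairs:

| protocol | meaning | gating |
| --- | --- | --- |
| `send` / `receive` | synaptic transmission | weight ≥ θ |
| `join` / `merge` | synapse modulation (ltp/ltd) | none — but tokens die with the stream, so LTP is a **coincidence detector** |
| `push` / `pull` / `reset` | short-term cache (stm) | single slot per location |
| `lts` / `ltr` / `broadcast` | associative long-term memory (ltm) | retrieval only of stored traces, across streams |

A *run* is a loop of interrupts: each cycle terminates the interrupted
stream (its registers, queues and pending coincidences vanish), activates
the sensory threads named by the interrupt, then sweeps all active
threads to quiescence.  Weights change only through ltp/ltd threads, by
±δ, clamped to `[w_min, w_max]`; a pathway is *open* when its weight ≥ θ.

Five experiments ship as runnable circuits with seeded, closed-loop trial
generators: `classical` (aplysia withdrawal), `operant_simple` (pigeon
probing grains vs pebbles), `matching_to_sample` (level-1 awareness),
`win_stay_lose_shift` (level-2, hummingbirds), and `categorize_sort`
(level-3, chimpanzees sorting edible vs inedible objects via long-term
memory).

## Worked example

Three paired cs+us trials followed by a cs-only probe, with threshold
θ=2 (so the cs pathway starts one below threshold, at weight 1):

```sh
$ neurovm run --experiment classical --trials 3 --seed 1 --theta 2 --out-dir demo
4 cycles, 66 trace events
weight sense(cs) -> motor(cs) = 4
weight sense(us) -> motor(us) = 2
```

The weight of the conditioned pathway grew by exactly δ=1 per pairing,
from 1 to 4 (`demo/weights.csv`):

```
cycle,p,q,old,new
1,sense(cs),motor(cs),1,2
2,sense(cs),motor(cs),2,3
3,sense(cs),motor(cs),3,4
```

and the text log (`demo/run.log`) shows sensor inputs (`|:`) and effector
outputs (`>>>`) — the final cs-only probe now triggers the enhanced
withdrawal reflex on its own:

```
|: cs
|: us
>>> withdraw(cs)
>>> withdraw(us)
...
|: cs
>>> withdraw(cs)
```

Running the same command with `probe_before` (via the library:
`build_experiment("classical", theta=2, probe_before=True)`) shows the
probe is silent *before* any pairing: the organism had to learn.

The same CLI drives the other experiments (`--experiment
matching_to_sample`, etc.), `neurovm compile` dumps a circuit's
implication table as TSV, `neurovm render` exports DOT, and `neurovm
replay` re-runs a recorded script byte-identically.

## Library surface

```python
from neurovm import build_experiment, run_experiment, evaluate

exp = build_experiment("matching_to_sample")
result = run_experiment(exp, seed=1)
metrics = evaluate(exp, result.state.trace)
metrics.trials_to_criterion     # e.g. 5
metrics.weight_changes          # tidy frame: cycle, p, q, old, new
```

`parse_model` / `serialize_model` read and write the `.nvm` circuit
language (see `src/neurovm/circuits/` for the shipped fixtures and
`docs/methods.md` for the grammar and semantics).

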