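# Methods

## Scope and stance

neurovm simulates behavior-level learning on an abstracted neural
substrate.  Threads stand for neurons or cell assemblies; nothing below
the communication-protocol level (membrane dynamics, spike timing,
continuous weights) is modeled.  The machine is a discrete, deterministic
interpreter: all randomness lives in the trial-script generators, which
are seeded.  Asynchrony is modeled as interleaving with per-thread local
clocks, not as OS concurrency; a tested confluence property (final
weights invariant under schedule permutations) is what licenses reading
the interleaving as "parallel".

## The circuit language

`.nvm` files are UTF-8 with `#` line comments and four sections: `fiber`
blocks of `thread <name>: <tree>` declarations, `weights`, `accept` and
`sensors`.  Terms are Prolog-like (lowercase atoms/functors, uppercase
variables, `[a, b]` list sugar).  Trees:

```
Tree  ::= '[' Step (',' Step)* ']' | '[]'
Step  ::= Instruction | '{' Guard '->' Tree (';' Guard '->' Tree)* '}'
Guard ::= 'always' | Kind '(' Term ')'     Kind ∈ {fetch, catch, excite, inhibit}
```

An alternative needs at least one guarded branch (not two): feedback-only
threads legitimately have a single `excite` branch, e.g. where a task
uses positive feedback only.  At most one branch may be the `always`
default.  The instruction set is `fire/1, send/1, receive/1, join/1,
merge/1, push/2, pull/1, reset/1, broadcast/1, lts/1, ltr/3, emit/1`;
this 12-opcode set is a reconstruction — it is the minimal set covering
every protocol and circuit the package implements, and is documented as
such.  Variable-functor ("variadic") terms are not supported; every
pattern that needs to range over stimuli does so through explicit
functors in guards and the sensor map.

Parameterized thread names (`learn(accept(I))`) are templates.  An
instance is created lazily: when a sensor term routes to it, when it is
`fire`d with bound arguments, or when an internal stimulus unifies with
one of its guards *and thereby grounds its name*.  A template whose name
is not fully determined by the stimulus (e.g. a `fetch` guard with no
name variables bound) is never stimulus-instantiated; such threads are
reached by `fire` and read the stimulus from the stream's buffer (below).

## Compilation

Recursive descent; clocks start at 1 and advance one per instruction
leaf.  Sibling branches of an alternative start at the same clock,
distinguished by their guards; an instruction following an alternative
resumes at 1 + the deepest branch clock.  Only the first instruction of a
branch carries the branch guard — the choice is made at entry, and with
registers persisting for the stream's lifetime, re-checking at every
depth would be redundant and would deadlock threads whose registers are
overwritten mid-branch.  Since sibling continuations then collide on
(clock, `always`), every implication carries a *branch tag* — the path of
(alternative-id, branch-index) choices above it — and the interpreter
filters implications against the choices the thread has already made.
Guards do not compose: an alternative may not be the first step inside a
guarded branch (compile error).  A branch shorter than its siblings
rejoins the sequence by jumping its clock forward to the next compatible
implication; this jump is not an execution and emits no event.

## Interpretation

Per run cycle: `sense` then `react`.

`sense` terminates the interrupted stream — active threads, signal pool,
modulation tokens and the stimulus buffer of that fiber are discarded;
weights, stm caches, ltm traces and broadcast paths persist.  Sensor
terms are routed through the sensor map (first matching pattern) and
activate their sensory threads at clock 1.  Internal stimuli
`kind(term)` are (a) written to the `kind` register of every active
thread with a unifying guard, (b) used for lazy template instantiation,
and (c) buffered for the stream's lifetime, so a thread activated later
in the same stream (e.g. a choice thread fired downstream of a memory
recall) still sees the stimulus at its own activation.  Registers hold
one value; a later stimulus of the same kind overwrites.

`react` sweeps a snapshot of the active threads; for each, deduction
selects the implication at the thread's clock whose guard holds —
satisfiable guarded branches take priority over the `always` default, and
two simultaneously satisfiable guarded branches are a model error
(raised).  Successful execution advances the clock by 1; failure
(receive below threshold or without signal, join without token, pull on
an empty cache, ltr without a stored trace) leaves the clock unchanged
and is retried next sweep.  Sweeps repeat until a full sweep makes no
progress; threads activated during a sweep are first visited on the
next.  The default visit order is activation order (FIFO); permutation
invariance of the final weights is asserted by test, not assumed.  A
configurable sweep cap (default 1000) turns genuine livelock (e.g. two
threads firing each other forever) into a diagnostic error naming the
active threads.

Firing an already-active thread restarts it at clock 1 with a fresh body
instantiation; its registers are kept (the stream's stimuli still apply).
Signals and tokens are held in per-fiber pools of (sender, addressee)
pairs rather than per-thread queues: a send addressed to a thread that
activates one sweep later must not be lost, and the pool has exactly the
queue semantics otherwise (cleared with the stream, consumed one per
receive, FIFO among matches).

`receive(P)` consumes one P-tagged signal iff the weight of (sender,
receiver) is ≥ θ (weak inequality).  `join`/`merge` tokens are not
weight-gated: they model the modulatory pathway, not a synapse.  `pull`
is non-consuming; `push` overwrites its single slot; `reset` is the only
eraser.  `lts` stores a ground trace; `broadcast` posts a global path
term; `ltr(P, Q, R)` succeeds when some path unifies with `ltm(P)` *and*
the (possibly further bound) P unifies with a stored trace, then fires R
in the caller's stream with those bindings.  Basic threads `ltp(P,Q)` /
`ltd(P,Q)` have the built-in body `[join(S), potentiate/depress(P,Q)]`:
the join consumes a token from whichever thread merged for them, so a
weight moves only on within-stream coincidence of the firing and the
merge.  `potentiate`/`depress` are internal opcodes, not surface
language: weights can change through no other path, which the trace
makes checkable.

Weights are integers clamped to `[w_min, w_max]`.  Weight entries may be
declared over *patterns* (`match(a, I) -> peck(a) = 0`); lookup and
plasticity resolve a ground pair against the entries by unification and
mutate the declared entry, so one potentiation generalizes over
everything the pattern covers.  Ground entries (the operant circuit)
keep learning item-specific.  Plasticity on a never-declared pair creates
an implicit entry at `w_min`.  Clamped-at-bound applications still emit a
weight_change event with old == new; the signed deltas therefore always
sum to final − initial per pair.

### Parameters

| parameter | default | meaning |
| --- | --- | --- |
| θ (`theta`) | 1 | receive threshold; pathway open iff weight ≥ θ |
| δ (`delta`) | 1 | ltp/ltd step |
| `w_min`, `w_max` | 0, 5 | weight clamp |
| `sweep_cap` | 1000 | livelock guard per run cycle |

All dimensionless integers.  Circuit fixtures write weights for θ=1
(open = 1, closed = 0); `build_experiment(..., theta=t)` rescales open
pathways to t and closed ones to t−1.

## Experiments and generators

The generators are the study conditions, not tuning knobs.  Feedback for
trial t is delivered in the interrupt opening trial t+1 (interrupts
delimit trials); random choices (item, colors, corners, the animal's
random action under `fetch`) are drawn from one seeded numpy generator
per run, so scripts replay byte-identically.

* **classical** — default 5 pairings (cs before us within each cycle)
  plus a cs-only probe; variants deliver us-only or cs-only blocks.  The
  conditioned weight follows w0 + n·δ exactly.
* **operant_simple** — 12 trials over grain `[mat, smooth]` (in the
  accept set) and pebble `[shiny, smooth]`; probing emits feedback
  judged against the accept set; terminal state: learn pathway closed,
  exactly one of accept/reject open per item.
* **matching_to_sample** — 100 trials; the sample-alone preliminary step
  is omitted; one green and one red button, arrangement and sample color
  random; positive feedback only.  The circuit's comparison is innate
  address unification; what is learned is the color-generic match→peck
  gate plus closure of random pecking.  Acquisition is typically reached
  within ~5–20 trials.
* **win_stay_lose_shift** — 60 two-stage trials; the information-stage
  corner is cached by `push`; reward potentiates the recall pathway.
  Swapping the world to win/shift (food in the opposite corner) defeats
  the trained circuit because it has no inhibit-driven re-learning
  circuitry — by design.
* **categorize_sort** — familiarization of all four objects (cake,
  orange, key, stick) with taste stimuli, then up to 30 closed-loop
  sorting trials on cake and key only, then a no-feedback test block on
  orange and stick.  Bin pathways are declared per category, so the test
  objects are sorted correctly on first presentation with zero
  plasticity.

What the generators emulate: trial-structured conditioning protocols
with deterministic reward rules.  What they do not: sensory noise,
partial reinforcement, motivational state, reaction time, forgetting.
Passing tests therefore show that the circuits implement the *logic* of
the described learning processes under idealized protocols — not that
they fit quantitative animal data.

## Metrics

Computed solely from the trace event log: per-trial correctness (the
emitted action set against the environment rule, trial configurations
reconstructed from the logged sensor terms), cumulative and trailing
reward rate, weight trajectories per pair, and trials-to-criterion — the
1-based index of the first trial after which every trial (itself
included) is correct, None if the run never settles.

## Known limitations

* Guards cannot be composed (no alternative as the first step of a
  guarded branch); nest the guard inside the branch body instead.
* The `catch` register exists but no shipped circuit uses it.
* Weight-pattern generalization is a declaration-time choice; the
  machine does not learn which pairs to generalize over.
* Livelock detection is a sweep-count heuristic, not a proof.
* Trace volume grows with retry events (one per stalled thread per
  sweep); large sweep caps on stalled circuits produce large traces.
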