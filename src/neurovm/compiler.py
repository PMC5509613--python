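"""Compiling instruction trees (language S) into virtual code implications.

A compiled unit is ``Guard => T:Instruction`` — the instruction a thread
executes when its local clock reaches T and the guard holds.  Clocks start
at 1 and follow the depth of the recursive descent: a linear body of three
instructions compiles to clocks 1, 2, 3; sibling branches of an
alternative restart at the same clock, distinguished by their guards, and
an instruction following an alternative resumes at one past the deepest
branch.

Only the first instruction of a branch carries the branch guard — once a
thread has descended into a branch the choice is made, so continuations
compile to ``always``.  Because two sibling continuations can then share a
clock, every implication carries a *branch tag* (a path of
``(alternative-id, branch-index)`` choices); the interpreter keeps the
choices a thread has made and only considers compatible implications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .dsl import ALWAYS, Alt, Guard, Instr, ModelSpec, Seq, ThreadSpec
from .terms import Term, format_term

__all__ = ["CodeImplication", "CompileError", "compile_tree", "compile_thread"]


class CompileError(ValueError):
    pass


@dataclass(frozen=True)
class CodeImplication:
    """``guard => clock : instruction`` with its branch-choice tag."""

    guard: Guard
    clock: int
    instruction: Term
    branch: tuple = ()  # ((alt_id, branch_index), ...)

    def __str__(self) -> str:
        return f"{self.guard} => {self.clock}:{format_term(self.instruction)}"


def compile_tree(tree: Seq, thread_name: str = "?") -> list[CodeImplication]:
    """Recursive descent producing one implication per instruction leaf."""
    imps: list[CodeImplication] = []
    alt_counter = [0]

    def descend(node, clock: int, pending: Optional[Guard], branch: tuple):
        # returns (next clock, still-pending guard)
        if isinstance(node, Instr):
            imps.append(
                CodeImplication(pending or ALWAYS, clock, node.term, branch)
            )
            return clock + 1, None
        if isinstance(node, Seq):
            g = pending
            for step in node.steps:
                clock, g = descend(step, clock, g, branch)
            return clock, g
        assert isinstance(node, Alt)
        if pending is not None:
            raise CompileError(
                f"thread {thread_name}: an alternative cannot be the first "
                f"step of a guarded branch (guards do not compose)"
            )
        n_always = sum(1 for bg, _ in node.branches if bg.is_always)
        if n_always > 1:
            raise CompileError(
                f"thread {thread_name}: ambiguous alternative with "
                f"{n_always} 'always' branches"
            )
        alt_counter[0] += 1
        alt_id = alt_counter[0]
        deepest = clock
        for idx, (bg, btree) in enumerate(node.branches):
            end, leftover = descend(
                btree, clock, None if bg.is_always else bg, branch + ((alt_id, idx),)
            )
            # leftover only for an empty branch: its guard guards nothing
            deepest = max(deepest, end)
        return deepest, None

    end, leftover = descend(tree, 1, None, ())
    return imps


def compile_thread(spec: ThreadSpec) -> list[CodeImplication]:
    return compile_tree(spec.body, format_term(spec.name))


def implications_tsv(model: ModelSpec) -> str:
    """Dump the full implication table (thread, guard, clock, opcode, args,
    branch) as TSV for inspection and golden-file testing."""
    rows = ["thread\tguard\tclock\topcode\targs\tbranch"]
    for fiber in model.fibers:
        for th in fiber.threads:
            for imp in compile_thread(th):
                args = ", ".join(format_term(a) for a in imp.instruction.args)
                branch = ".".join(f"{a}:{b}" for a, b in imp.branch)
                rows.append(
                    f"{format_term(th.name)}\t{imp.guard}\t{imp.clock}\t"
                    f"{imp.instruction.functor}\t{args}\t{branch}"
                )
    return "\n".join(rows) + "\n"
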