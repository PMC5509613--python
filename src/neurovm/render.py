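"""DOT export of a parsed model, for visual comparison with wiring diagrams.

Threads are nodes grouped by fiber; synaptic send edges are solid and
labeled with the declared initial weight when one exists; modulatory
merge edges (join/merge protocol) are dashed; fire edges are dotted.
"""

from __future__ import annotations

from .dsl import Alt, Instr, ModelSpec, Seq
from .terms import format_term

__all__ = ["to_dot"]


def _edges(body: Seq):
    for step in body.steps:
        if isinstance(step, Instr):
            if step.opcode in ("send", "fire", "merge"):
                yield step.opcode, step.args[0]
        else:
            for _, tree in step.branches:
                yield from _edges(tree)


def to_dot(model: ModelSpec) -> str:
    lines = [f'digraph "{model.name}" {{', "  rankdir=LR;", "  node [shape=box];"]
    weights = {
        (format_term(w.source), format_term(w.recipient)): w.weight
        for w in model.weights
    }
    ids: dict[str, str] = {}

    def node_id(name: str) -> str:
        if name not in ids:
            ids[name] = f"n{len(ids)}"
        return ids[name]

    for fiber in model.fibers:
        lines.append(f'  subgraph "cluster_{fiber.name}" {{')
        lines.append(f'    label="{fiber.name}";')
        for th in fiber.threads:
            name = format_term(th.name)
            lines.append(f'    {node_id(name)} [label="{name}"];')
        lines.append("  }")
    for fiber in model.fibers:
        for th in fiber.threads:
            src = format_term(th.name)
            for op, target in _edges(th.body):
                dst = format_term(target)
                if dst not in ids:  # basic-thread instance, e.g. ltp(...)
                    lines.append(
                        f'  {node_id(dst)} [label="{dst}", shape=ellipse];'
                    )
                attrs = []
                if op == "send":
                    w = weights.get((src, dst))
                    if w is not None:
                        attrs.append(f'label="{w}"')
                elif op == "merge":
                    attrs.append("style=dashed")
                else:
                    attrs.append("style=dotted")
                a = f' [{", ".join(attrs)}]' if attrs else ""
                lines.append(f"  {node_id(src)} -> {node_id(dst)}{a};")
    lines.append("}")
    return "\n".join(lines) + "\n"
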