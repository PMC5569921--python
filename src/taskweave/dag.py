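"""Build the task DAG and derive a deterministic, maximally concurrent plan.

Nodes are task sections; edges come from IO-connections (data flow) and
from forced dependencies (ordering without data flow, e.g. "the index
file must exist before the caller runs").  Both edge kinds constrain
scheduling identically; the kind is kept for reporting and DOT export.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx

from .config_model import WorkflowConfig
from .errors import CycleError


@dataclass
class WorkflowGraph:
    """Task DAG with per-node payload (task section, component definition)."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str, str]]:
        return {
            (u, v, data["kind"]) for u, v, data in self.graph.edges(data=True)
        }

    def payload(self, task: str):
        node = self.graph.nodes[task]
        return node["section"], node["component"]

    def predecessors(self, task: str) -> list[str]:
        return sorted(self.graph.predecessors(task))

    def descendants(self, task: str) -> set[str]:
        return nx.descendants(self.graph, task)

    def to_dot(self) -> str:
        """Graphviz DOT rendering; forced edges are dashed."""
        lines = ["digraph workflow {"]
        for node in sorted(self.graph.nodes):
            comp = self.graph.nodes[node].get("component")
            label = f"{node}\\n({comp.name})" if comp is not None else node
            lines.append(f'  "{node}" [label="{label}"];')
        for u, v, data in sorted(self.graph.edges(data=True)):
            style = ' [style=dashed,label="forced"]' if data["kind"] == "forced" else ""
            lines.append(f'  "{u}" -> "{v}"{style};')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ExecutionPlan:
    """Stages of tasks; stage k depends only on stages < k.

    Stage membership is the longest-path depth of each node, so the plan
    is maximally concurrent: every task runs at the earliest stage its
    dependencies allow.  Names within a stage are sorted so plans and
    logs are reproducible across runs and platforms.
    """

    stages: tuple[tuple[str, ...], ...]

    def stage_of(self, task: str) -> int:
        for i, stage in enumerate(self.stages):
            if task in stage:
                return i
        raise KeyError(task)

    def tasks(self) -> list[str]:
        return [t for stage in self.stages for t in stage]

    def to_json(self) -> str:
        return json.dumps({"stages": [list(s) for s in self.stages]}, indent=2)


def build_graph(config: WorkflowConfig, registry=None) -> WorkflowGraph:
    """Turn a concrete (post-sweep) configuration into a task DAG.

    Raises :class:`CycleError` naming one offending cycle as a task-name
    path if the dependencies are circular.
    """
    g = nx.DiGraph()
    for tname, task in config.tasks.items():
        comp = registry.get(task.component_name) if registry is not None else None
        g.add_node(tname, section=task, component=comp)
    for tname, task in config.tasks.items():
        for _, conn in task.connections():
            if conn.is_task:
                _add_edge(g, conn.source_task, tname, "io")
        for dep in task.forced_dependencies:
            _add_edge(g, dep, tname, "forced")
    _check_acyclic(g)
    return WorkflowGraph(graph=g)


def _add_edge(g: nx.DiGraph, u: str, v: str, kind: str) -> None:
    # io (data-flow) wins when both kinds exist between the same pair
    if g.has_edge(u, v) and g.edges[u, v]["kind"] == "io":
        return
    g.add_edge(u, v, kind=kind)


def _check_acyclic(g: nx.DiGraph) -> None:
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return
    raise CycleError([u for u, _ in cycle] + [cycle[-1][1]])


def plan(graph: WorkflowGraph | nx.DiGraph) -> ExecutionPlan:
    """Partition the DAG into stages by longest-path depth (Kahn levels)."""
    g = graph.graph if isinstance(graph, WorkflowGraph) else graph
    _check_acyclic(g)
    depth: dict[str, int] = {}
    for node in nx.topological_sort(g):
        preds = list(g.predecessors(node))
        depth[node] = 1 + max((depth[p] for p in preds), default=-1)
    n_stages = max(depth.values(), default=-1) + 1
    stages: list[list[str]] = [[] for _ in range(n_stages)]
    for node, d in depth.items():
        stages[d].append(node)
    return ExecutionPlan(stages=tuple(tuple(sorted(s)) for s in stages))
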