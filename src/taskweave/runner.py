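"""Execute compiled workflows: workspaces, dispatch, sentinels, scatter-gather.

Each run gets a run-ID-tagged directory tree with one directory per
sample, each holding exactly four standard subdirectories::

    <out_root>/<run_id>/<sample_id>/
        logs/       per-task stdout/stderr
        outputs/    everything the wrapped tools write
        scripts/    the generated shell script for each task invocation
        sentinels/  completion markers enabling skip-on-resume

A sentinel records a hash of the task's rendered command, its component
version, and the sentinels of its dependencies; a task is skipped on
re-execution iff its sentinel hash still matches.  Because dependency
hashes chain, editing one task's parameters invalidates exactly that
task and its descendants.  Workspace paths are canonicalized out of the
hash, so a completed workspace can be relocated (intermediates included)
and resumed on another machine.
"""

from __future__ import annotations

import hashlib
import json
import random
import shlex
import string
import subprocess
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import networkx as nx

from .components import ComponentDefinition, build_command
from .config_model import (
    KeywordContext,
    TaskSection,
    WorkflowConfig,
    interpolate_keywords,
)
from .dag import ExecutionPlan, build_graph, plan
from .errors import ExecutionError, WorkspaceError

STANDARD_SUBDIRS = ("logs", "outputs", "scripts", "sentinels")

_RUN_MARKER = ".run.json"
_WS_TOKEN = "<WS>"  # stands in for the sample workspace root when hashing


# --------------------------------------------------------------------------
# run identifiers and workspaces
# --------------------------------------------------------------------------

def make_run_id(rng: random.Random | None = None) -> str:
    """UTC timestamp plus a 4-char base36 suffix; unique per invocation."""
    rng = rng or random.Random()
    stamp = datetime.now(timezone.utc).strftime("%Y%m%d-%H%M%S")
    alphabet = string.digits + string.ascii_lowercase
    suffix = "".join(rng.choice(alphabet) for _ in range(4))
    return f"{stamp}-{suffix}"


@dataclass(frozen=True)
class Workspace:
    """One sample's directory tree inside a run."""

    root: Path

    @property
    def logs_dir(self) -> Path:
        return self.root / "logs"

    @property
    def outputs_dir(self) -> Path:
        return self.root / "outputs"

    @property
    def scripts_dir(self) -> Path:
        return self.root / "scripts"

    @property
    def sentinels_dir(self) -> Path:
        return self.root / "sentinels"


@dataclass
class RunState:
    """Workspace layout and sentinel ledger of one run."""

    run_id: str
    root: Path
    sample_workspaces: dict[str, Workspace]

    def sentinel_path(self, sample_id: str, instance: str) -> Path:
        return self.sample_workspaces[sample_id].sentinels_dir / f"{instance}.json"


def create_run_workspace(
    out_root: Path,
    run_id: str,
    sample_ids,
    workflow_name: str = "workflow",
) -> RunState:
    """Create (idempotently) the run-ID-tagged directory tree.

    An existing directory belonging to a *different* workflow is refused
    rather than clobbered; re-creating the same run's tree changes
    nothing, which is what resume relies on.
    """
    out_root = Path(out_root)
    run_root = out_root / run_id
    marker = run_root / _RUN_MARKER
    if marker.exists():
        recorded = json.loads(marker.read_text())
        if recorded.get("workflow") != workflow_name:
            raise WorkspaceError(
                f"{run_root} belongs to workflow "
                f"{recorded.get('workflow')!r}, not {workflow_name!r}"
            )
    sample_ids = list(sample_ids) or ["run"]
    workspaces: dict[str, Workspace] = {}
    for sid in sample_ids:
        ws = Workspace(root=run_root / sid)
        for sub in STANDARD_SUBDIRS:
            (ws.root / sub).mkdir(parents=True, exist_ok=True)
        workspaces[sid] = ws
    if not marker.exists():
        marker.write_text(json.dumps(
            {"run_id": run_id, "workflow": workflow_name}
        ))
    return RunState(run_id=run_id, root=run_root, sample_workspaces=workspaces)


# --------------------------------------------------------------------------
# executor backends
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Resources:
    memory: str = "1G"
    num_cpus: int = 1


class LocalBackend:
    """Run task scripts as local subprocesses."""

    def submit(self, script: Path, resources: Resources, stdout: Path, stderr: Path):
        out = open(stdout, "ab")
        err = open(stderr, "ab")
        proc = subprocess.Popen(["bash", str(script)], stdout=out, stderr=err)
        return proc, out, err

    def wait(self, handle) -> int:
        proc, out, err = handle
        rc = proc.wait()
        out.close()
        err.close()
        return rc


class DryRunBackend:
    """Executes nothing; every submission succeeds instantly.

    Useful for inspecting schedules and traces: the engine still writes
    scripts and sentinels and records per-task timings, but the wrapped
    tools never run.
    """

    def submit(self, script, resources, stdout, stderr):
        return 0

    def wait(self, handle) -> int:
        return 0


class ShellTemplateBackend:
    """Cluster-style backend: shells out to a user-supplied submit template.

    The template is a shell command with ``{script}``, ``{memory}``,
    ``{num_cpus}``, ``{stdout}`` and ``{stderr}`` placeholders; it must
    block until the job finishes and propagate the job's exit status
    (most schedulers offer a sync/wait flag, e.g. ``qsub -sync y``).
    """

    def __init__(self, template: str):
        self.template = template

    def submit(self, script: Path, resources: Resources, stdout: Path, stderr: Path):
        cmd = self.template.format(
            script=shlex.quote(str(script)),
            memory=resources.memory,
            num_cpus=resources.num_cpus,
            stdout=shlex.quote(str(stdout)),
            stderr=shlex.quote(str(stderr)),
        )
        return subprocess.Popen(cmd, shell=True)

    def wait(self, handle) -> int:
        return handle.wait()


# --------------------------------------------------------------------------
# chunking
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ChunkSpec:
    """One shard of a parallelized task.

    ``region`` is a genomic interval token ``chrom:start-end`` (0-based,
    half-open, BED convention) or a generic ``i/n`` shard token.
    """

    chunk_id: str
    region: str


def chunks_from_bed(bed_path: Path) -> list[ChunkSpec]:
    """One chunk per BED interval, in file order; overlaps are an error."""
    chunks: list[ChunkSpec] = []
    intervals: dict[str, list[tuple[int, int]]] = {}
    for line in Path(bed_path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split()
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        if end <= start:
            raise ExecutionError(f"{bed_path}: empty interval {line!r}")
        for s, e in intervals.setdefault(chrom, []):
            if start < e and s < end:
                raise ExecutionError(
                    f"{bed_path}: overlapping intervals on {chrom}"
                )
        intervals[chrom].append((start, end))
        chunks.append(ChunkSpec(f"c{len(chunks)}", f"{chrom}:{start}-{end}"))
    if not chunks:
        raise ExecutionError(f"{bed_path}: no intervals")
    return chunks


def chunks_from_count(n: int) -> list[ChunkSpec]:
    if n < 1:
        raise ExecutionError("chunk count must be >= 1")
    return [ChunkSpec(f"c{i}", f"{i}/{n}") for i in range(n)]


# --------------------------------------------------------------------------
# task instances (static resolution)
# --------------------------------------------------------------------------

@dataclass
class TaskInstance:
    """One schedulable unit: a task, a chunk of a task, or a merge node."""

    name: str
    kind: str  # "task" | "chunk" | "merge"
    command: str
    resources: Resources
    output_dirs: list[Path] = field(default_factory=list)
    hash: str = ""


def _resolve_params(
    config: WorkflowConfig,
    graph,
    ws: Workspace,
    ctx_base: dict,
) -> dict[str, dict]:
    """Statically resolve every task's parameter values, in topo order."""
    resolved: dict[str, dict] = {}
    order = [t for stage in plan(graph).stages for t in stage]
    for tname in order:
        section, comp = graph.payload(tname)
        ctx = KeywordContext(task_name=tname, **ctx_base)
        out_dir = ws.outputs_dir / interpolate_keywords(
            section.output_dir_name or tname, ctx
        )
        values: dict = {}
        for pname, value in section.params.items():
            values[pname] = _resolve_value(
                value, pname, comp, resolved, out_dir, ctx
            )
        resolved[tname] = values
    return resolved


def _resolve_value(value, pname, comp, resolved, out_dir, ctx):
    from .config_model import IOConnection

    if isinstance(value, IOConnection):
        return resolved[value.source_task][value.source_param]
    if isinstance(value, list):
        return [
            _resolve_value(v, pname, comp, resolved, out_dir, ctx)
            for v in value
        ]
    if isinstance(value, str):
        value = interpolate_keywords(value, ctx)
        try:
            role = comp.param(pname).role if comp is not None else "argument"
        except KeyError:
            role = "argument"
        if role == "output_file" and not Path(value).is_absolute():
            return str(out_dir / value)
    return value


def _resources_for(section: TaskSection, comp: ComponentDefinition | None,
                   general: dict) -> Resources:
    memory = (
        section.run.memory
        or general.get("default_memory")
        or (comp.requirements.memory if comp else "1G")
    )
    cpus = (
        section.run.num_cpus
        or general.get("default_num_cpus")
        or (comp.requirements.num_cpus if comp else 1)
    )
    return Resources(memory=str(memory), num_cpus=int(cpus))


def _merge_script(strategy: str, inputs: list[str], output: str,
                  template: str | None) -> str:
    q_in = " ".join(shlex.quote(i) for i in inputs)
    q_out = shlex.quote(output)
    if strategy == "concat":
        return f"cat {q_in} > {q_out}"
    if strategy == "concat_skip_header":
        first = shlex.quote(inputs[0])
        return (
            f"( head -n 1 {first} && tail -q -n +2 {q_in} ) > {q_out}"
        )
    if strategy == "merge_command":
        return template.format(inputs=q_in, output=q_out)
    raise ExecutionError(f"unknown merge strategy {strategy!r}")


def prepare_sample(
    config: WorkflowConfig,
    registry,
    ws: Workspace,
    run_id: str,
    sample_id: str,
    workflow_name: str,
) -> tuple[nx.DiGraph, dict[str, TaskInstance]]:
    """Build the execution graph of task instances for one sample.

    Parallelizable tasks with ``parallel_run`` set are expanded here into
    per-chunk children plus a merge node that reassembles the outputs the
    serial task would have produced; downstream consumers are untouched
    because they already point at those (merged) paths.
    """
    graph = build_graph(config, registry)
    ctx_base = {
        "run_id": run_id, "workflow_name": workflow_name,
        "sample_id": sample_id,
    }
    resolved = _resolve_params(config, graph, ws, ctx_base)

    exec_graph = nx.DiGraph()
    instances: dict[str, TaskInstance] = {}

    # topological order so predecessors are already expanded when wiring
    for tname in plan(graph).tasks():
        section, comp = graph.payload(tname)
        ctx = KeywordContext(task_name=tname, **ctx_base)
        resources = _resources_for(section, comp, config.general)
        boilerplate = (
            interpolate_keywords(section.run.boilerplate, ctx)
            if section.run.boilerplate else None
        )
        out_dirs = [
            Path(v).parent
            for p, v in resolved[tname].items()
            if comp is not None
            and any(s.name == p and s.role == "output_file" for s in comp.params)
        ]
        if section.run.parallel_run:
            names = _expand_parallel(
                tname, section, comp, resolved[tname], boilerplate,
                resources, out_dirs, exec_graph, instances,
            )
            entries = names[:-1]  # every chunk waits on the task's deps
        else:
            command = build_command(comp, resolved[tname], boilerplate)
            instances[tname] = TaskInstance(
                name=tname, kind="task", command=command,
                resources=resources, output_dirs=out_dirs,
            )
            exec_graph.add_node(tname)
            entries = [tname]
        for pred in graph.predecessors(tname):
            pred_exit = _exit_of(exec_graph, pred)
            for node in entries:
                exec_graph.add_edge(pred_exit, node)

    # chain sentinel hashes through dependencies so edits propagate
    ws_root = str(ws.root)
    for name in nx.topological_sort(exec_graph):
        inst = instances[name]
        h = hashlib.sha256()
        h.update(inst.command.replace(ws_root, _WS_TOKEN).encode())
        for pred in sorted(exec_graph.predecessors(name)):
            h.update(instances[pred].hash.encode())
        inst.hash = h.hexdigest()
    return exec_graph, instances


def _expand_parallel(
    tname, section, comp, values, boilerplate, resources, out_dirs,
    exec_graph, instances,
):
    if comp is None or comp.parallelization is None:
        raise ExecutionError(
            f"{tname}: parallel_run set but component declares no "
            "parallelization contract"
        )
    par = comp.parallelization
    chunks = _derive_chunks(tname, section, comp, values)
    out_params = [p.name for p in comp.output_params]
    missing = [p for p in out_params if values.get(p) is None]
    if missing:
        raise ExecutionError(
            f"{tname}: parallel_run requires explicit values for output "
            "parameter(s): " + ", ".join(missing)
        )
    child_names = []
    for chunk in chunks:
        child_values = dict(values)
        child_values[par.split_param] = chunk.region
        for p in out_params:
            child_values[p] = f"{values[p]}.{chunk.chunk_id}"
        cname = f"{tname}.{chunk.chunk_id}"
        instances[cname] = TaskInstance(
            name=cname, kind="chunk",
            command=build_command(comp, child_values, boilerplate),
            resources=resources, output_dirs=list(out_dirs),
        )
        exec_graph.add_node(cname)
        child_names.append(cname)
    merge_name = f"{tname}.merge"
    merge_cmd = " && ".join(
        _merge_script(
            par.merge_strategy,
            [f"{values[p]}.{c.chunk_id}" for c in chunks],
            values[p],
            par.merge_command,
        )
        for p in out_params
    )
    instances[merge_name] = TaskInstance(
        name=merge_name, kind="merge", command=merge_cmd,
        resources=Resources(), output_dirs=list(out_dirs),
    )
    exec_graph.add_node(merge_name)
    for cname in child_names:
        exec_graph.add_edge(cname, merge_name)
    # dependency wiring: predecessors feed every child; merge feeds onward
    return child_names + [merge_name]


def _derive_chunks(tname, section, comp, values) -> list[ChunkSpec]:
    src = section.run.interval_source
    if src is not None:
        path = values.get(src, src) if isinstance(src, str) else src
        return chunks_from_bed(Path(str(path)))
    if section.run.num_chunks:
        return chunks_from_count(int(section.run.num_chunks))
    raise ExecutionError(
        f"{tname}: parallel_run needs interval_source or num_chunks"
    )


def _exit_of(exec_graph, task: str) -> str:
    """The instance downstream consumers wait on: the merge node if expanded."""
    merge = f"{task}.merge"
    return merge if merge in exec_graph else task


# --------------------------------------------------------------------------
# run reports
# --------------------------------------------------------------------------

@dataclass
class TaskResult:
    name: str
    status: str  # done | skipped | failed | blocked | not_run
    stage: int
    started_at: float | None = None
    finished_at: float | None = None
    exit_code: int | None = None

    def to_dict(self) -> dict:
        return self.__dict__.copy()


@dataclass
class SampleReport:
    sample_id: str
    status: str  # success | failed | paused
    tasks: dict[str, TaskResult] = field(default_factory=dict)

    def by_status(self, status: str) -> list[str]:
        return sorted(t for t, r in self.tasks.items() if r.status == status)

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "status": self.status,
            "tasks": {t: r.to_dict() for t, r in self.tasks.items()},
        }


@dataclass
class RunReport:
    run_id: str
    workflow_name: str
    status: str
    samples: dict[str, SampleReport] = field(default_factory=dict)

    @property
    def failed_tasks(self) -> list[str]:
        return [
            f"{sid}:{t}"
            for sid, rep in self.samples.items()
            for t in rep.by_status("failed")
        ]

    def to_dict(self) -> dict:
        return {
            "run_id": self.run_id,
            "workflow": self.workflow_name,
            "status": self.status,
            "samples": {s: r.to_dict() for s, r in self.samples.items()},
        }


# --------------------------------------------------------------------------
# execution
# --------------------------------------------------------------------------

_SCRIPT_HEADER = "#!/usr/bin/env bash\nset -euo pipefail\n"


def execute(
    compiled,
    backend=None,
    num_jobs: int = 1,
    resume: str | None = None,
    out_root: Path | None = None,
    breakpoint_task: str | None = None,
    halt_on_first_failure: bool = False,
    run_id: str | None = None,
    rng: random.Random | None = None,
) -> RunReport:
    """Run a compiled workflow and return the run report.

    Stages execute in order; within a stage up to ``num_jobs`` tasks run
    concurrently, and sweep sub-workflows run concurrently with each
    other under the same global job bound.  Tasks whose sentinel hash
    matches are skipped, which is both the resume mechanism and the
    no-op behaviour of re-running a finished workflow.  ``resume`` names
    an existing run-ID to pick up; ``breakpoint_task`` pauses the run
    after that task (configuration-file breakpoints do the same).
    """
    backend = backend or LocalBackend()
    if resume is not None:
        run_id = resume
    elif run_id is None:
        run_id = make_run_id(rng)
    out_root = Path(out_root) if out_root is not None else compiled.root / "runs"

    sub = compiled.sub_workflows
    if breakpoint_task is not None and not any(
        breakpoint_task in cfg.tasks for cfg in sub.values()
    ):
        raise ExecutionError(f"breakpoint task {breakpoint_task!r} not in workflow")
    state = create_run_workspace(
        out_root, run_id, list(sub), workflow_name=compiled.workflow_name
    )
    throttle = threading.BoundedSemaphore(max(1, num_jobs))

    reports: dict[str, SampleReport] = {}
    with ThreadPoolExecutor(max_workers=max(1, len(sub))) as pool:
        futures = {
            sid: pool.submit(
                _run_sample, compiled, cfg, state, sid, backend, num_jobs,
                throttle, breakpoint_task, halt_on_first_failure,
            )
            for sid, cfg in sub.items()
        }
        for sid, fut in futures.items():
            reports[sid] = fut.result()

    if any(r.status == "failed" for r in reports.values()):
        status = "failed"
    elif any(r.status == "paused" for r in reports.values()):
        status = "paused"
    else:
        status = "success"
    report = RunReport(
        run_id=run_id, workflow_name=compiled.workflow_name,
        status=status, samples=reports,
    )
    (state.root / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report


def _run_sample(
    compiled, config, state, sample_id, backend, num_jobs,
    throttle, breakpoint_task, halt_on_first_failure,
) -> SampleReport:
    ws = state.sample_workspaces[sample_id]
    exec_graph, instances = prepare_sample(
        config, compiled.registry, ws, state.run_id, sample_id,
        compiled.workflow_name,
    )
    exec_plan = plan(exec_graph)
    report = SampleReport(sample_id=sample_id, status="success")
    for name in instances:
        report.tasks[name] = TaskResult(
            name=name, status="not_run", stage=exec_plan.stage_of(name)
        )

    bp_stage = _breakpoint_stage(
        config, instances, exec_plan, ws, breakpoint_task
    )
    statuses: dict[str, str] = {}
    lock = threading.Lock()
    halted = False
    for stage_idx, stage in enumerate(exec_plan.stages):
        if halted or (bp_stage is not None and stage_idx > bp_stage):
            break
        runnable, blocked = [], []
        for name in stage:
            preds = list(exec_graph.predecessors(name))
            if all(statuses.get(p) in ("done", "skipped") for p in preds):
                runnable.append(name)
            else:
                blocked.append(name)
        for name in blocked:
            statuses[name] = "blocked"
            report.tasks[name].status = "blocked"
        with ThreadPoolExecutor(max_workers=max(1, num_jobs)) as stage_pool:
            futs = {
                name: stage_pool.submit(
                    _run_instance, instances[name], ws, state, sample_id,
                    backend, throttle, lock,
                )
                for name in runnable
            }
            for name, fut in futs.items():
                result = fut.result()
                statuses[name] = result.status
                result.stage = stage_idx
                report.tasks[name] = result
        if halt_on_first_failure and any(
            statuses.get(n) == "failed" for n in runnable
        ):
            halted = True

    if any(r.status == "failed" for r in report.tasks.values()):
        report.status = "failed"
    elif bp_stage is not None and bp_stage < len(exec_plan.stages) - 1:
        report.status = "paused"
    (ws.root / "report.json").write_text(json.dumps(report.to_dict(), indent=2))
    return report


def _breakpoint_stage(config, instances, exec_plan, ws, breakpoint_task):
    """Earliest stage to pause after, or None when no breakpoint is active.

    A breakpoint is active only while its task still has work to do: once
    the task carries a valid sentinel (i.e. a previous invocation got
    past it), subsequent invocations run through it.
    """
    bp_tasks = {
        t for t, section in config.tasks.items() if section.run.breakpoint
    }
    if breakpoint_task is not None:
        bp_tasks.add(breakpoint_task)
    stages = []
    for task in bp_tasks:
        # an expanded task pauses after its merge completes
        name = task if task in instances else f"{task}.merge"
        if name not in instances:
            raise ExecutionError(f"breakpoint task {task!r} not in workflow")
        if _sentinel_matches(ws, instances[name]):
            continue
        stages.append(exec_plan.stage_of(name))
    return min(stages) if stages else None


def _sentinel_matches(ws: Workspace, inst: TaskInstance) -> bool:
    path = ws.sentinels_dir / f"{inst.name}.json"
    if not path.is_file():
        return False
    try:
        record = json.loads(path.read_text())
    except json.JSONDecodeError:
        return False
    return record.get("status") == "done" and record.get("command_hash") == inst.hash


def _run_instance(
    inst: TaskInstance, ws: Workspace, state: RunState, sample_id: str,
    backend, throttle, lock,
) -> TaskResult:
    result = TaskResult(name=inst.name, status="not_run", stage=0)
    if _sentinel_matches(ws, inst):
        result.status = "skipped"
        return result

    script = ws.scripts_dir / f"{inst.name}.sh"
    with lock:
        script.write_text(_SCRIPT_HEADER + inst.command + "\n")
        script.chmod(0o755)
        for d in inst.output_dirs:
            Path(d).mkdir(parents=True, exist_ok=True)
    stdout = ws.logs_dir / f"{inst.name}.out"
    stderr = ws.logs_dir / f"{inst.name}.err"

    with throttle:
        result.started_at = time.time()
        handle = backend.submit(script, inst.resources, stdout, stderr)
        rc = backend.wait(handle)
        result.finished_at = time.time()
    result.exit_code = rc
    if rc == 0:
        sentinel = ws.sentinels_dir / f"{inst.name}.json"
        sentinel.write_text(json.dumps({
            "task": inst.name,
            "command_hash": inst.hash,
            "status": "done",
            "finished_at": datetime.now(timezone.utc).isoformat(),
        }, indent=2))
        result.status = "done"
    else:
        result.status = "failed"
    return result


def raise_on_failure(report: RunReport) -> RunReport:
    """Convenience: turn a failed report into an :class:`ExecutionError`."""
    if report.status == "failed":
        raise ExecutionError(
            "workflow failed; failed tasks: " + ", ".join(report.failed_tasks)
        )
    return report
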