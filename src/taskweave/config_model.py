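"""The YAML workflow-configuration language.

A workflow is described entirely by one YAML document with five kinds of
top-level sections:

``GENERAL``
    System-specific settings (paths, default resources) — editing these is
    how a workflow moves between machines.
``PIPELINE_INFO``
    Name / version / author metadata for the workflow.
``SHARED``
    Workflow-wide inputs and arguments, cited by tasks as
    ``('__SHARED__', 'key')``.
``SAMPLES``
    Zero or more named parameter sets.  Each entry produces one concrete
    sub-workflow (a parameter sweep); tasks cite per-sample values as
    ``('__SAMPLES__', 'key')``.
``TASK_*``
    One section per task, instantiating a component with concrete
    parameters, run options and dependencies.  A task input is wired to
    another task's output with an *IO-connection*: a
    ``('TASK_NAME', 'param')`` pair, accepted both as the quoted-tuple
    string and as a two-element YAML flow list.

This module parses, validates, templates and transforms that language; it
never executes anything.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping

import yaml

from .errors import ConfigParseError, ConfigValidationError, KeywordError

RESERVED_SECTIONS = ("GENERAL", "PIPELINE_INFO", "SHARED", "SAMPLES")

#: Task section names: TASK_1, TASK_ALIGN, __TASK_1__, ...
TASK_NAME_RE = re.compile(r"_{0,2}TASK_\w+")

#: The quoted-tuple IO-connection form, exactly two quoted elements.
_TUPLE_RE = re.compile(
    r"""^\(\s*(['"])(?P<task>[^'"]+)\1\s*,\s*(['"])(?P<param>[^'"]+)\3\s*\)$"""
)

SHARED_SOURCE = "__SHARED__"
SAMPLES_SOURCE = "__SAMPLES__"

#: Placeholder emitted by templates for parameters the user must fill in.
REQUIRED_PLACEHOLDER = "__REQUIRED__"


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class IOConnection:
    """Wires one task's input parameter to another task's output parameter.

    ``source_task`` may also be the pseudo-sources ``__SHARED__`` or
    ``__SAMPLES__``, in which case ``source_param`` names a key of that
    section instead of a parameter.
    """

    source_task: str
    source_param: str

    @property
    def is_shared(self) -> bool:
        return self.source_task == SHARED_SOURCE

    @property
    def is_sample(self) -> bool:
        return self.source_task == SAMPLES_SOURCE

    @property
    def is_task(self) -> bool:
        return not (self.is_shared or self.is_sample)

    def as_literal(self) -> str:
        return f"('{self.source_task}', '{self.source_param}')"


@dataclass
class RunOptions:
    """Per-task execution options."""

    use_cluster: bool = False
    memory: str | None = None
    num_cpus: int | None = None
    parallel_run: bool = False
    interval_source: str | None = None
    num_chunks: int | None = None
    boilerplate: str | None = None
    breakpoint: bool = False

    _FIELDS = (
        "use_cluster", "memory", "num_cpus", "parallel_run",
        "interval_source", "num_chunks", "boilerplate", "breakpoint",
    )


@dataclass
class TaskSection:
    """One TASK_* section: a component instantiated with parameters."""

    name: str
    component_name: str
    params: dict[str, Any] = field(default_factory=dict)
    run: RunOptions = field(default_factory=RunOptions)
    forced_dependencies: list[str] = field(default_factory=list)
    output_dir_name: str | None = None

    def connections(self) -> list[tuple[str, IOConnection]]:
        """All (param, connection) pairs, flattening fan-in lists."""
        out: list[tuple[str, IOConnection]] = []
        for pname, value in self.params.items():
            if isinstance(value, IOConnection):
                out.append((pname, value))
            elif isinstance(value, list):
                out.extend(
                    (pname, v) for v in value if isinstance(v, IOConnection)
                )
        return out


@dataclass
class WorkflowConfig:
    """Parsed configuration: the in-memory form of the YAML document."""

    general: dict[str, Any] = field(default_factory=dict)
    pipeline_info: dict[str, Any] = field(default_factory=dict)
    shared: dict[str, Any] = field(default_factory=dict)
    samples: dict[str, dict[str, Any]] = field(default_factory=dict)
    tasks: dict[str, TaskSection] = field(default_factory=dict)

    @property
    def name(self) -> str:
        return str(self.pipeline_info.get("name", "workflow"))


@dataclass(frozen=True)
class KeywordContext:
    """Runtime values substituted for ``$TOKEN`` keywords in the config."""

    run_id: str
    workflow_name: str
    sample_id: str
    task_name: str

    def mapping(self) -> dict[str, str]:
        return {
            "RUN_ID": self.run_id,
            "WORKFLOW_NAME": self.workflow_name,
            "SAMPLE_ID": self.sample_id,
            "TASK_NAME": self.task_name,
        }


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: ``severity: location: message``."""

    severity: str  # "error" | "warning"
    location: str
    message: str

    def __str__(self) -> str:
        return f"{self.severity}: {self.location}: {self.message}"


def errors_only(diagnostics: Iterable[Diagnostic]) -> list[Diagnostic]:
    return [d for d in diagnostics if d.severity == "error"]


# --------------------------------------------------------------------------
# IO-connection literal recognition
# --------------------------------------------------------------------------

def parse_connection_literal(value: Any) -> IOConnection | None:
    """Recognize one IO-connection literal, else return None.

    Accepted forms: the quoted-tuple string ``('TASK', 'param')`` and a
    two-element YAML list whose first element looks like a task name or a
    pseudo-source.  One- and three-element tuple strings are plain strings.
    """
    if isinstance(value, str):
        m = _TUPLE_RE.match(value.strip())
        if m:
            return IOConnection(m.group("task"), m.group("param"))
        return None
    if isinstance(value, list) and len(value) == 2:
        first, second = value
        if (
            isinstance(first, str)
            and isinstance(second, str)
            and (
                TASK_NAME_RE.fullmatch(first)
                or first in (SHARED_SOURCE, SAMPLES_SOURCE)
            )
        ):
            return IOConnection(first, second)
    return None


def _normalize_param_value(value: Any) -> Any:
    conn = parse_connection_literal(value)
    if conn is not None:
        return conn
    if isinstance(value, list):
        # Fan-in: a list value may mix connections and literals.
        elems = [parse_connection_literal(v) for v in value]
        if any(e is not None for e in elems):
            return [e if e is not None else v for e, v in zip(elems, value)]
    return value


# --------------------------------------------------------------------------
# parsing
# --------------------------------------------------------------------------

def parse_config(yaml_text: str) -> WorkflowConfig:
    """Parse configuration YAML into a :class:`WorkflowConfig`.

    Section order is preserved; IO-connection literals are normalized to
    :class:`IOConnection`.  Raises :class:`ConfigParseError` on malformed
    YAML and :class:`ConfigValidationError` on unknown top-level sections
    or structurally broken task sections.
    """
    try:
        doc = yaml.safe_load(yaml_text)
    except yaml.YAMLError as exc:  # report the line if the parser knows it
        mark = getattr(exc, "problem_mark", None)
        line = mark.line + 1 if mark is not None else None
        raise ConfigParseError(str(getattr(exc, "problem", exc)), line) from exc
    if doc is None:
        doc = {}
    if not isinstance(doc, Mapping):
        raise ConfigParseError("top level of the configuration must be a mapping")

    config = WorkflowConfig()
    diags: list[Diagnostic] = []
    for section, body in doc.items():
        key = str(section)
        if key == "GENERAL":
            config.general = dict(body or {})
        elif key == "PIPELINE_INFO":
            config.pipeline_info = dict(body or {})
        elif key == "SHARED":
            config.shared = dict(body or {})
        elif key == "SAMPLES":
            config.samples = {
                str(sid): dict(params or {})
                for sid, params in dict(body or {}).items()
            }
        elif TASK_NAME_RE.fullmatch(key):
            config.tasks[key] = _parse_task_section(key, body or {}, diags)
        else:
            diags.append(Diagnostic(
                "error", key,
                f"unknown top-level section {key!r}; expected "
                f"{', '.join(RESERVED_SECTIONS)} or a TASK_* section",
            ))
    if errors_only(diags):
        raise ConfigValidationError(errors_only(diags))
    return config


def _parse_task_section(name: str, body: Any, diags: list[Diagnostic]) -> TaskSection:
    if not isinstance(body, Mapping):
        diags.append(Diagnostic("error", name, "task section must be a mapping"))
        return TaskSection(name=name, component_name="")
    component = body.get("component")
    if not component:
        diags.append(Diagnostic("error", name, "missing 'component' key"))
    run = RunOptions()
    run_body = body.get("run") or {}
    if not isinstance(run_body, Mapping):
        diags.append(Diagnostic("error", f"{name}.run", "run options must be a mapping"))
        run_body = {}
    for key, value in run_body.items():
        if key in RunOptions._FIELDS:
            setattr(run, key, value)
        else:
            diags.append(Diagnostic(
                "warning", f"{name}.run", f"unknown run option {key!r} ignored"
            ))
    params_body = body.get("params") or {}
    params = {
        str(p): _normalize_param_value(v) for p, v in dict(params_body).items()
    }
    forced = body.get("forced_dependencies") or []
    if isinstance(forced, str):
        forced = [forced]
    known = {"component", "run", "params", "forced_dependencies", "output_dir_name"}
    for key in body:
        if key not in known:
            diags.append(Diagnostic(
                "warning", name, f"unknown task key {key!r} ignored"
            ))
    return TaskSection(
        name=name,
        component_name=str(component or ""),
        params=params,
        run=run,
        forced_dependencies=[str(t) for t in forced],
        output_dir_name=body.get("output_dir_name"),
    )


# --------------------------------------------------------------------------
# serialization (used by templates and by the compiler's frozen sub-configs)
# --------------------------------------------------------------------------

def _param_value_to_yaml(value: Any) -> Any:
    if isinstance(value, IOConnection):
        return value.as_literal()
    if isinstance(value, list):
        return [_param_value_to_yaml(v) for v in value]
    return value


def dump_config(config: WorkflowConfig) -> str:
    """Serialize a WorkflowConfig back to YAML (IO-connections as tuples)."""
    doc: dict[str, Any] = {
        "GENERAL": config.general,
        "PIPELINE_INFO": config.pipeline_info,
        "SHARED": config.shared,
        "SAMPLES": config.samples,
    }
    for tname, task in config.tasks.items():
        run = {
            f: getattr(task.run, f)
            for f in RunOptions._FIELDS
            if getattr(task.run, f) != getattr(RunOptions(), f)
        }
        section: dict[str, Any] = {"component": task.component_name}
        if run:
            section["run"] = run
        if task.forced_dependencies:
            section["forced_dependencies"] = list(task.forced_dependencies)
        if task.output_dir_name is not None:
            section["output_dir_name"] = task.output_dir_name
        section["params"] = {
            p: _param_value_to_yaml(v) for p, v in task.params.items()
        }
        doc[tname] = section
    return yaml.safe_dump(doc, sort_keys=False, default_flow_style=False)


def make_config_template(components) -> str:
    """Emit a configuration template for an ordered component list.

    One TASK_<i> section per component, parameters prefilled with declared
    defaults or the ``__REQUIRED__`` placeholder.  The emitted text
    re-parses into a config with exactly ``len(components)`` tasks.
    """
    components = list(components)
    if not components:
        raise ValueError("component list must be non-empty")
    config = WorkflowConfig(
        general={"temp_dir": "./tmp"},
        pipeline_info={"name": "workflow", "version": "1.0", "author": ""},
    )
    for i, comp in enumerate(components, start=1):
        params: dict[str, Any] = {}
        for spec in comp.params:
            if spec.default is not None:
                params[spec.name] = spec.default
            elif spec.required:
                params[spec.name] = REQUIRED_PLACEHOLDER
            else:
                params[spec.name] = None
        config.tasks[f"TASK_{i}"] = TaskSection(
            name=f"TASK_{i}",
            component_name=comp.name,
            params=params,
            run=RunOptions(
                memory=comp.requirements.memory,
                num_cpus=comp.requirements.num_cpus,
            ),
        )
    return dump_config(config)


# --------------------------------------------------------------------------
# validation
# --------------------------------------------------------------------------

def validate_config(config: WorkflowConfig, registry=None) -> list[Diagnostic]:
    """Validate a parsed configuration; an empty error set means compilable.

    Checks dangling IO-connections, unknown components and parameters,
    self- and cyclic dependencies, ragged sample sweeps, unfilled template
    placeholders, and nonsensical resource requests.  ``registry`` is an
    optional component registry used for component-level checks.
    """
    diags: list[Diagnostic] = []
    task_names = set(config.tasks)

    sample_key_sets = {sid: set(params) for sid, params in config.samples.items()}
    if sample_key_sets:
        all_keys = set().union(*sample_key_sets.values())
        for sid, keys in sample_key_sets.items():
            missing = all_keys - keys
            if missing:
                diags.append(Diagnostic(
                    "error", f"SAMPLES.{sid}",
                    "ragged sweep: missing key(s) "
                    + ", ".join(sorted(missing)),
                ))
    referenced_sample_keys: set[str] = set()

    components = {}
    for tname, task in config.tasks.items():
        comp = None
        if registry is not None and task.component_name:
            try:
                comp = registry.get(task.component_name)
            except Exception as exc:
                diags.append(Diagnostic("error", tname, str(exc)))
        components[tname] = comp

    for tname, task in config.tasks.items():
        comp = components[tname]
        if comp is not None:
            declared = {p.name for p in comp.params}
            for pname in task.params:
                if pname not in declared:
                    diags.append(Diagnostic(
                        "error", f"{tname}.{pname}",
                        f"component {comp.name!r} declares no parameter "
                        f"{pname!r}",
                    ))
            for spec in comp.params:
                if (
                    spec.required
                    and spec.default is None
                    and task.params.get(spec.name) is None
                ):
                    diags.append(Diagnostic(
                        "error", f"{tname}.{spec.name}",
                        "required parameter has no value",
                    ))
            if task.run.parallel_run and comp.parallelization is None:
                diags.append(Diagnostic(
                    "error", tname,
                    f"parallel_run requested but component {comp.name!r} "
                    "declares no parallelization contract",
                ))
        for pname, conn in task.connections():
            loc = f"{tname}.{pname}"
            if conn.is_shared:
                if conn.source_param not in config.shared:
                    diags.append(Diagnostic(
                        "error", loc,
                        f"SHARED has no key {conn.source_param!r}",
                    ))
            elif conn.is_sample:
                referenced_sample_keys.add(conn.source_param)
                for sid, keys in sample_key_sets.items():
                    if conn.source_param not in keys:
                        diags.append(Diagnostic(
                            "error", loc,
                            f"sample {sid!r} has no key "
                            f"{conn.source_param!r}",
                        ))
            else:
                if conn.source_task == tname:
                    diags.append(Diagnostic(
                        "error", loc, "self-connection: a task cannot "
                        "consume its own output",
                    ))
                elif conn.source_task not in task_names:
                    diags.append(Diagnostic(
                        "error", loc,
                        f"IO-connection references unknown task "
                        f"{conn.source_task!r}",
                    ))
                else:
                    src_comp = components[conn.source_task]
                    if src_comp is not None and conn.source_param not in {
                        p.name for p in src_comp.params
                    }:
                        diags.append(Diagnostic(
                            "error", loc,
                            f"task {conn.source_task!r} (component "
                            f"{src_comp.name!r}) has no parameter "
                            f"{conn.source_param!r}",
                        ))
        for dep in task.forced_dependencies:
            if dep == tname:
                diags.append(Diagnostic(
                    "error", tname, "self-dependency in forced_dependencies"
                ))
            elif dep not in task_names:
                diags.append(Diagnostic(
                    "error", tname,
                    f"forced dependency on unknown task {dep!r}",
                ))
        if task.run.num_cpus is not None and task.run.num_cpus <= 0:
            diags.append(Diagnostic("error", tname, "num_cpus must be positive"))
        if task.run.memory is not None and not re.fullmatch(
            r"\d+(\.\d+)?[KMGTkmgt]?B?", str(task.run.memory)
        ):
            diags.append(Diagnostic(
                "error", tname, f"unparseable memory request "
                f"{task.run.memory!r}",
            ))
        for pname, value in task.params.items():
            if value == REQUIRED_PLACEHOLDER:
                diags.append(Diagnostic(
                    "error", f"{tname}.{pname}",
                    "unfilled required placeholder",
                ))

    for key in set().union(*sample_key_sets.values()) if sample_key_sets else set():
        if key not in referenced_sample_keys:
            diags.append(Diagnostic(
                "warning", f"SAMPLES.{key}",
                "sample key referenced by no task",
            ))

    diags.extend(_cycle_diagnostics(config))
    return diags


def _cycle_diagnostics(config: WorkflowConfig) -> list[Diagnostic]:
    import networkx as nx

    g = nx.DiGraph()
    g.add_nodes_from(config.tasks)
    for tname, task in config.tasks.items():
        for _, conn in task.connections():
            # self-connections are reported separately, not as cycles
            if (conn.is_task and conn.source_task in config.tasks
                    and conn.source_task != tname):
                g.add_edge(conn.source_task, tname)
        for dep in task.forced_dependencies:
            if dep in config.tasks and dep != tname:
                g.add_edge(dep, tname)
    try:
        cycle = nx.find_cycle(g)
    except nx.NetworkXNoCycle:
        return []
    path = [u for u, _ in cycle] + [cycle[-1][1]]
    return [Diagnostic(
        "error", path[0], "dependency cycle: " + " -> ".join(path)
    )]


# --------------------------------------------------------------------------
# transformations
# --------------------------------------------------------------------------

def expand_samples(config: WorkflowConfig) -> list[tuple[str, WorkflowConfig]]:
    """Expand the SAMPLES sweep into concrete per-sample configurations.

    Every ``__SHARED__`` and ``__SAMPLES__`` reference is substituted with
    its value, so each returned config contains only literals and
    task-to-task IO-connections.  An empty SAMPLES section yields a single
    ``("run", config)`` pair.  Task structure is identical across outputs.
    """
    sample_items = list(config.samples.items()) or [("run", {})]
    out: list[tuple[str, WorkflowConfig]] = []
    for sample_id, sample_params in sample_items:
        concrete = WorkflowConfig(
            general=copy.deepcopy(config.general),
            pipeline_info=copy.deepcopy(config.pipeline_info),
            shared=copy.deepcopy(config.shared),
            samples={},
        )
        for tname, task in config.tasks.items():
            new_task = copy.deepcopy(task)
            new_task.params = {
                p: _resolve_pseudo(v, config.shared, sample_params, f"{tname}.{p}")
                for p, v in task.params.items()
            }
            concrete.tasks[tname] = new_task
        out.append((sample_id, concrete))
    return out


def _resolve_pseudo(value, shared, sample_params, loc):
    if isinstance(value, IOConnection):
        if value.is_shared:
            if value.source_param not in shared:
                raise ConfigValidationError([Diagnostic(
                    "error", loc, f"SHARED has no key {value.source_param!r}"
                )])
            return shared[value.source_param]
        if value.is_sample:
            if value.source_param not in sample_params:
                raise ConfigValidationError([Diagnostic(
                    "error", loc,
                    f"sample has no key {value.source_param!r}",
                )])
            return sample_params[value.source_param]
        return value
    if isinstance(value, list):
        return [_resolve_pseudo(v, shared, sample_params, loc) for v in value]
    return value


_KEYWORD_RE = re.compile(r"\$\$|\$[A-Za-z_][A-Za-z0-9_]*")


def interpolate_keywords(template: str, ctx: KeywordContext) -> str:
    """Replace ``$RUN_ID``/``$SAMPLE_ID``/``$WORKFLOW_NAME``/``$TASK_NAME``.

    ``$$`` escapes a literal dollar sign.  Any other ``$TOKEN`` is an
    error — silent pass-through would hide typos in path templates.
    Idempotent on strings without ``$``.
    """
    mapping = ctx.mapping()

    def repl(m: re.Match) -> str:
        tok = m.group(0)
        if tok == "$$":
            return "$"
        name = tok[1:]
        if name not in mapping:
            raise KeywordError(
                f"unknown keyword ${name} in {template!r}; known keywords: "
                + ", ".join("$" + k for k in mapping)
            )
        value = mapping[name]
        if not value:
            raise KeywordError(f"keyword ${name} has no value at interpolation time")
        return value

    return _KEYWORD_RE.sub(repl, template)
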