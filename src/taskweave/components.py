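"""Components: reusable wrappers around command-line tools.

A component is a directory with a standard layout::

    <name>/
        component.yaml   declarative definition (this module's schema)
        wrapper          thin executable entry point for manual runs
        seed/            the wrapped tool's source or a link to it
        README.md
        tests/

The definition file declares the wrapped command, its parameters and
their IO roles, resource requirements, and — for scatter-gather capable
tools — a parallelization contract (which parameter receives the chunk
and how chunk outputs are merged back together).  Wrappers and seeds may
be written in any language; the engine only ever builds and runs shell
command strings.
"""

from __future__ import annotations

import hashlib
import re
import shlex
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import (
    ComponentLoadError,
    ComponentNotFoundError,
    MissingParameterError,
)

DEFINITION_FILENAME = "component.yaml"

PARAM_ROLES = ("input_file", "output_file", "argument", "flag")
MERGE_STRATEGIES = ("concat", "concat_skip_header", "merge_command")

_IDENT_RE = re.compile(r"[A-Za-z_]\w*")


@dataclass(frozen=True)
class ParamSpec:
    """One declared parameter of a component."""

    name: str
    role: str = "argument"
    required: bool = False
    default: object | None = None


@dataclass(frozen=True)
class Requirements:
    memory: str = "1G"
    num_cpus: int = 1


@dataclass(frozen=True)
class Parallelization:
    """Scatter-gather contract of a parallelizable component.

    ``split_param`` names the parameter that receives one chunk token
    (a genomic region ``chrom:start-end`` or a generic shard id);
    ``merge_strategy`` says how per-chunk outputs combine into the output
    a serial run would have produced.  ``merge_command`` is a shell
    template with ``{inputs}`` and ``{output}`` placeholders, used only
    when the strategy is ``merge_command``.
    """

    split_param: str
    merge_strategy: str = "concat"
    merge_command: str | None = None


@dataclass
class ComponentDefinition:
    """Declarative description of one wrapped command-line tool."""

    name: str
    seed_command: str
    version: str = "0.1.0"
    params: list[ParamSpec] = field(default_factory=list)
    requirements: Requirements = field(default_factory=Requirements)
    parallelization: Parallelization | None = None
    root_dir: Path | None = None

    def param(self, name: str) -> ParamSpec:
        for p in self.params:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def output_params(self) -> list[ParamSpec]:
        return [p for p in self.params if p.role == "output_file"]

    def to_dict(self) -> dict:
        doc: dict = {
            "name": self.name,
            "version": self.version,
            "seed_command": self.seed_command,
            "params": [
                {
                    "name": p.name,
                    "role": p.role,
                    "required": p.required,
                    **({"default": p.default} if p.default is not None else {}),
                }
                for p in self.params
            ],
            "requirements": {
                "memory": self.requirements.memory,
                "num_cpus": self.requirements.num_cpus,
            },
        }
        if self.parallelization is not None:
            par = {
                "split_param": self.parallelization.split_param,
                "merge_strategy": self.parallelization.merge_strategy,
            }
            if self.parallelization.merge_command is not None:
                par["merge_command"] = self.parallelization.merge_command
            doc["parallelization"] = par
        return doc

    def dump(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)


@dataclass(frozen=True)
class ComponentScaffold:
    """Paths created by :func:`make_component_template`."""

    root_dir: Path
    definition_file: Path
    wrapper_file: Path
    seed_dir: Path
    readme: Path
    tests_dir: Path


# --------------------------------------------------------------------------
# scaffolding
# --------------------------------------------------------------------------

_WRAPPER_STUB = """\
#!/usr/bin/env bash
# Thin entry point for running this component's seed by hand.
# The workflow engine builds the command from component.yaml instead.
set -euo pipefail
exec "$@"
"""

_README_STUB = """\
# {name}

Describe what this component's wrapped tool does, its inputs and outputs.
"""

_TEST_STUB = """\
# Add tests for the {name} component here.
"""


def make_component_template(name: str, dest: Path) -> ComponentScaffold:
    """Scaffold a fresh component directory under ``dest``.

    Refuses to clobber an existing directory.  The emitted definition file
    parses (with zero parameters) so a scaffold is immediately loadable.
    """
    if not _IDENT_RE.fullmatch(name):
        raise ComponentLoadError(
            f"component name {name!r} is not a valid identifier"
        )
    dest = Path(dest)
    root = dest / name
    if root.exists():
        raise ComponentLoadError(f"refusing to overwrite existing {root}")
    seed_dir = root / "seed"
    tests_dir = root / "tests"
    for d in (root, seed_dir, tests_dir):
        d.mkdir(parents=True)
    definition = ComponentDefinition(
        name=name, seed_command=f"python {{seed_dir}}/main.py"
    )
    (root / DEFINITION_FILENAME).write_text(definition.dump())
    wrapper = root / "wrapper"
    wrapper.write_text(_WRAPPER_STUB)
    wrapper.chmod(0o755)
    (root / "README.md").write_text(_README_STUB.format(name=name))
    (tests_dir / f"test_{name}.py").write_text(_TEST_STUB.format(name=name))
    return ComponentScaffold(
        root_dir=root,
        definition_file=root / DEFINITION_FILENAME,
        wrapper_file=wrapper,
        seed_dir=seed_dir,
        readme=root / "README.md",
        tests_dir=tests_dir,
    )


# --------------------------------------------------------------------------
# loading
# --------------------------------------------------------------------------

def load_component(path: Path) -> ComponentDefinition:
    """Load and validate a component directory's definition file."""
    path = Path(path)
    def_file = path / DEFINITION_FILENAME
    if not def_file.is_file():
        raise ComponentLoadError(f"no {DEFINITION_FILENAME} in {path}")
    try:
        doc = yaml.safe_load(def_file.read_text())
    except yaml.YAMLError as exc:
        raise ComponentLoadError(f"{def_file}: invalid YAML: {exc}") from exc
    if not isinstance(doc, dict):
        raise ComponentLoadError(f"{def_file}: definition must be a mapping")

    problems: list[str] = []
    name = doc.get("name")
    if not name or not _IDENT_RE.fullmatch(str(name)):
        problems.append(f"name: missing or invalid ({name!r})")
    seed_command = doc.get("seed_command")
    if not seed_command:
        problems.append("seed_command: missing")

    params: list[ParamSpec] = []
    seen: set[str] = set()
    for i, entry in enumerate(doc.get("params") or []):
        if not isinstance(entry, dict) or "name" not in entry:
            problems.append(f"params[{i}]: each entry needs a 'name'")
            continue
        pname = str(entry["name"])
        if pname in seen:
            problems.append(f"params: duplicated parameter name {pname!r}")
        seen.add(pname)
        role = entry.get("role", "argument")
        if role not in PARAM_ROLES:
            problems.append(
                f"params.{pname}: unknown role {role!r} "
                f"(expected one of {', '.join(PARAM_ROLES)})"
            )
        params.append(ParamSpec(
            name=pname,
            role=role,
            required=bool(entry.get("required", False)),
            default=entry.get("default"),
        ))

    req_doc = doc.get("requirements") or {}
    requirements = Requirements(
        memory=str(req_doc.get("memory", "1G")),
        num_cpus=int(req_doc.get("num_cpus", 1)),
    )
    if requirements.num_cpus <= 0:
        problems.append("requirements.num_cpus: must be positive")

    parallelization = None
    par_doc = doc.get("parallelization")
    if par_doc is not None:
        split_param = par_doc.get("split_param")
        strategy = par_doc.get("merge_strategy")
        if not split_param:
            problems.append("parallelization.split_param: missing")
        elif split_param not in seen:
            problems.append(
                f"parallelization.split_param: {split_param!r} is not a "
                "declared parameter"
            )
        if strategy not in MERGE_STRATEGIES:
            problems.append(
                f"parallelization.merge_strategy: {strategy!r} not one of "
                + ", ".join(MERGE_STRATEGIES)
            )
        if strategy == "merge_command" and not par_doc.get("merge_command"):
            problems.append(
                "parallelization.merge_command: required for the "
                "merge_command strategy"
            )
        if not problems:
            parallelization = Parallelization(
                split_param=str(split_param),
                merge_strategy=str(strategy),
                merge_command=par_doc.get("merge_command"),
            )
    elif doc.get("merge_strategy") is not None:
        problems.append(
            "merge_strategy given without a parallelization block"
        )

    if problems:
        raise ComponentLoadError(
            f"{def_file}: invalid definition:\n  " + "\n  ".join(problems)
        )
    return ComponentDefinition(
        name=str(name),
        seed_command=str(seed_command),
        version=str(doc.get("version", "0.1.0")),
        params=params,
        requirements=requirements,
        parallelization=parallelization,
        root_dir=path,
    )


def definition_hash(path: Path) -> str:
    """sha256 of a component's definition file (provenance guard)."""
    return hashlib.sha256(
        (Path(path) / DEFINITION_FILENAME).read_bytes()
    ).hexdigest()


class ComponentRegistry:
    """Resolves component names against an ordered search path."""

    def __init__(self, search_paths):
        self.search_paths = [Path(p) for p in search_paths]
        self._cache: dict[str, ComponentDefinition] = {}

    @classmethod
    def from_dir(cls, path: Path) -> "ComponentRegistry":
        return cls([path])

    def resolve_dir(self, name: str) -> Path:
        for base in self.search_paths:
            candidate = base / name
            if (candidate / DEFINITION_FILENAME).is_file():
                return candidate
        raise ComponentNotFoundError(
            f"component {name!r} not found; searched: "
            + ", ".join(str(p) for p in self.search_paths)
        )

    def get(self, name: str) -> ComponentDefinition:
        if name not in self._cache:
            self._cache[name] = load_component(self.resolve_dir(name))
        return self._cache[name]

    def names(self) -> list[str]:
        found = []
        for base in self.search_paths:
            if base.is_dir():
                for child in sorted(base.iterdir()):
                    if (child / DEFINITION_FILENAME).is_file():
                        found.append(child.name)
        return found


# --------------------------------------------------------------------------
# command rendering
# --------------------------------------------------------------------------

def build_command(
    comp: ComponentDefinition,
    values: dict,
    boilerplate: str | None = None,
) -> str:
    """Render the shell command for one invocation of a component.

    A pure function of its inputs: the seed command (with ``{seed_dir}``
    and any ``{param}`` placeholders substituted) followed by ``--name
    value`` pairs in declaration order; flags appear only when truthy;
    list values join with commas.  A boilerplate fragment, when given, is
    prepended with ``&&`` so its failure aborts the task.
    """
    resolved = dict(values)
    for spec in comp.params:
        if spec.name not in resolved and spec.default is not None:
            resolved[spec.name] = spec.default
    missing = [
        p.name for p in comp.params
        if p.required and resolved.get(p.name) is None
    ]
    if missing:
        raise MissingParameterError(
            f"component {comp.name!r}: missing required parameter(s): "
            + ", ".join(missing)
        )

    cmd = comp.seed_command
    if "{seed_dir}" in cmd:
        if comp.root_dir is None:
            raise ComponentLoadError(
                f"component {comp.name!r} uses {{seed_dir}} but has no "
                "directory on disk"
            )
        cmd = cmd.replace("{seed_dir}", str(Path(comp.root_dir) / "seed"))

    inline: set[str] = set()
    for spec in comp.params:
        placeholder = "{" + spec.name + "}"
        if placeholder in cmd:
            cmd = cmd.replace(placeholder, _render_value(resolved.get(spec.name)))
            inline.add(spec.name)

    parts = [cmd]
    for spec in comp.params:
        if spec.name in inline:
            continue
        value = resolved.get(spec.name)
        if value is None:
            continue
        if spec.role == "flag":
            if value:
                parts.append(f"--{spec.name}")
        else:
            parts.append(f"--{spec.name} {_render_value(value)}")
    command = " ".join(parts)
    if boilerplate:
        command = f"{boilerplate} && {command}"
    return command


def _render_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, list):
        return shlex.quote(",".join(str(v) for v in value))
    return shlex.quote(str(value))
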