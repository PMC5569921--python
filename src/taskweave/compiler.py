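"""Freeze a configuration + component registry into a runnable artifact.

``init`` validates the configuration, expands the SAMPLES sweep into
per-sample concrete configurations, and writes a self-contained workflow
directory::

    <out_dir>/<name>/
        config.yaml            the exact configuration text, verbatim
        manifest.json          component name -> version, definition hash, path
        sub_workflows/<sid>.yaml   one concrete config per sample
        run_workflow           thin launcher invoking the engine

Compilation adds no semantics: compile-then-run equals
validate-build-plan-run on the same inputs.  The manifest hash guards
provenance — a run refuses to start if a component definition changed
since the workflow was frozen.  The artifact contains no timestamps, so
re-initializing the same inputs is bit-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from .components import ComponentRegistry, definition_hash
from .config_model import (
    WorkflowConfig,
    dump_config,
    errors_only,
    expand_samples,
    parse_config,
    validate_config,
)
from .errors import InitError, ProvenanceError

MANIFEST_NAME = "manifest.json"
CONFIG_NAME = "config.yaml"
LAUNCHER_NAME = "run_workflow"

_LAUNCHER = """\
#!/bin/sh
# Launcher written at init time; runs this workflow with the engine.
exec taskweave run "$(CDPATH= cd -- "$(dirname -- "$0")" && pwd)" "$@"
"""


@dataclass
class CompiledWorkflow:
    """A frozen, runnable workflow."""

    workflow_name: str
    root: Path
    frozen_config: str
    config: WorkflowConfig
    sub_workflows: dict[str, WorkflowConfig]
    manifest: dict
    registry: ComponentRegistry = field(repr=False, default=None)


def init_workflow(
    config_text: str,
    registry: ComponentRegistry,
    out_dir: Path,
    name: str,
) -> CompiledWorkflow:
    """Compile configuration text into a workflow artifact directory.

    Validation failures abort with the full diagnostic list before
    anything is written.
    """
    config = parse_config(config_text)
    diagnostics = validate_config(config, registry)
    errors = errors_only(diagnostics)
    if errors:
        raise InitError(
            f"cannot initialize {name!r}:\n"
            + "\n".join(str(d) for d in errors)
        )

    sub = dict(expand_samples(config))
    manifest = {
        "workflow_name": name,
        "samples": list(sub),
        "components": {
            task.component_name: {
                "version": registry.get(task.component_name).version,
                "definition_sha256": definition_hash(
                    registry.resolve_dir(task.component_name)
                ),
                "path": str(registry.resolve_dir(task.component_name)),
            }
            for task in config.tasks.values()
        },
    }

    root = Path(out_dir) / name
    root.mkdir(parents=True, exist_ok=True)
    (root / CONFIG_NAME).write_text(config_text)
    (root / MANIFEST_NAME).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    sub_dir = root / "sub_workflows"
    sub_dir.mkdir(exist_ok=True)
    for sid, concrete in sub.items():
        (sub_dir / f"{sid}.yaml").write_text(dump_config(concrete))
    launcher = root / LAUNCHER_NAME
    launcher.write_text(_LAUNCHER)
    launcher.chmod(0o755)

    return CompiledWorkflow(
        workflow_name=name,
        root=root,
        frozen_config=config_text,
        config=config,
        sub_workflows=sub,
        manifest=manifest,
        registry=registry,
    )


def load_compiled(root: Path, registry: ComponentRegistry | None = None) -> CompiledWorkflow:
    """Load a previously initialized workflow artifact.

    Re-resolves components (from the manifest's recorded paths unless a
    registry is supplied) and refuses to proceed if any component's
    definition hash no longer matches the frozen manifest.
    """
    root = Path(root)
    manifest_file = root / MANIFEST_NAME
    if not manifest_file.is_file():
        raise InitError(f"{root} is not a compiled workflow (no {MANIFEST_NAME})")
    manifest = json.loads(manifest_file.read_text())
    config_text = (root / CONFIG_NAME).read_text()
    config = parse_config(config_text)

    if registry is None:
        paths = {
            Path(entry["path"]).parent
            for entry in manifest["components"].values()
        }
        registry = ComponentRegistry(sorted(paths))
    for cname, entry in manifest["components"].items():
        current = definition_hash(registry.resolve_dir(cname))
        if current != entry["definition_sha256"]:
            raise ProvenanceError(
                f"component {cname!r} changed since this workflow was "
                f"frozen (definition hash mismatch); re-run init"
            )

    return CompiledWorkflow(
        workflow_name=manifest["workflow_name"],
        root=root,
        frozen_config=config_text,
        config=config,
        sub_workflows=dict(expand_samples(config)),
        manifest=manifest,
        registry=registry,
    )
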