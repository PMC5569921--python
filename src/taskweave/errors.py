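"""Exception hierarchy for the workflow assembler."""

from __future__ import annotations


class TaskweaveError(Exception):
    """Base class for all package errors."""


class ConfigParseError(TaskweaveError):
    """The configuration text is not syntactically valid YAML.

    Carries the 1-based line number of the offending construct when the
    YAML parser reports one.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ConfigValidationError(TaskweaveError):
    """A configuration failed validation; ``diagnostics`` holds the details."""

    def __init__(self, diagnostics):
        self.diagnostics = list(diagnostics)
        super().__init__(
            "configuration invalid:\n"
            + "\n".join(str(d) for d in self.diagnostics)
        )


class KeywordError(TaskweaveError):
    """An unknown ``$TOKEN`` was found during keyword interpolation."""


class ComponentError(TaskweaveError):
    """Base for component definition / scaffolding problems."""


class ComponentNotFoundError(ComponentError):
    """A component name could not be resolved in the search path."""


class ComponentLoadError(ComponentError):
    """A component definition file is missing or invalid."""


class MissingParameterError(ComponentError):
    """A required parameter had no value when building a command."""


class CycleError(TaskweaveError):
    """The task graph contains a cycle; ``path`` is one offending cycle."""

    def __init__(self, path):
        self.path = list(path)
        super().__init__("cycle detected: " + " -> ".join(self.path))


class InitError(TaskweaveError):
    """Workflow compilation (init) failed; nothing was written."""


class ProvenanceError(TaskweaveError):
    """A compiled workflow's component changed since it was frozen."""


class WorkspaceError(TaskweaveError):
    """Run workspace creation conflicted with an existing directory."""


class ExecutionError(TaskweaveError):
    """A workflow run finished with failed tasks."""
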