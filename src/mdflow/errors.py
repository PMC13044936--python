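"""Exception hierarchy for mdflow.

Every error raised by the library derives from :class:`MdflowError` so
callers (and the CLI) can distinguish workflow-definition problems from
genuine bugs.
"""


class MdflowError(Exception):
    """Base class for all mdflow errors."""


class ProjectError(MdflowError):
    """Project directory missing or not laid out as a workflow project."""


class WorkflowDefinitionError(MdflowError):
    """Invalid step registration: duplicate ids, unknown or cyclic deps."""


class TargetsError(MdflowError):
    """Malformed or invalid targets (sample sheet) content."""


class ToolDefinitionError(MdflowError):
    """CWL tool description outside the supported subset or malformed."""


class BindingError(MdflowError):
    """Command rendering failed: missing required inputs or bad placeholders."""


class TemplateGrammarError(MdflowError):
    """Malformed annotated command template."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class LiterateError(MdflowError):
    """Malformed literate workflow document."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message)
        self.line = line


class StateError(MdflowError):
    """Corrupt or unreadable run-state store."""


class RunPreconditionError(MdflowError):
    """Run request violates its preconditions (exit code 2 in the CLI)."""
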