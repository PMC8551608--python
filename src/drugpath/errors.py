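"""Exception hierarchy shared across the pipeline.

The CLI maps these onto distinct exit codes so batch drivers can triage
failures: configuration errors (2), snapshot schema errors (3), empty
results (4).
"""


class DrugPathError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DrugPathError):
    """Invalid or incomplete run/simulation configuration (exit code 2)."""


class SchemaError(DrugPathError):
    """A snapshot file does not match its documented schema (exit code 3)."""


class UnknownTissueError(ConfigurationError):
    """Requested tissue absent from the expression table."""

    def __init__(self, tissue: str, available: list[str]):
        self.tissue = tissue
        self.available = sorted(available)
        super().__init__(
            f"unknown tissue {tissue!r}; available tissues: {', '.join(self.available)}"
        )
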