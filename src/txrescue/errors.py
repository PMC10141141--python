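"""Exception hierarchy shared across the package.

Each class carries a distinct process exit code so the command-line
front end can signal the error class to shell callers.
"""


class TxRescueError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(TxRescueError, ValueError):
    """Invalid configuration (simulation, thresholds, run setup)."""

    exit_code = 2


class DataError(TxRescueError, ValueError):
    """Input data violates a contract (negative counts, missing groups, ...)."""

    exit_code = 3


class StageError(TxRescueError, RuntimeError):
    """A pipeline stage failed; records which stage and why."""

    exit_code = 4

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}' failed: {message}")
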