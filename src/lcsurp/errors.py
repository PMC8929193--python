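"""Exception types shared across the package."""


class LcsurpError(Exception):
    """Base class for all package errors."""


class FormatError(LcsurpError):
    """Malformed input file (treebank, rule file, response table)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class StateError(LcsurpError):
    """Transition applied to a store state that does not license it."""


class ConfigError(LcsurpError):
    """Invalid configuration (unknown operator, ablation id, version)."""


class DepthBoundError(LcsurpError):
    """A tree requires more derivation fragments than the store allows."""


class StateSpaceError(LcsurpError):
    """Exact enumeration would exceed the configured state budget."""


class GenerationError(LcsurpError):
    """Synthetic-grammar constraints are infeasible."""


class NumericalConsistencyError(LcsurpError):
    """Prefix probabilities increased, or a distribution failed to normalize."""


class AlignmentError(LcsurpError):
    """Token alignment between response data and surprisal table failed."""
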