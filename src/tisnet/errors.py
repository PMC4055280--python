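"""Exception types shared across the package."""


class TisnetError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(TisnetError):
    """Invalid configuration (bad mixture, threshold, unknown key, ...)."""


class ParseError(TisnetError):
    """A malformed input file; carries the 1-based line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class UnmappedSubpartError(TisnetError):
    """A tissue subpart missing from the consolidation scheme."""


class ExcludedGeneError(TisnetError):
    """A tissue-specific disease gene was passed to an op that ignores them."""


class PipelineError(TisnetError):
    """A pipeline stage failed; message names the stage and the cause."""
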