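"""Exception hierarchy shared by all pipeline stages.

``ParseError`` covers malformed input files, ``IntegrityError`` covers
inputs that parse but violate an invariant (duplicate IDs, overlapping
coverage intervals, unbalanced designs ...), and ``ConfigError`` covers
invalid configuration.  The CLI maps these to exit codes 3, 3 and 2.
"""


class FermstageError(Exception):
    """Base class for all errors raised by fermstage."""


class ParseError(FermstageError):
    """A file could not be parsed as the expected format."""


class IntegrityError(FermstageError):
    """Parsed data violates a structural invariant."""


class ConfigError(FermstageError):
    """Invalid or inconsistent configuration."""


class PipelineStageError(FermstageError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
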