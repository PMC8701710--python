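"""Exception hierarchy.

Every error raised by the package derives from :class:`EmrSqlError` so
callers can catch pipeline failures with a single except clause while the
concrete subclasses keep failure modes distinguishable (parse vs. execution
vs. decoding vs. data generation).
"""


class EmrSqlError(Exception):
    """Base class for all package errors."""


class SchemaError(EmrSqlError):
    """Malformed or inconsistent database schema definition."""


class LoadError(EmrSqlError):
    """Record content incompatible with the declared schema."""


class ExecutionError(EmrSqlError):
    """The SQL engine rejected a query.

    Evaluation treats this as a non-executable prediction rather than a
    crash, so execution accuracy can count it as a miss.
    """


class UnsupportedSyntaxError(EmrSqlError):
    """SQL text uses a construct outside the supported query subset."""


class MalformedSequenceError(EmrSqlError):
    """An action sequence is not grammar-consistent.

    ``position`` is the index of the offending action (or the sequence
    length when the sequence ended prematurely).
    """

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at action position {position})")
        self.position = position


class ValueNotFoundError(EmrSqlError):
    """A condition value does not occur as a contiguous question span."""


class JoinPathError(EmrSqlError):
    """Referenced tables cannot be connected through the join-key graph."""


class DecodingError(EmrSqlError):
    """Internal decoding-state inconsistency (empty admissible set)."""


class IncompleteOutputError(EmrSqlError):
    """Decoding hit the action-length cap before completing a tree."""


class GenerationError(EmrSqlError):
    """Synthetic corpus generation could not satisfy a template."""


class InputError(EmrSqlError):
    """Invalid user input to an evaluation or training entry point."""
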