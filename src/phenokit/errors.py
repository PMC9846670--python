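"""Exception hierarchy for phenokit.

All errors raised by the library derive from :class:`PhenokitError`, so
callers (and the CLI) can catch one type. The subtypes distinguish the
three failure modes of terminology plumbing: a file that cannot be parsed
(:class:`FormatError`), tables that parse but contradict each other
(:class:`IntegrityError`), and a query naming a concept the graph does not
contain (:class:`UnknownConceptError`).
"""


class PhenokitError(Exception):
    """Base class for all phenokit errors."""


class FormatError(PhenokitError):
    """A file or field does not conform to the expected format."""


class IntegrityError(PhenokitError):
    """Cross-table referential integrity or snapshot semantics violated."""


class UnknownConceptError(PhenokitError, KeyError):
    """A concept id was queried that is not a node of the graph."""

    def __str__(self) -> str:  # KeyError quotes its args; keep a plain message
        return Exception.__str__(self)


class EclParseError(PhenokitError):
    """Expression constraint text could not be parsed."""

    def __init__(self, message: str, position: int):
        super().__init__(f"{message} (at position {position})")
        self.position = position
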