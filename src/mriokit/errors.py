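"""Exception hierarchy shared across the toolkit.

All user-facing failures derive from :class:`MrioError` so the CLI can map
them onto a single exit code; anything else escaping a command is treated as
an internal invariant failure.
"""


class MrioError(Exception):
    """Base class for all expected toolkit failures."""


class ResolutionError(MrioError):
    """A CURIE or label did not resolve in the knowledge base."""


class NotFoundError(ResolutionError):
    """Lookup key matched nothing."""


class AmbiguousLookupError(ResolutionError):
    """Lookup key matched more than one record."""

    def __init__(self, key, candidates):
        self.key = key
        self.candidates = tuple(candidates)
        super().__init__(
            f"ambiguous key {key!r}: matches {', '.join(self.candidates)}"
        )


class FormatError(MrioError):
    """Input could not be parsed in the advertised format."""


class ModalityError(FormatError):
    """A DICOM dataset is not an MR series."""


class InvariantError(MrioError):
    """A value violates a domain invariant (e.g. negative duration)."""


class SchemaError(MrioError):
    """A rule references a parameter that does not exist."""


class EmptyInputError(MrioError):
    """An operation requiring at least one element received none."""


class KBValidationError(MrioError):
    """A knowledge base failed validation where a valid one is required."""

    def __init__(self, report):
        self.report = report
        super().__init__(
            "knowledge base failed validation: " + "; ".join(report.errors)
        )


class NoConventionError(MrioError):
    """No BIDS naming convention exists for the requested type."""


class CollisionError(MrioError):
    """Two sources map onto the same target path."""
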