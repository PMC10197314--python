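"""Exception hierarchy for circseam.

All user-facing failures derive from :class:`CircseamError` so the CLI can
map them to exit code 2 without catching unrelated bugs.
"""


class CircseamError(Exception):
    """Base class for all circseam input/usage errors."""


class UnrecognizedFormat(CircseamError):
    """No supported circRNA-caller dialect matches the file content."""


class MalformedRow(CircseamError):
    """A data row could not be mapped to a circRNA record."""

    def __init__(self, line_no: int, line: str, reason: str):
        self.line_no = line_no
        self.line = line
        self.reason = reason
        super().__init__(f"line {line_no}: {reason}: {line!r}")


class CapExceeded(CircseamError):
    """More records than the per-run cap in strict mode."""


class UnknownSequence(CircseamError):
    """A record names a sequence absent from the genome."""


class OutOfBounds(CircseamError):
    """A requested interval extends outside a genome sequence."""


class GenomeError(CircseamError):
    """A genome source could not be opened or parsed."""
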