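"""Exception hierarchy.

Errors are categorized so the CLI can report them uniformly: bad user input
(:class:`InputError`), unparseable files (:class:`FormatError`), mathematically
degenerate situations such as zero variance (:class:`DegenerateError`), and
PWM-scale misuse (:class:`ScaleError`).
"""


class RbpknnError(Exception):
    """Base class for all package errors."""

    category = "error"


class InputError(RbpknnError, ValueError):
    """Invalid argument or precondition violation."""

    category = "input"


class FormatError(RbpknnError, ValueError):
    """A file does not conform to its declared format."""

    category = "format"


class DegenerateError(RbpknnError, ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""

    category = "degenerate"


class ScaleError(RbpknnError, ValueError):
    """A PWM was supplied on the wrong scale for the requested operation."""

    category = "scale"
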