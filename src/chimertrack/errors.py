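"""Exception hierarchy.

Validation problems (bad inputs, schema violations) raise
:class:`ValidationError`; malformed files raise :class:`FormatError`;
QC failures that invalidate a whole sample (e.g. the reference assay
never amplified) raise :class:`QCError` so callers can distinguish a
broken sample from a genuinely negative marker.
"""


class ChimertrackError(Exception):
    """Base class for all package errors."""


class FormatError(ChimertrackError):
    """A file does not parse as its documented schema."""


class ValidationError(ChimertrackError):
    """An input violates a documented invariant."""


class QCError(ChimertrackError):
    """A sample-level quality-control failure (not a negative result)."""


class ConfigurationError(ChimertrackError):
    """An analysis was requested that the inputs cannot support."""
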