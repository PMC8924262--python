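"""Exception hierarchy.

All package-specific failures derive from :class:`PiezoquantError` so callers
(and the CLI) can catch one base class; most also derive from ``ValueError``
because they signal invalid inputs rather than internal faults.
"""


class PiezoquantError(Exception):
    """Base class for all piezoquant errors."""


class InvalidParameterError(PiezoquantError, ValueError):
    """A generator or analysis parameter is non-finite or out of range."""


class WindowError(PiezoquantError, ValueError):
    """A requested sample/time window is empty, too short, or out of bounds."""


class DegenerateBaselineError(PiezoquantError, ValueError):
    """Baseline SD is exactly zero so an SD-relative criterion is undefined."""


class NoDecayError(PiezoquantError, ValueError):
    """The decay segment has no exponential component to fit."""


class NoResolvableOpeningsError(PiezoquantError, ValueError):
    """The amplitude histogram does not resolve two conductance levels."""
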