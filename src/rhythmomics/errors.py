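"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input problems -> 2, degenerate or
unidentifiable models -> 3.
"""


class RhythmomicsError(Exception):
    """Base class for all package-specific errors."""


class InputError(RhythmomicsError):
    """Malformed or inconsistent input data / configuration."""


class IdentifiabilityError(RhythmomicsError):
    """Design matrix is rank deficient; model parameters not identifiable."""


class DegenerateModelError(RhythmomicsError):
    """A model fit is degenerate beyond what a warning flag can express."""
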