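"""Exception hierarchy shared across the package.

The CLI maps :class:`InputError` to exit code 2 and
:class:`EmptyResultError` to exit code 3; everything else is a bug.
"""


class CylmapError(Exception):
    """Base class for all package errors."""


class InputError(CylmapError):
    """Malformed, inconsistent or missing input data."""


class EmptyResultError(CylmapError):
    """A computation produced no usable result (e.g. subunits not in contact)."""
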