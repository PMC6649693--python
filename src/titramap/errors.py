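"""Exception hierarchy shared across the package.

The CLI maps these onto exit codes: input/format problems -> 2,
parameter problems -> 3.
"""


class TitramapError(Exception):
    """Base class for all package errors."""


class InputError(TitramapError):
    """Malformed or inconsistent input data (files, peak lists, series)."""


class FormatError(InputError):
    """A file could not be parsed in the declared dialect."""


class ParameterError(TitramapError):
    """An analysis parameter is outside its valid range."""


class FitError(TitramapError):
    """A model fit could not be performed (e.g. no responsive residues)."""
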