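"""Exception hierarchy shared by the library and the command line."""


class IdrpredError(Exception):
    """Base class for all package errors."""


class DataError(IdrpredError):
    """Malformed or inconsistent input data (files, labels, shapes)."""


class NumericalError(IdrpredError):
    """A computation could not be carried out (empty statistics, divergence)."""
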