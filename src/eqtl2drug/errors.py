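"""Exception hierarchy: configuration problems vs malformed/empty data."""


class Eqtl2DrugError(Exception):
    """Base class for package errors."""


class ConfigurationError(Eqtl2DrugError):
    """A parameter, column mapping, or config file is invalid."""


class EmptyInputError(Eqtl2DrugError):
    """An input file contained no usable rows."""


class DataError(Eqtl2DrugError):
    """Input data violates a precondition that cannot be repaired by dropping rows."""
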