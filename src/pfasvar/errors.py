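"""Exception hierarchy shared across the pipeline."""


class PfasVarError(Exception):
    """Base class for all package errors."""


class SchemaError(PfasVarError):
    """An input file does not match the declared column dialect."""


class ValidationError(PfasVarError):
    """Input data violate a structural invariant (ids, codes, ranges)."""


class DegenerateDataError(PfasVarError):
    """Data are too degenerate for the requested computation
    (zero variance, too few points, rank deficiency...)."""
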