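"""Exception hierarchy."""


class RicephysError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RicephysError):
    """A CSV/JSON input does not match the documented schema."""


class InputDataError(RicephysError):
    """Input data are structurally valid but unusable for the requested
    operation (too few points, unbalanced design, constant predictor, ...)."""
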