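"""Exception types raised by plsdabench."""


class InvalidInputError(ValueError):
    """An input violates a documented precondition (shape, range, class count)."""


class DegenerateInputError(ValueError):
    """The input is structurally valid but carries no usable information
    (e.g. a zero-variance matrix handed to PCA)."""


class SingularScatterError(ValueError):
    """The within-class scatter matrix is singular and no ridge was requested."""
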