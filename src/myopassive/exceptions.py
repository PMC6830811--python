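"""Package-wide exception types."""


class DomainError(ValueError):
    """An input violates a physical or mathematical precondition."""


class FitError(RuntimeError):
    """A fit cannot be carried out on the given data."""


class NonIdentifiableError(FitError):
    """The requested parameters do not influence the objective."""


class LoadError(ValueError):
    """A measurement file failed validation.

    Attributes
    ----------
    row_errors : list of (int, str)
        One entry per offending row: 1-based line number in the source
        file and a human-readable message.
    """

    def __init__(self, message, row_errors=None):
        super().__init__(message)
        self.row_errors = list(row_errors or [])
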