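"""Exception hierarchy for dropjet."""


class DropjetError(Exception):
    """Base class for all dropjet errors."""


class InvalidParameterError(DropjetError, ValueError):
    """A physical parameter is outside its valid domain."""


class DegenerateFitError(DropjetError, ValueError):
    """The regression design is rank deficient (too few or identical points)."""


class NoSolutionError(DropjetError, RuntimeError):
    """A root-finding problem has no solution in the searched bracket."""


class InvalidInputError(DropjetError, ValueError):
    """A table, trace or image stack does not satisfy the operation's contract."""
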