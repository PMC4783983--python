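"""Exception hierarchy shared by all mdflex modules."""


class MDFlexError(Exception):
    """Base class for all mdflex errors."""


class ParseError(MDFlexError):
    """A structure or trajectory file could not be parsed."""


class TrajectoryFormatError(MDFlexError):
    """A trajectory file violates the TRJF v1 format contract."""


class ValidationError(MDFlexError):
    """Input data violate a documented invariant."""


class SelectionError(MDFlexError):
    """A selection expression is syntactically invalid."""


class DegenerateGeometryError(MDFlexError):
    """A geometric operation received rank-deficient input."""


class IntegrationError(MDFlexError):
    """A stochastic integrator diverged."""
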