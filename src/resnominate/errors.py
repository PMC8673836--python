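"""Exception hierarchy shared across the pipeline stages."""


class ResnominateError(Exception):
    """Base class for all package-specific errors."""


class FormatError(ResnominateError):
    """A file did not parse under the named standard."""


class RoleError(ResnominateError):
    """A structure lacks the protein/DNA chains required for contact analysis."""


class ValidationError(ResnominateError):
    """An input value violates a stated precondition."""


class MappingError(ResnominateError):
    """A residue key could not be mapped onto query numbering."""


class AlignmentError(ResnominateError):
    """A multiple sequence alignment is malformed (e.g. ragged rows)."""


class TrajectoryError(ResnominateError):
    """Frames of a trajectory do not share a topology."""


class ParameterError(ResnominateError):
    """A force-field style parameter is missing for an atom."""


class ConstructionError(ResnominateError):
    """A synthetic-data spec is geometrically or combinatorially unrealizable."""


class UndefinedFractionError(ResnominateError):
    """A fraction or percentage was requested over an empty denominator."""
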