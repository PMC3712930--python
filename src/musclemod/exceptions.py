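"""Exception hierarchy for musclemod."""


class MuscleModError(Exception):
    """Base class for all musclemod errors."""


class SchemaError(MuscleModError):
    """Input file or array does not match the expected schema."""


class IntegrityError(MuscleModError):
    """Data is schematically valid but internally inconsistent (duplicates, gaps)."""


class ParameterError(MuscleModError):
    """A parameter value is outside its valid domain."""
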