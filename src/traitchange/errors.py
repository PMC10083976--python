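"""Exception hierarchy for panel validation and analysis contracts."""


class TraitChangeError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(TraitChangeError):
    """A required column is missing or mis-typed in an input table."""


class IntegrityError(TraitChangeError):
    """A uniqueness or cross-row invariant of the data model is violated."""


class ValidationError(TraitChangeError):
    """Row values fall outside their documented ranges."""


class ConfigError(TraitChangeError):
    """A generator or pipeline configuration is infeasible."""


class FitError(TraitChangeError):
    """A model fit could not be performed under its preconditions."""


class UsageError(TraitChangeError):
    """Operations combined with incompatible arguments."""
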