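"""Exception hierarchy for missensemix."""


class MissensemixError(Exception):
    """Base class for all package errors."""


class IntegrityError(MissensemixError):
    """Referential or uniqueness violation in cohort tables."""


class ParseError(MissensemixError):
    """Unparseable field in an input file; message carries the line context."""


class DesignError(MissensemixError):
    """Rank-deficient or otherwise unusable design matrix."""


class SeparationError(MissensemixError):
    """Complete or quasi-complete separation in a logistic fit."""


class PartitionError(MissensemixError):
    """A variant matched zero or more than one risk-category predicate."""


class ConfigurationError(MissensemixError):
    """Invalid pipeline or simulation configuration."""
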