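"""Exception hierarchy shared across the pipeline."""


class PhosphopipeError(Exception):
    """Base class for all package errors."""


class DialectError(PhosphopipeError):
    """A required semantic column is not mapped to an existing header."""


class DataError(PhosphopipeError):
    """Input data violates a documented contract (non-numeric intensity,
    negative intensity, duplicate FASTA accession, ...)."""


class ConfigError(PhosphopipeError):
    """An analysis configuration is inconsistent (wrong replicate count,
    rank-deficient design, invalid generator parameters)."""


class ContractError(PhosphopipeError):
    """An internal pre-condition was violated, e.g. a triplet with two
    missing values reached the imputation step."""


class MappingError(PhosphopipeError):
    """A peptide sequence could not be located in its leading protein."""
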