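"""Exception hierarchy shared across the pipeline."""


class CostDecompError(Exception):
    """Base class for all package errors."""


class MissingDataError(CostDecompError):
    """A required phenotype/cost input is absent; the record is excluded upstream."""


class ConfigurationError(CostDecompError):
    """The analysis configuration is incomplete or inconsistent."""


class ValidationError(CostDecompError):
    """An input value violates its documented domain."""


class FitError(CostDecompError):
    """A GLM fit failed (rank deficiency or non-convergence)."""
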