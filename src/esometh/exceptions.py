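"""Exception hierarchy for esometh."""


class EsomethError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EsomethError, ValueError):
    """Invalid simulation or pipeline configuration."""


class ValidationError(EsomethError, ValueError):
    """Input data failed validation (range, ids, reconciliation)."""


class AnnotationError(EsomethError, KeyError):
    """Probe present in the matrix but absent from the annotation."""


class ConsistencyError(EsomethError, ValueError):
    """Cross-object inconsistency (e.g. planted CpG missing from matrix)."""


class StratificationError(EsomethError, ValueError):
    """A resampling fold or partition lost a class or all events."""


class HyperparameterError(EsomethError, RuntimeError):
    """Empirical-Bayes hyperparameter estimation failed."""
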