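"""Exception hierarchy for the dcefoci pipeline."""


class DcefociError(Exception):
    """Base class for all pipeline errors."""


class ParameterError(DcefociError, ValueError):
    """Invalid configuration or parameter value (bad simplex, negative size...)."""


class FormatError(DcefociError, ValueError):
    """Malformed on-disk input (wrong time-point count, mismatched grids...)."""


class AnnotationError(DcefociError, ValueError):
    """Invalid lesion annotation (empty mask, out-of-bounds slice...)."""


class DegenerateBaselineError(DcefociError, ZeroDivisionError):
    """Kinetic ratio requested against a (near-)zero baseline signal."""


class DataError(DcefociError, ValueError):
    """Dataset-level problem (missing file, single-class training set...)."""


class TrainingError(DcefociError, RuntimeError):
    """Optimization failure (non-finite loss)."""


class ConfigurationError(DcefociError, ValueError):
    """Model configuration that cannot be realized (spatial size < 1...)."""
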