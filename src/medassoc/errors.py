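"""Exception types shared across the pipeline."""


class MedassocError(Exception):
    """Base class for all package errors."""


class ConfigError(MedassocError, ValueError):
    """Invalid simulation or pipeline configuration."""


class CohortError(MedassocError, ValueError):
    """Degenerate case/control or class-choice design."""


class ConvergenceError(MedassocError, RuntimeError):
    """A penalized fit failed to converge at some penalty."""


class SeparationError(MedassocError, RuntimeError):
    """Perfect separation left the unpenalized logistic MLE undefined."""
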