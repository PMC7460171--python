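"""Exception hierarchy shared across the package.

Domain errors signal invalid parameters or observations; fit errors carry the
optimizer trace; the remaining classes mark configuration, schema, inference
and pipeline failures so callers can react per stage.
"""

from __future__ import annotations


class DomainError(ValueError):
    """Parameter or observation outside its mathematical domain."""


class FitError(RuntimeError):
    """Maximum-likelihood optimization failed to converge.

    The scipy ``OptimizeResult`` (when available) is attached as ``trace``.
    """

    def __init__(self, message: str, trace=None):
        super().__init__(message)
        self.trace = trace


class InferenceError(RuntimeError):
    """Standard errors unavailable (singular or indefinite observed information)."""


class ConfigurationError(ValueError):
    """Invalid configuration (unsupported mode/family combination, bad rates, ...)."""


class SchemaError(ValueError):
    """Dataset does not match the expected column schema."""


class PredictionError(ValueError):
    """Covariate row incompatible with a fitted model."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""
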