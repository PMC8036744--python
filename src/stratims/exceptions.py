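"""Exception hierarchy used across the pipeline.

Errors are grouped so that callers (and the CLI exit-code mapping) can
distinguish configuration problems from data problems from numerical ones.
"""


class StratIMSError(Exception):
    """Base class for all package errors."""


class ConfigurationError(StratIMSError):
    """Invalid configuration (non-simplex proportions, empty grid, bad range)."""


class ParameterError(StratIMSError):
    """A function parameter is out of its valid domain."""


class EmptyInputError(StratIMSError):
    """An operation received an empty dataset, matrix or panel."""


class DegenerateSpectrumError(StratIMSError):
    """A spectrum cannot be processed (e.g. all-zero total ion count)."""

    def __init__(self, message, pixel=None):
        super().__init__(message)
        self.pixel = pixel


class MetadataJoinError(StratIMSError):
    """Spectrum metadata could not be joined (missing core/patient ids)."""


class StratificationError(StratIMSError):
    """Stratified subset construction failed (empty class, unsplittable core set)."""


class DegenerateLabelError(StratIMSError):
    """A supervised step received fewer than two label classes."""


class FeatureParityError(StratIMSError):
    """Feature axes of a model and a matrix do not match; run axis alignment."""


class FoldConstructionError(StratIMSError):
    """Cross-validation folds cannot be built (class count below fold count)."""


class UnsupportedDialectError(StratIMSError):
    """An input file uses a dialect the reader does not support (e.g. processed-mode imzML)."""
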