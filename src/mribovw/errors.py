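"""Exception hierarchy.

Every error raised by the library derives from :class:`MribovwError` so
callers can catch the whole family with one clause.
"""


class MribovwError(Exception):
    """Base class for all library errors."""


class FormatError(MribovwError):
    """Raster input has an unsupported layout (channel count, dtype)."""


class DatasetError(MribovwError):
    """Dataset folder layout is invalid (empty class folder, no classes)."""


class SplitError(MribovwError):
    """Stratified split preconditions violated."""


class ScaleError(MribovwError):
    """Requested filter/patch scale does not fit the image."""


class ExtractionError(MribovwError):
    """Dense feature extraction cannot proceed on this image."""


class SelectionError(MribovwError):
    """Strongest-feature selection called on an empty pool."""


class VocabularyError(MribovwError):
    """Vocabulary fitting preconditions violated (too few descriptors)."""


class EncodingError(MribovwError):
    """Histogram encoding mismatch (descriptor family vs vocabulary)."""


class TrainingError(MribovwError):
    """Classifier training preconditions violated."""


class DimensionError(MribovwError):
    """Feature dimensionality does not match the trained model."""


class EvaluationError(MribovwError):
    """Evaluation inputs invalid (unknown label, empty test set)."""


class RegistryError(MribovwError):
    """Unknown classifier name requested from the registry."""


class ConfigError(MribovwError):
    """Pipeline configuration invalid (unknown key, bad value)."""


class ParameterError(MribovwError):
    """Numerical parameter out of range (e.g. non-positive time step)."""
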