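"""Exception hierarchy for the rhizoclass pipeline."""


class RhizoclassError(Exception):
    """Base class for all rhizoclass errors."""


class ConfigurationError(RhizoclassError):
    """Invalid simulation or run configuration."""


class DesignError(RhizoclassError):
    """Contrast design inconsistency (unknown condition, mismatched baselines...)."""


class InputError(RhizoclassError):
    """Malformed or incomplete input data."""


class NormalizationError(RhizoclassError):
    """Slide cannot be normalized (too few usable spots)."""


class StatisticsError(RhizoclassError):
    """Replicate statistics cannot be computed (e.g. fewer than two replicates)."""


class ParameterError(RhizoclassError):
    """Parameter outside its admissible range."""


class AssayError(RhizoclassError):
    """Competition assay with no usable plant records."""
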