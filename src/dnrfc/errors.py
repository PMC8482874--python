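"""Exception types shared across the pipeline."""


class ConfigurationError(ValueError):
    """A parameter combination is invalid (bad band, cluster count, folds...)."""


class DimensionError(ValueError):
    """Input array dimensions are incompatible with the requested operation."""


class DataFormatError(ValueError):
    """An on-disk cohort artifact (manifest or subject file) is malformed."""
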