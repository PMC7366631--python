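"""Exception types raised across the pipeline."""


class FibrospecError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FibrospecError, ValueError):
    """A configuration object has an invalid field; message names the field."""


class SpectraFormatError(FibrospecError, ValueError):
    """A spectra CSV file violates the documented layout."""


class DataIntegrityError(FibrospecError, ValueError):
    """Row metadata is internally inconsistent (e.g. conflicting labels)."""


class DegenerateSpectrumError(FibrospecError, ValueError):
    """A spectrum cannot be processed (e.g. zero norm); message names the sample."""


class StratificationError(FibrospecError, ValueError):
    """A class is too small to be split into train/validation/test."""
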