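"""Exception hierarchy shared across the pipeline stages."""


class DocEEGError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(DocEEGError, ValueError):
    """A caller-supplied parameter is outside its admissible range."""


class ConfigurationError(DocEEGError, ValueError):
    """A configuration is internally inconsistent (e.g. band edge beyond Nyquist)."""


class InvalidInputError(DocEEGError, ValueError):
    """Input data violate a structural contract (shape, labels, grids)."""


class EmptyDataError(DocEEGError, ValueError):
    """No data survive to this stage (e.g. every epoch rejected)."""
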