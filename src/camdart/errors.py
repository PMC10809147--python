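"""Exception hierarchy shared by all pipeline stages."""


class PipelineError(Exception):
    """Base class for all camdart errors."""


class FormatError(PipelineError):
    """Malformed input data (inconsistent TIFF pages, odd dual-view split, ...)."""


class DegenerateInputError(PipelineError):
    """Input is structurally valid but degenerate (constant image, empty mask, ...)."""


class GeometryError(PipelineError):
    """Invalid geometry (centroid outside outline, angular gap too large, ...)."""


class FitError(PipelineError):
    """A model fit failed to converge; carries diagnostics in ``args``."""
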