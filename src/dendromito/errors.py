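"""Exception hierarchy shared across the pipeline."""


class DendromitoError(Exception):
    """Base class for all package errors."""


class AnnotationParseError(DendromitoError):
    """An annotation table or GenBank file could not be parsed."""


class MalformedAnnotationError(DendromitoError):
    """Annotations are syntactically valid but internally inconsistent."""


class BoundsError(DendromitoError):
    """Feature coordinates fall outside the genome."""


class DegenerateRecordError(DendromitoError):
    """A record has too few features for the requested statistic."""


class FrameError(DendromitoError):
    """A protein-coding sequence cannot be put in frame / translated."""


class SaturationError(DendromitoError):
    """A pairwise distance exceeded the model's saturation bound."""


class ConfigError(DendromitoError):
    """A simulation or run configuration is inconsistent."""
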