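"""Exception hierarchy for the pipeline."""


class RibohetError(Exception):
    """Base class for all package errors."""


class MapFormatError(RibohetError):
    """Malformed or unsupported MRC/CCP4 map."""


class EmptyModelError(RibohetError):
    """A structure file yielded no atoms."""


class TraceFormatError(RibohetError):
    """Gradient trace table is malformed, too short, or out of order."""


class ValidationError(RibohetError):
    """Invalid block library or taxonomy configuration."""


class DegenerateVolumeError(RibohetError):
    """Volume has no variance; z-normalization undefined."""


class GeometryError(RibohetError):
    """Volumes do not share grid geometry, or packing is infeasible."""


class ParameterError(RibohetError):
    """Invalid clustering / simulation parameter."""


class RuleError(RibohetError):
    """Taxonomy rules reference a category the occupancy vector lacks."""


class ConsistencyError(RibohetError):
    """Counts or labels disagree between pipeline stages."""


class WindowError(RibohetError):
    """A peak window lies outside the trace span."""


class ComparisonError(RibohetError):
    """Summaries or runs are not comparable (different taxonomy)."""
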