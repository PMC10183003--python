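"""Exception hierarchy for the dCNA pipeline.

Every error raised deliberately by this package derives from
:class:`DCNAError`, so callers (and the CLI) can distinguish pipeline
failures from programming errors.
"""


class DCNAError(Exception):
    """Base class for all pipeline errors."""


class FormatError(DCNAError):
    """An input file could not be parsed in its declared format."""


class EmptyModelError(DCNAError):
    """A topology yielded no eligible network nodes."""


class TopologyError(DCNAError):
    """Trajectory and topology disagree (atom counts, residue order...)."""


class EnsembleError(DCNAError):
    """An ensemble is unusable (no frames, too few frames, bad fit set)."""


class GeometryError(DCNAError):
    """A geometric mode was requested without the coordinates it needs."""


class MappingError(DCNAError):
    """Per-node values could not be mapped onto a structure template."""


class NetworkError(DCNAError):
    """A graph operation received an unusable network or partition."""


class AlignmentError(DCNAError):
    """Two objects that must share a node/record set do not."""


class SpecError(DCNAError):
    """A synthetic-ensemble specification is infeasible or inconsistent."""


class MutationError(DCNAError):
    """A mutation record cannot be resolved against the topology."""


class ConfigError(DCNAError):
    """A run configuration is invalid."""
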