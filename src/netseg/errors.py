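"""Exception hierarchy for the netseg toolkit."""


class NetsegError(Exception):
    """Base class for all netseg errors."""


class ConfigurationError(NetsegError):
    """Invalid configuration or generator parameters."""


class FormatError(NetsegError):
    """Malformed input table (wrong shape, missing columns, bad values)."""


class PipelineOrderError(NetsegError):
    """A denoising stage was applied out of the mandated order."""


class DesignMatrixError(NetsegError):
    """Rank-deficient or otherwise unusable regression design."""


class AllFramesCensoredError(NetsegError):
    """Scrubbing removed every frame of a run."""


class UndefinedSegregationError(NetsegError):
    """Segregation is undefined (mean within-system connectivity is zero)."""
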