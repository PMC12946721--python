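"""Exception hierarchy for mrpipe.

Every error raised deliberately by the package derives from :class:`MRPipeError`
so callers (the screening loop in particular) can distinguish expected
per-trait failures from genuine bugs.
"""


class MRPipeError(Exception):
    """Base class for all mrpipe errors."""


class FormatError(MRPipeError):
    """A summary-statistics file does not conform to the expected dialect."""


class ValidationError(MRPipeError):
    """A record or container violates a domain invariant."""


class EmptyOverlapError(MRPipeError):
    """Exposure and outcome panels share no usable SNPs."""


class NoInstrumentError(MRPipeError):
    """No SNP survives instrument selection.

    ``stage`` names the pipeline stage at which the set became empty.
    """

    def __init__(self, message: str, stage: str | None = None):
        super().__init__(message)
        self.stage = stage


class MissingLDError(MRPipeError):
    """A SNP required for clumping is absent from the supplied LD matrix."""


class DegenerateInstrumentError(MRPipeError):
    """Wald ratio requested for a SNP with zero exposure effect."""


class InsufficientInstrumentsError(MRPipeError):
    """An estimator was given fewer SNPs than it mathematically requires."""


class IdentificationError(MRPipeError):
    """The multivariable design matrix is rank deficient or under-determined."""


class ConfigError(MRPipeError):
    """A simulation or run configuration is invalid."""
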