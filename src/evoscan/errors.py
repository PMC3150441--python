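"""Exception hierarchy shared across the pipeline stages."""


class EvoscanError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(EvoscanError):
    """A file did not conform to its documented dialect."""


class CoordinateError(EvoscanError):
    """A genomic coordinate fell outside chromosome bounds or no chromosome."""


class FrameError(EvoscanError):
    """A CDS length was not divisible by 3."""


class PairingError(EvoscanError):
    """Paired inputs (pileups, coverage tracks) do not cover the same space."""


class ConfigError(EvoscanError):
    """An invalid or infeasible configuration value."""


class EstimationError(EvoscanError):
    """Too little usable data for a regression or normalization."""
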