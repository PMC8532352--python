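"""Exception types shared across the package."""


class EctvarError(Exception):
    """Base class for all package errors."""


class ConfigurationError(EctvarError):
    """Invalid or infeasible configuration (e.g. impossible length ranges)."""


class GTFParseError(EctvarError):
    """Malformed GTF input (missing attributes, bad coordinates)."""


class BoundsError(EctvarError):
    """A genomic interval falls outside the stored chromosome sequence."""


class SimulationInfeasibleError(EctvarError):
    """The requested simulation cannot be satisfied by the given annotation."""
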