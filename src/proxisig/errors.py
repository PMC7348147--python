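"""Exception hierarchy shared across the pipeline stages."""


class ProxisigError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ProxisigError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SimulationError(ProxisigError, RuntimeError):
    """A requested planted structure cannot be realised."""


class ParseError(ProxisigError, ValueError):
    """A malformed input file; carries position information where available."""


class RecordError(ProxisigError, ValueError):
    """A structurally invalid record (e.g. sequence/quality length mismatch)."""


class DegenerateDataError(ProxisigError, ValueError):
    """Input data degenerate for the requested computation (e.g. constant matrix)."""
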