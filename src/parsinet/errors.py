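"""Exception hierarchy shared across the package."""


class ParsinetError(Exception):
    """Base class for all errors raised by parsinet."""


class InputError(ParsinetError):
    """Invalid user-supplied data (unknown node ids, mismatched graphs, ...)."""


class ModelError(ParsinetError):
    """A structure violates the history model (e.g. self-flip without self-loops)."""


class FormatError(ParsinetError):
    """Malformed file content."""


class ConfigError(ParsinetError):
    """Inconsistent configuration (e.g. branch-length penalty without times)."""


class SimulationRestart(ParsinetError):
    """The simulated network died out; the caller should restart with fresh randomness."""
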