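"""Exception types shared across the pipeline stages."""


class MirswitchError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MirswitchError):
    """A configuration value is invalid or inconsistent with the inputs."""


class ValidationError(MirswitchError):
    """An input violates a documented precondition."""


class UndefinedStatisticError(MirswitchError):
    """A statistic is undefined for the given input (e.g. zero variance)."""


class OntologyStructureError(MirswitchError):
    """The ontology graph violates a structural requirement (e.g. a cycle)."""
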