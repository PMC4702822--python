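"""Exception hierarchy for domainhotspots."""


class DomainHotspotsError(Exception):
    """Base class for all package errors."""


class FormatError(DomainHotspotsError):
    """An input file violates its documented format contract."""


class ValidationError(DomainHotspotsError):
    """In-memory data violates a type invariant."""


class ConfigError(DomainHotspotsError):
    """A pipeline or simulation configuration is invalid."""


class PipelineError(DomainHotspotsError):
    """A pipeline stage failed; the message names the stage."""
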