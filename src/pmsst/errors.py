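"""Exception hierarchy for the PMSST engine.

Every stage of the pipeline raises a subclass of :class:`PmsstError` so that
orchestration code (the CLI) can attribute a failure to a stage.
"""


class PmsstError(Exception):
    """Base class for all PMSST errors."""


class RegistryLoadError(PmsstError):
    """A registry dump violates the registry invariants (duplicate ids,
    dangling semantic-link targets, malformed value domains)."""


class NotFoundError(PmsstError, KeyError):
    """An element, object class, code system or concept id does not resolve."""

    def __str__(self) -> str:  # KeyError quotes its message; keep it readable
        return Exception.__str__(self)


class ResolutionError(PmsstError):
    """No extraction specification for the requested content model is
    reachable over the semantic-link graph."""


class SpecError(PmsstError):
    """An extraction specification script is malformed or uses a dialect
    incompatible with the payload it was dispatched on."""


class DataQualityError(PmsstError):
    """Extracted data violates the declared value domain, or a derivation's
    single-value contract is broken by conflicting duplicates."""


class SchemaValidationError(PmsstError):
    """A data-collection-set schema is inconsistent: duplicate item names,
    unknown dependencies, dependency cycles, or value bindings that fail
    value-domain validation."""


class ConfigError(PmsstError):
    """A run or generator configuration is invalid."""
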