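"""Exception hierarchy shared across the package."""


class SmaCallerError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(SmaCallerError):
    """Unknown build name or malformed locus-configuration file."""


class ContigError(SmaCallerError):
    """A required contig is absent from a FASTA or alignment header."""


class ReferenceRequiredError(SmaCallerError):
    """A CRAM input was given without its reference FASTA."""


class ValidationError(SmaCallerError):
    """Reference-base validation failed (wrong base at a configured position)."""


class ContractError(SmaCallerError):
    """An input object violates its documented invariants."""


class UndefinedMetricError(SmaCallerError):
    """A ratio metric was requested with a zero denominator."""


class ManifestError(SmaCallerError):
    """Simulated-cohort manifest is inconsistent (e.g. duplicate sample ids)."""
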