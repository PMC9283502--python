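"""Exception hierarchy.

Validation errors (bad inputs, malformed files) and computation errors
(non-identifiable fits, discordant assay calls) are kept on separate branches
so callers — in particular the CLI — can map them to distinct exit codes.
"""


class KdrmonError(Exception):
    """Base class for all package errors."""


class ValidationError(KdrmonError):
    """Malformed or inconsistent input data."""


class InvalidSequenceError(ValidationError):
    """A sequence contains characters outside the IUPAC nucleotide alphabet."""


class LocusMismatchError(ValidationError):
    """A diploid call was supplied for the wrong locus."""


class GenotypeParseError(ValidationError):
    """A genotype string does not match the nine-class 'X/Y:W/Z' grammar."""


class ComputationError(KdrmonError):
    """A well-formed input on which the requested computation fails."""


class AmpliconNotFoundError(ComputationError):
    """A primer pair has no match in the template."""


class AmbiguousPrimingError(ComputationError):
    """A primer matches the template at more than one position."""


class AmbiguityOverflowError(ComputationError):
    """Too many ambiguous positions to expand into alleles (unusable trace)."""


class AssayFailureError(ComputationError):
    """No allele-specific probe or enzyme pattern matched any allele."""


class CoverageError(ComputationError):
    """The sample sequence does not cover the locus codon (anchoring failed)."""


class DiscordanceError(ComputationError):
    """Independent genotyping routes disagree on the same sample."""

    def __init__(self, message, calls=None):
        super().__init__(message)
        self.calls = calls or {}


class NonIdentifiableError(ComputationError):
    """Dose-response data carry no information about the LC50 (all dead/alive)."""


class ConvergenceError(ComputationError):
    """The optimizer failed to converge after the documented restart schedule."""


class InferenceError(ComputationError):
    """Standard errors are unavailable (singular or non-PD covariance)."""


class EmptySampleError(ValidationError):
    """A genotype count table with n = 0."""


class DegenerateTableError(ValidationError):
    """A contingency table with an all-zero row cannot be tested."""
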