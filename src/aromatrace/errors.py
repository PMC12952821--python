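"""Exception hierarchy used across the package."""


class AromatraceError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(AromatraceError):
    """A CSV header or config does not match the documented schema."""


class ValidationError(AromatraceError):
    """A record or value violates a domain invariant.

    The message always names the offending field.
    """


class DuplicateCompoundError(AromatraceError):
    """Two rows map to the same canonical compound name within one table."""


class AlignmentError(AromatraceError):
    """Sample identifiers of abundance matrices do not line up."""


class LadderRangeError(AromatraceError):
    """A retention time falls outside the n-alkane ladder span."""


class InvalidThresholdError(AromatraceError):
    """A numeric odor threshold of zero (distinct from the ND sentinel)."""


class DegenerateDesignError(AromatraceError):
    """A discriminant design with fewer than two classes."""


class RankError(AromatraceError):
    """More latent components requested than the data matrix supports."""


class ConstantVectorError(AromatraceError):
    """Correlation requested on a constant (zero-variance) vector."""
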