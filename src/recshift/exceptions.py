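"""Exception hierarchy for recshift.

All exceptions derive from :class:`RecshiftError` so callers can catch the
package's errors with a single except clause; each subclass also derives from
the closest built-in (ValueError / RuntimeError / IndexError) so generic
handling keeps working.
"""


class RecshiftError(Exception):
    """Base class for all recshift errors."""


class ConfigurationError(RecshiftError, ValueError):
    """Invalid configuration values (non-positive sizes, rates, ...)."""


class DegeneratePanelError(ConfigurationError):
    """Founder configuration expected to yield too few segregating sites."""


class LayoutError(RecshiftError, ValueError):
    """Region layout cannot be constructed (divisibility, region length)."""


class StateError(RecshiftError, RuntimeError):
    """Operation applied in an invalid state (e.g. shifting twice)."""


class BoundsError(RecshiftError, IndexError):
    """Genomic coordinate outside the chromosome."""


class SamplingError(RecshiftError, ValueError):
    """Not enough eligible sites to sample the requested QTN."""


class DimensionError(RecshiftError, ValueError):
    """Vector length mismatch between genotypes and trait architecture."""
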