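"""Exception hierarchy shared across the package."""


class NmrDomainsError(Exception):
    """Base class for all package errors."""


class FormatError(NmrDomainsError):
    """A file could not be parsed under the requested format."""


class ValidationError(NmrDomainsError):
    """Parsed data violates an invariant (duplicates, out-of-range values)."""


class BoundsError(NmrDomainsError, ValueError):
    """A residue range falls outside the available sequence."""


class NumberingError(NmrDomainsError, ValueError):
    """Construct prefix numbering would extend below residue 1."""


class AlphabetError(NmrDomainsError, ValueError):
    """A sequence contains a non-standard one-letter code."""


class FitError(NmrDomainsError):
    """A least-squares fit failed to converge."""
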