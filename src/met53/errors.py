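"""Exception hierarchy shared across the package."""


class Met53Error(Exception):
    """Base class for all package-specific errors."""


class FormatError(Met53Error):
    """A file does not conform to its declared dialect (missing columns,
    malformed lines, unparseable cells)."""


class ValidationError(Met53Error):
    """A parsed structure violates a domain invariant (duplicate labels,
    out-of-range values, unknown category labels)."""


class DegenerateVarianceError(Met53Error):
    """Raised when a variance-based test is requested on data with no
    variance; the message points at the rank-based alternative."""
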