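"""Exception types shared across the pipeline stages."""


class PorefixError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PorefixError):
    """A sequence or table file violates its format contract."""


class UnsupportedFeatureError(PorefixError):
    """Input uses a format feature outside the supported subset."""


class ConsistencyError(PorefixError):
    """Internally inconsistent inputs (e.g. pileup/read length mismatch)."""


class InputError(PorefixError):
    """Semantically invalid input values (empty database, zero totals, ...)."""
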