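"""Exception hierarchy shared across modules."""


class FadynError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FadynError, ValueError):
    """A simulation or analysis parameter violates its documented constraint."""


class DegenerateTraceError(FadynError, ValueError):
    """An input trace cannot be analyzed (e.g. prebleach signal <= background)."""
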