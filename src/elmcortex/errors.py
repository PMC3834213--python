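"""Exception hierarchy used across the package."""


class ElmCortexError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ElmCortexError):
    """An input violates a documented precondition."""


class SchemaError(ElmCortexError):
    """A table or file does not conform to the expected column schema."""


class ParseError(ElmCortexError):
    """A file could not be parsed; the message names the offending location."""


class MissingRegionError(ParseError):
    """A parcellation summary lacks one or more schema regions."""

    def __init__(self, regions, hemisphere):
        self.regions = list(regions)
        self.hemisphere = hemisphere
        super().__init__(
            f"missing region(s) in {hemisphere} hemisphere stats: "
            + ", ".join(self.regions)
        )
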