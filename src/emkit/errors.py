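"""Exception hierarchy shared across the library."""


class EmkitError(Exception):
    """Base class for all errors raised by emkit."""


class CastError(EmkitError):
    """A value cannot be represented in the destination element type."""


class FormatError(EmkitError):
    """A file does not conform to its declared binary or text format."""


class TableError(EmkitError):
    """Invalid table structure, column reference or filter expression."""


class PipelineError(EmkitError):
    """A processing step inside a pipeline failed; message names the step."""
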