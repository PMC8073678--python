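"""Exception hierarchy shared across the package."""


class SmiletraceError(Exception):
    """Base class for all package-specific errors."""


class FormatError(SmiletraceError, ValueError):
    """An input file does not conform to the expected dialect."""


class EmptyInputError(SmiletraceError, ValueError):
    """An input yielded zero usable rows/subjects."""


class ParameterError(SmiletraceError, ValueError):
    """A parameter is outside its documented range."""


class InputError(SmiletraceError, ValueError):
    """Semantically invalid input (duplicate ids, non-positive durations...)."""


class PipelineError(SmiletraceError, RuntimeError):
    """A pipeline stage failed; the message names the stage and subject."""
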