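"""Exception hierarchy shared across the package."""


class ListcompError(Exception):
    """Base class for all errors raised by this package."""


class ContractError(ListcompError, ValueError):
    """An operation was called with arguments violating its preconditions."""


class DegenerateInputError(ListcompError, ValueError):
    """An input is structurally valid but yields an empty or meaningless result."""


class FormatError(ListcompError, ValueError):
    """A file could not be parsed; readers reject rather than coerce."""
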