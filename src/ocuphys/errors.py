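"""Exception hierarchy shared across the toolkit.

``InputError`` marks malformed or insufficient input (CLI exit code 2),
``AnalysisError`` marks a computation that cannot produce a result from
otherwise valid input (CLI exit code 3).
"""


class OcuphysError(Exception):
    """Base class for all toolkit errors."""


class InputError(OcuphysError, ValueError):
    """Invalid, malformed, or insufficient input data or parameters."""


class AnalysisError(OcuphysError, RuntimeError):
    """A computation failed on valid input (e.g. no receptive field detected)."""
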