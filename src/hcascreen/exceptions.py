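"""Error taxonomy shared by the library and the CLI.

The CLI maps these onto exit codes: :class:`InputError` -> 2,
:class:`ConfigError` and :class:`AnalysisError` -> 3.
"""


class HcaError(Exception):
    """Base class for all package errors."""


class InputError(HcaError):
    """Malformed or inconsistent user-supplied input (files, tables)."""


class ConfigError(HcaError):
    """Invalid simulation or run configuration."""


class AnalysisError(HcaError):
    """A statistical operation cannot be carried out on the given data."""
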