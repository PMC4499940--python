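"""Exception hierarchy.

All fatal user-facing conditions derive from :class:`GsoaError` so the CLI can
catch one type, print the message, clean up partial output and exit nonzero.
"""


class GsoaError(Exception):
    """Base class for all fatal errors raised by this package."""


class InputError(GsoaError):
    """A problem with an input file: missing, malformed, or violating a contract."""


class ConfigError(GsoaError):
    """An invalid configuration value or combination of options."""


class NoFeatureOverlap(GsoaError):
    """A gene set shares no features with the loaded data; the set is skipped."""
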