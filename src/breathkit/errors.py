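"""Exception hierarchy; exit codes used by the CLI."""


class BreathkitError(Exception):
    """Base class for all breathkit errors."""

    exit_code = 1


class InputError(BreathkitError):
    """A data file could not be ingested (missing, malformed, non-monotone)."""

    exit_code = 2


class ConfigError(BreathkitError):
    """A configuration value violates its invariants."""

    exit_code = 3
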