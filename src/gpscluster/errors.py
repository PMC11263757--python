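"""Exception hierarchy; the CLI maps these onto distinct exit codes."""


class GpsClusterError(Exception):
    """Base class for all package errors."""


class ConfigError(GpsClusterError):
    """Bad or missing run configuration (wrong column name, missing key...)."""


class InputError(GpsClusterError):
    """Malformed input data (unparseable timestamp, unreadable file...)."""


class SettingsMismatchError(GpsClusterError):
    """A subsequent analysis changed clustering parameters mid-study."""
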