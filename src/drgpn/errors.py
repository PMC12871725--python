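"""Exception hierarchy shared across the pipeline."""


class DrgpnError(Exception):
    """Base class for all package errors."""


class FormatError(DrgpnError):
    """A file is malformed or missing (names the offending file/line)."""


class IntegrityError(DrgpnError):
    """Internally inconsistent data, e.g. matrix/annotation dimension mismatch."""


class ConfigError(DrgpnError):
    """An infeasible or invalid configuration value."""
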