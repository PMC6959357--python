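"""Exception hierarchy mapped onto CLI exit codes."""


class AdaptscanError(Exception):
    """Base class; exit code 1."""

    exit_code = 1


class ConfigError(AdaptscanError):
    """Invalid configuration or missing inputs; exit code 2."""

    exit_code = 2


class DataError(AdaptscanError):
    """Malformed or inconsistent data; exit code 3."""

    exit_code = 3


class NumericalError(AdaptscanError):
    """Numerical failure (non-convergence, singularity); exit code 4."""

    exit_code = 4
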