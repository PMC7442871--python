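"""Exception types shared across the package."""


class ConfigError(ValueError):
    """A configuration value violates an invariant or an unknown key was given."""


class FormatError(ValueError):
    """An external file (life table CSV, cohort CSV) is malformed."""


class CalibrationError(RuntimeError):
    """Utility calibration could not bracket the requested QALY target."""
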