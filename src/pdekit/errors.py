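"""Exception hierarchy shared across the package."""


class PdekitError(Exception):
    """Base class for all package errors."""


class InputError(PdekitError):
    """Malformed or out-of-contract user input (sequences, tables, files)."""


class IntegrityError(PdekitError):
    """Internal inconsistency between derived objects (e.g. a match that
    does not re-validate against its sequence)."""


class ConfigurationError(PdekitError):
    """Missing or invalid rule-table / signature configuration."""


class CalibrationError(PdekitError):
    """Insufficient or contradictory labelled data for rule calibration."""


class FitError(PdekitError):
    """A curve fit was refused outright (as opposed to flagged non-converged)."""
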