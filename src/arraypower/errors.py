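"""Exception hierarchy for arraypower."""


class ArrayPowerError(Exception):
    """Base class for all arraypower errors."""


class InvalidDesignError(ArrayPowerError, ValueError):
    """A study design parameter is outside its admissible range, or the
    implied per-comparison significance level is degenerate (alpha >= 1)."""


class NonConvergenceError(ArrayPowerError, RuntimeError):
    """No sample size up to the configured cap satisfies the criterion."""


class DataError(ArrayPowerError, ValueError):
    """A pilot matrix or label file violates its contract."""
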