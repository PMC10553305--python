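"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a physical or structural constraint (e.g. a negative speed)."""


class DegenerateMotionError(ValidationError):
    """Searcher and particles are both stationary: no relative motion, the
    encounter-rate formula is undefined rather than zero.  Raised explicitly
    so configuration mistakes surface instead of silently returning 0."""


class GridError(ValidationError):
    """A depth grid cannot be constructed (e.g. step not smaller than the extent)."""


class StationParseError(ValueError):
    """A station concentration table could not be parsed; the message names
    the offending rows."""


class FeasibilityError(RuntimeError):
    """A requested synthetic station summary (n, mean, SD, range) cannot be
    realised; raised with a diagnostic instead of looping forever."""
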