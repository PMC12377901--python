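"""Shared helpers: rounding, error and warning types."""

from __future__ import annotations

from decimal import Decimal, ROUND_HALF_UP


class ValidationError(ValueError):
    """Input violates a documented precondition."""


class SaturationError(ValidationError):
    """All droplets positive; concentration not estimable."""


class GatingInconsistencyError(ValueError):
    """Gated populations are mutually inconsistent beyond sampling error."""


class ConsistencyWarning(UserWarning):
    """Cross-channel reference concentrations disagree beyond tolerance."""


class ClampWarning(UserWarning):
    """A small negative net value was clamped to zero."""


class ExtrapolationWarning(UserWarning):
    """An inverted estimate lies outside the calibrated range."""


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero, as bench software reports values.

    Python's built-in ``round`` uses banker's rounding; instrument reports
    (densitometry percentages, cp/µL ledgers) use conventional half-up.
    """
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))
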