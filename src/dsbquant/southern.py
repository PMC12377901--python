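"""Southern-blot densitometry arithmetic for DSB quantification.

After restriction digestion, blotting and hybridization with probes flanking
the break site, each lane shows four bands: the full-length allele, the
contracted allele, the 5′ break fragment and the 3′ break fragment. The
scanner reports a signal "volume" for each band and for a matched local
background region — eight readings U1–U8 per lane. Percentages are net
volumes over the net total.

Both break ends come from the same molecules, so the 5′ and 3′ percentages
should agree; with chemiluminescent (DIG) detection the response is not
always linear and they can diverge, which :func:`end_agreement` flags.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

from ._util import ClampWarning, ValidationError, round_half_up

_BANDS = (
    ("full_length", "u1", "u2"),
    ("contracted", "u3", "u4"),
    ("5prime_dsb", "u5", "u6"),
    ("3prime_dsb", "u7", "u8"),
)


@dataclass(frozen=True)
class LaneVolumes:
    """The eight densitometry readings for one lane (arbitrary scanner units).

    Odd-numbered fields are band signals, even-numbered the matched local
    backgrounds: u1/u2 full-length allele, u3/u4 contracted allele, u5/u6
    5′ break, u7/u8 3′ break.
    """

    u1: float
    u2: float
    u3: float
    u4: float
    u5: float
    u6: float
    u7: float
    u8: float
    sample_id: str = ""

    def __post_init__(self) -> None:
        for name in ("u1", "u2", "u3", "u4", "u5", "u6", "u7", "u8"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be non-negative")


@dataclass(frozen=True)
class LaneResult:
    """Net total volume and band percentages for one lane."""

    total_volume: float
    pct_full_length: float
    pct_contracted: float
    pct_5prime_dsb: float
    pct_3prime_dsb: float
    sample_id: str = ""

    @property
    def end_discrepancy(self) -> float:
        """|5′ − 3′| break percentage, in percentage points."""
        return abs(self.pct_5prime_dsb - self.pct_3prime_dsb)

    def as_report(self, decimals: int = 1) -> dict[str, float]:
        return {
            "total_volume": self.total_volume,
            "pct_full_length": round_half_up(self.pct_full_length, decimals),
            "pct_contracted": round_half_up(self.pct_contracted, decimals),
            "pct_5prime_dsb": round_half_up(self.pct_5prime_dsb, decimals),
            "pct_3prime_dsb": round_half_up(self.pct_3prime_dsb, decimals),
        }


def quantify_lane(volumes: LaneVolumes, clamp: bool = False) -> LaneResult:
    """Background-subtract the four bands and express each as % of the total.

    A background exceeding its band signal is an error by default — it never
    occurs on a sound scan and silently zeroing it would hide scanner misuse.
    With ``clamp=True`` such a net volume is set to 0 with a warning instead.
    """
    nets = {}
    for band, sig, bg in _BANDS:
        net = getattr(volumes, sig) - getattr(volumes, bg)
        if net < 0:
            if not clamp:
                raise ValidationError(
                    f"background {bg} exceeds signal {sig} for band {band!r}"
                )
            warnings.warn(
                f"band {band!r}: background exceeds signal; net clamped to 0",
                ClampWarning,
                stacklevel=2,
            )
            net = 0.0
        nets[band] = net
    total = sum(nets.values())
    if total <= 0:
        raise ValidationError("total net volume is zero; nothing to quantify")
    return LaneResult(
        total_volume=total,
        pct_full_length=100.0 * nets["full_length"] / total,
        pct_contracted=100.0 * nets["contracted"] / total,
        pct_5prime_dsb=100.0 * nets["5prime_dsb"] / total,
        pct_3prime_dsb=100.0 * nets["3prime_dsb"] / total,
        sample_id=volumes.sample_id,
    )


def end_agreement(result: LaneResult, tolerance: float = 5.0) -> bool:
    """Whether the 5′ and 3′ break quantifications agree within ``tolerance``
    percentage points; a failure suggests non-linear detection response."""
    if tolerance < 0:
        raise ValidationError("tolerance must be non-negative")
    return result.end_discrepancy <= tolerance
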