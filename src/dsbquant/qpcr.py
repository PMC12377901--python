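"""DSB-qPCR support: standard mixtures, standard-curve fit/inversion, melt
curves.

The qPCR route tails free 3′ DNA ends with polyC and amplifies across the
break, so the cycle threshold (Ct) falls as the broken fraction rises. Ct is
not a percentage: a standard curve is built from mixtures of fully digested
and undigested genomic DNA at known percent-DSB, a trendline of mean Ct on
percent DSB is fitted, and unknown samples are read off by inverting the
line. Melt-curve peak counting supports dye-concentration troubleshooting
(a second melt peak indicates off-target product and disqualifies the run).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from ._util import ExtrapolationWarning, ValidationError


@dataclass(frozen=True)
class StandardPoint:
    """One standard mixture: its designed percent DSB and replicate Cts."""

    pct_dsb: float
    ct_replicates: tuple[float, ...]
    sybr_concentration: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.pct_dsb <= 100.0:
            raise ValidationError("pct_dsb must lie in [0, 100]")
        if len(self.ct_replicates) == 0:
            raise ValidationError("at least one Ct replicate required")
        if any(ct <= 0 for ct in self.ct_replicates):
            raise ValidationError("Ct values must be positive")

    @property
    def mean_ct(self) -> float:
        return float(np.mean(self.ct_replicates))


@dataclass(frozen=True)
class StandardCurve:
    """Least-squares trendline of mean Ct against percent DSB.

    ``correlation`` is |r| (the magnitude usually quoted next to a
    trendline); the signed Pearson r and r² are also carried. ``log_percent``
    records whether the fit used log10(percent) as the abscissa.
    """

    slope: float
    intercept: float
    correlation: float
    pearson_r: float
    r_squared: float
    n_points: int
    log_percent: bool = False


@dataclass(frozen=True)
class MixtureVolumes:
    """Pipetting recipe for one standard: volumes in µL."""

    digested: float
    undigested: float
    diluent: float
    target_pct: float


@dataclass(frozen=True)
class MeltCurve:
    """A melt trace: fluorescence on a strictly increasing temperature grid."""

    temperatures: tuple[float, ...]
    fluorescence: tuple[float, ...]
    sybr_concentration: float | None = None

    def __post_init__(self) -> None:
        if len(self.temperatures) != len(self.fluorescence):
            raise ValidationError("temperature and fluorescence lengths differ")
        if np.any(np.diff(self.temperatures) <= 0):
            raise ValidationError("temperatures must be strictly increasing")


def design_mixture(
    target_pct: float,
    final_concentration: float,
    final_volume: float,
    digested_stock: float,
    undigested_stock: float,
) -> MixtureVolumes:
    """Volumes of digested/undigested stock and diluent for one standard.

    Mass balance: the digested DNA mass fraction equals ``target_pct``/100
    and the total DNA mass equals ``final_concentration · final_volume``
    (concentrations in ng/µL, volumes in µL).
    """
    if not 0.0 <= target_pct <= 100.0:
        raise ValidationError("target_pct must lie in [0, 100]")
    if final_concentration <= 0 or final_volume <= 0:
        raise ValidationError("final concentration and volume must be positive")
    total_mass = final_concentration * final_volume
    masses = {
        "digested": total_mass * target_pct / 100.0,
        "undigested": total_mass * (100.0 - target_pct) / 100.0,
    }
    stocks = {"digested": digested_stock, "undigested": undigested_stock}
    vols = {}
    for name, mass in masses.items():
        if mass > 0 and stocks[name] < final_concentration:
            raise ValidationError(
                f"{name} stock ({stocks[name]:g} ng/µL) is more dilute than "
                f"the final concentration ({final_concentration:g} ng/µL); "
                f"mixture infeasible"
            )
        vols[name] = mass / stocks[name] if mass > 0 else 0.0
    diluent = final_volume - vols["digested"] - vols["undigested"]
    return MixtureVolumes(
        digested=vols["digested"],
        undigested=vols["undigested"],
        diluent=diluent,
        target_pct=target_pct,
    )


def fit_standard_curve(
    points: list[StandardPoint], log_percent: bool = False
) -> StandardCurve:
    """Ordinary least squares of mean Ct on percent DSB.

    With ``log_percent=True`` the abscissa is log10(percent), which requires
    all standards to have pct_dsb > 0.
    """
    if len(points) < 2:
        raise ValidationError("at least two standards required")
    x = np.array([p.pct_dsb for p in points], dtype=float)
    y = np.array([p.mean_ct for p in points], dtype=float)
    if np.unique(x).size < 2:
        raise ValidationError("standards must span at least two distinct pct_dsb")
    if log_percent:
        if np.any(x <= 0):
            raise ValidationError("log-percent fit requires pct_dsb > 0")
        x = np.log10(x)
    fit = stats.linregress(x, y)
    return StandardCurve(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        correlation=abs(float(fit.rvalue)),
        pearson_r=float(fit.rvalue),
        r_squared=float(fit.rvalue) ** 2,
        n_points=len(points),
        log_percent=log_percent,
    )


def invert_curve(curve: StandardCurve, ct: float) -> float:
    """Read a percent-DSB estimate off the standard curve for an observed Ct.

    Estimates outside [0, 100] are returned as-is with an
    :class:`ExtrapolationWarning`.
    """
    if curve.slope == 0:
        raise ValidationError("cannot invert a flat standard curve")
    x = (ct - curve.intercept) / curve.slope
    pct = 10.0**x if curve.log_percent else x
    if not 0.0 <= pct <= 100.0:
        warnings.warn(
            f"inverted estimate {pct:.2f}% lies outside [0, 100]; Ct is "
            f"beyond the calibrated range",
            ExtrapolationWarning,
            stacklevel=2,
        )
    return float(pct)


def melt_peaks(
    curve: MeltCurve, prominence: float = 0.1, window: int = 5
) -> list[float]:
    """Peak temperatures of the negative-derivative melt profile.

    Fluorescence is smoothed with a centered moving average (``window``
    points), −dF/dT is taken by central differences, and local maxima above
    ``prominence`` times the derivative maximum are returned. One peak means
    a single product; two peaks indicate an off-target species.
    """
    if len(curve.temperatures) < 10:
        raise ValidationError("need at least 10 temperature points")
    if not 0.0 < prominence <= 1.0:
        raise ValidationError("prominence must lie in (0, 1]")
    t = np.asarray(curve.temperatures, dtype=float)
    f = np.asarray(curve.fluorescence, dtype=float)
    if window > 1:
        kernel = np.ones(window) / window
        pad = window // 2
        f = np.convolve(np.pad(f, pad, mode="edge"), kernel, mode="valid")[: t.size]
    deriv = -np.gradient(f, t)
    top = deriv.max()
    if top <= 0:
        return []
    idx, _ = signal.find_peaks(deriv, height=prominence * top)
    return [float(t[i]) for i in idx]
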