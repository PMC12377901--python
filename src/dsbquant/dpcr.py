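"""Poisson-law quantification of digital-PCR droplet counts and the
broken-fraction arithmetic for a CTG-repeat locus.

A digital-PCR chip partitions the reaction into ~25,000 droplets. With a
mean of λ target copies per droplet, occupancy is Poisson, so the fraction
of empty droplets is e^(−λ) and λ is recovered from k positive droplets out
of N analyzable ones as λ = −ln(1 − k/N). Dividing by the effective droplet
volume v (µL) gives the absolute concentration C = λ/v in copies/µL.

The double-strand-break (DSB) assay multiplexes two targets in one
reaction:

* ``JEM1`` — a single-copy control gene that is never cut, detected by a
  sequence-specific HEX probe (green channel) and, like every amplicon, by
  the intercalating EvaGreen dye (blue channel, upper population);
* the CTG-repeat locus — amplifiable only when unbroken, detected by
  EvaGreen alone (blue channel, middle population).

The blue channel therefore shows a double positive population whose total
concentration is C(unbroken CTG) + C(JEM1); subtracting the JEM1 reference
concentration leaves the unbroken-CTG concentration, and the percentage of
broken molecules follows as 100 − 100·C(unbroken CTG)/C(JEM1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Literal

from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from ._util import (
    ClampWarning,
    ConsistencyWarning,
    GatingInconsistencyError,
    SaturationError,
    ValidationError,
    round_half_up,
)

#: Effective droplet volume in µL, back-derived from the self-consistency of
#: vendor-reported concentrations (all gated populations of one published
#: chip yield the same volume within 0.2%). Absorbs any dead-volume or
#: pre-reaction dilution correction the vendor software applies.
DEFAULT_DROPLET_VOLUME_UL = 6.236e-4

_CI_METHODS = {"wilson": "wilson", "clopper-pearson": "beta"}


@dataclass(frozen=True)
class DropletCounts:
    """Positive/total droplet tally for one gated population.

    Parameters
    ----------
    n_total
        Number of analyzable droplets N on the chip.
    n_positive
        Number of droplets k falling in the gated population.
    population_label
        Free-text description, e.g. ``"blue double population"``.
    """

    n_total: int
    n_positive: int
    population_label: str = ""

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise ValidationError("n_total must be positive")
        if not 0 <= self.n_positive <= self.n_total:
            raise ValidationError(
                f"n_positive must lie in [0, n_total]; got "
                f"{self.n_positive}/{self.n_total}"
            )

    @property
    def fraction_positive(self) -> float:
        return self.n_positive / self.n_total


@dataclass(frozen=True)
class PoissonEstimate:
    """Mean copies per droplet and, once a volume is supplied, copies/µL."""

    lambda_hat: float
    lambda_ci: tuple[float, float]
    confidence_level: float
    droplet_volume: float | None = None
    concentration: float | None = None
    concentration_ci: tuple[float, float] | None = None


@dataclass(frozen=True)
class DsbResult:
    """Ledger of the DSB quantification for one chip.

    Concentrations in copies/µL; percentages of the total CTG molecules.
    ``pct_unbroken + pct_broken == 100`` exactly.
    """

    c_blue_total: float
    c_jem1: float
    c_ctg_unbroken: float
    pct_unbroken: float
    pct_broken: float
    consistency_delta: float
    pct_unbroken_ci: tuple[float, float]
    pct_broken_ci: tuple[float, float]
    c_blue_jem1: float
    c_green_jem1: float
    droplet_volume: float
    confidence_level: float
    warnings: tuple[str, ...] = ()

    def as_report(self, decimals: int = 1) -> dict[str, float]:
        """Rounded values as the vendor ledger prints them."""
        return {
            "c_blue_total_cp_per_ul": round_half_up(self.c_blue_total, decimals),
            "c_jem1_cp_per_ul": round_half_up(self.c_jem1, decimals),
            "c_ctg_unbroken_cp_per_ul": round_half_up(self.c_ctg_unbroken, decimals),
            "pct_unbroken": round_half_up(self.pct_unbroken, decimals),
            "pct_broken": round_half_up(self.pct_broken, decimals),
        }


def estimate_lambda(
    counts: DropletCounts,
    confidence_level: float = 0.95,
    ci_method: Literal["wilson", "clopper-pearson"] = "wilson",
) -> PoissonEstimate:
    """Estimate mean copies per droplet from a positive-droplet tally.

    λ̂ = −ln(1 − k/N), the maximum-likelihood estimate under Poisson
    occupancy (a droplet is positive iff it received ≥1 copy, so k is
    binomial with success probability 1 − e^(−λ)). The confidence interval
    is a binomial interval on k/N (Wilson by default) mapped through the
    same logarithm.

    Raises
    ------
    SaturationError
        If every droplet is positive (k = N): λ is unbounded above.
    ValidationError
        For invalid counts or confidence level.
    """
    if not 0.0 < confidence_level < 1.0:
        raise ValidationError("confidence_level must lie in (0, 1)")
    if ci_method not in _CI_METHODS:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    k, n = counts.n_positive, counts.n_total
    if k == n:
        raise SaturationError(
            f"all {n} droplets positive; concentration not estimable "
            f"(dilute the sample)"
        )
    lam = -math.log1p(-k / n)
    p_lo, p_hi = proportion_confint(
        k, n, alpha=1.0 - confidence_level, method=_CI_METHODS[ci_method]
    )
    p_lo = min(max(float(p_lo), 0.0), 1.0 - 1e-15)
    p_hi = min(max(float(p_hi), 0.0), 1.0 - 1e-15)
    lo, hi = -math.log1p(-p_lo), -math.log1p(-p_hi)
    return PoissonEstimate(
        lambda_hat=lam,
        lambda_ci=(min(lo, lam), max(hi, lam)),
        confidence_level=confidence_level,
    )


def lambda_to_concentration(
    estimate: PoissonEstimate, droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
) -> PoissonEstimate:
    """Convert copies per droplet to copies/µL given the droplet volume."""
    if not droplet_volume > 0:
        raise ValidationError("droplet_volume must be positive")
    return replace(
        estimate,
        droplet_volume=droplet_volume,
        concentration=estimate.lambda_hat / droplet_volume,
        concentration_ci=(
            estimate.lambda_ci[0] / droplet_volume,
            estimate.lambda_ci[1] / droplet_volume,
        ),
    )


def calibrate_droplet_volume(
    counts: DropletCounts, reported_concentration: float
) -> float:
    """Back-derive the effective droplet volume from a vendor-reported row.

    Given a gated population with k positive of N droplets that the vendor
    software reported as C copies/µL, the volume it implicitly used is
    v = −ln(1 − k/N) / C. Useful to stay consistent with instrument output
    whose nominal volume is not documented.
    """
    if counts.n_positive == 0 or counts.n_positive == counts.n_total:
        raise ValidationError(
            "volume calibration needs 0 < n_positive < n_total"
        )
    if not reported_concentration > 0:
        raise ValidationError("reported_concentration must be positive")
    lam = -math.log1p(-counts.fraction_positive)
    return lam / reported_concentration


def _lambda_variance(counts: DropletCounts) -> float:
    """Variance of λ̂ by the delta method: var(p̂)/(1−p)² = p/((1−p)N)."""
    p = counts.fraction_positive
    return p / ((1.0 - p) * counts.n_total)


def quantify_dsb(
    blue_total: DropletCounts,
    blue_jem1: DropletCounts,
    green_jem1: DropletCounts,
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL,
    confidence_level: float = 0.95,
    jem1_reference: Literal["green", "blue"] = "green",
    consistency_tolerance: float = 0.05,
    ci_method: Literal["wilson", "clopper-pearson"] = "wilson",
) -> DsbResult:
    """Compute the broken-CTG percentage from the three gated populations.

    Parameters
    ----------
    blue_total
        The blue-channel double population (unbroken CTG + JEM1 droplets).
    blue_jem1
        The upper blue population (JEM1-containing droplets, gated by
        raising the blue threshold).
    green_jem1
        The green-channel (HEX probe) positive population.
    droplet_volume
        Effective droplet volume in µL.
    jem1_reference
        Which channel supplies the JEM1 reference concentration; the probe
        (green) is the default, the blue upper population the cross-check.
    consistency_tolerance
        Relative disagreement between the two JEM1 measurements above which
        a :class:`ConsistencyWarning` is emitted.

    Notes
    -----
    The unbroken-CTG concentration is the difference of two estimates made
    on the *same* droplets, with the JEM1 gate nested inside the blue total
    gate; the delta-method interval on log(C_ctg/C_jem1) therefore uses
    cov(λ̂_total, λ̂_ref) = var(λ̂_ref) (exact for nested indicator gates)
    and is approximate overall.
    """
    n = blue_total.n_total
    if not (blue_jem1.n_total == n and green_jem1.n_total == n):
        raise ValidationError("all counts must share the same n_total")
    if blue_total.n_positive < blue_jem1.n_positive:
        raise ValidationError(
            "blue double population cannot have fewer positives than its "
            "JEM1 sub-population"
        )
    if green_jem1.n_positive == 0:
        raise ValidationError(
            "no reference molecules: green-channel JEM1 count is zero"
        )
    if jem1_reference not in ("green", "blue"):
        raise ValidationError(f"unknown jem1_reference {jem1_reference!r}")

    est_total = lambda_to_concentration(
        estimate_lambda(blue_total, confidence_level, ci_method), droplet_volume
    )
    est_bjem1 = lambda_to_concentration(
        estimate_lambda(blue_jem1, confidence_level, ci_method), droplet_volume
    )
    est_gjem1 = lambda_to_concentration(
        estimate_lambda(green_jem1, confidence_level, ci_method), droplet_volume
    )

    ref_est, ref_counts = (
        (est_gjem1, green_jem1) if jem1_reference == "green" else (est_bjem1, blue_jem1)
    )
    if ref_est.lambda_hat == 0.0:
        raise ValidationError("no reference molecules in the chosen channel")

    lam_diff = est_total.lambda_hat - ref_est.lambda_hat
    var_total = _lambda_variance(blue_total)
    var_ref = _lambda_variance(ref_counts)
    # JEM1-positive droplets are a subset of blue-total positives, so
    # cov(λ̂_total, λ̂_ref) = var(λ̂_ref) and var(λ̂_total − λ̂_ref) simplifies.
    var_diff = max(var_total - var_ref, 0.0)
    # A negative difference means the gates are NOT nested as assumed, so the
    # clamp-vs-error decision uses the conservative independent-variance band.
    var_clamp = var_total + var_ref
    z = stats.norm.ppf(0.5 + confidence_level / 2.0)

    issued: list[str] = []
    if lam_diff < 0:
        if -lam_diff <= z * math.sqrt(var_clamp):
            msg = (
                "unbroken-CTG concentration slightly negative "
                f"({lam_diff / droplet_volume:.3g} cp/µL) but within the "
                f"{confidence_level:.0%} interval of zero; clamped to 0"
            )
            warnings.warn(msg, ClampWarning, stacklevel=2)
            issued.append(msg)
            lam_diff = 0.0
        else:
            raise GatingInconsistencyError(
                "reference concentration exceeds the blue double population "
                "beyond sampling error; check the gates"
            )

    c_ctg = lam_diff / droplet_volume
    pct_unbroken = 100.0 * lam_diff / ref_est.lambda_hat
    pct_broken = 100.0 - pct_unbroken

    if lam_diff > 0:
        # Delta method on log(λ_diff / λ_ref), with the nested-gate covariance.
        g_total = 1.0 / lam_diff
        g_ref = -est_total.lambda_hat / (lam_diff * ref_est.lambda_hat)
        var_log = (
            g_total**2 * var_total
            + g_ref**2 * var_ref
            + 2.0 * g_total * g_ref * var_ref
        )
        half = z * math.sqrt(max(var_log, 0.0))
        unb_lo = pct_unbroken * math.exp(-half)
        unb_hi = pct_unbroken * math.exp(half)
    else:
        unb_lo = 0.0
        unb_hi = 100.0 * z * math.sqrt(var_clamp) / ref_est.lambda_hat
    pct_unbroken_ci = (unb_lo, unb_hi)
    pct_broken_ci = (100.0 - unb_hi, 100.0 - unb_lo)

    assert est_gjem1.concentration is not None  # for type-checkers
    delta = abs(est_bjem1.concentration - est_gjem1.concentration) / (
        est_gjem1.concentration
    )
    if delta > consistency_tolerance:
        msg = (
            f"JEM1 concentrations disagree between channels by {delta:.1%} "
            f"(blue {est_bjem1.concentration:.1f} vs green "
            f"{est_gjem1.concentration:.1f} cp/µL); check the blue upper gate"
        )
        warnings.warn(msg, ConsistencyWarning, stacklevel=2)
        issued.append(msg)

    return DsbResult(
        c_blue_total=est_total.concentration,
        c_jem1=ref_est.concentration,
        c_ctg_unbroken=c_ctg,
        pct_unbroken=pct_unbroken,
        pct_broken=pct_broken,
        consistency_delta=delta,
        pct_unbroken_ci=pct_unbroken_ci,
        pct_broken_ci=pct_broken_ci,
        c_blue_jem1=est_bjem1.concentration,
        c_green_jem1=est_gjem1.concentration,
        droplet_volume=droplet_volume,
        confidence_level=confidence_level,
        warnings=tuple(issued),
    )
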