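"""Threshold gating of per-droplet fluorescence into the assay populations.

The blue (EvaGreen) channel carries up to three intensity classes —
negative, CTG-only, and JEM1-containing droplets — separated by two
thresholds; the green (HEX probe) channel is a simple ON/OFF split. Gating
is plain 1-D thresholding: the instrument's image segmentation happens
upstream and this module only consumes the per-droplet intensity table.

Automatic thresholds come from a deterministic one-dimensional k-means with
quantile-based initialization; manual thresholds always take precedence and
the provenance is recorded in the :class:`GateSet`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._util import ValidationError
from .dpcr import DropletCounts

REQUIRED_COLUMNS = ("droplet_id", "blue", "green")

#: Keys of the populations produced by :func:`gate_counts`.
POPULATIONS = ("blue_total", "blue_jem1", "blue_ctg_only", "green_jem1")


@dataclass(frozen=True)
class GateSet:
    """Intensity thresholds for one chip.

    ``blue_low`` separates negatives from CTG-only droplets, ``blue_high``
    separates CTG-only from JEM1-containing droplets (``None`` when only a
    single blue split was fitted), ``green_threshold`` is the probe ON/OFF
    cut. A droplet is positive when its intensity is strictly above the
    threshold.
    """

    blue_low: float
    green_threshold: float
    blue_high: float | None = None
    provenance: str = "manual"

    def __post_init__(self) -> None:
        if self.blue_high is not None and not self.blue_low < self.blue_high:
            raise ValidationError("blue_low must be below blue_high")


@dataclass(frozen=True)
class CrossChannelReport:
    """Droplets positive in green but negative in blue (physically forbidden:
    every probe-positive droplet also contains EvaGreen-stained amplicon)."""

    violating_ids: tuple[int, ...]
    n_green_positive: int
    violation_fraction: float

    @property
    def n_violations(self) -> int:
        return len(self.violating_ids)


def validate_droplet_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the droplet table schema and basic invariants."""
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValidationError(f"droplet table missing column(s): {missing}")
    if len(table) == 0:
        raise ValidationError("droplet table is empty")
    if table["droplet_id"].duplicated().any():
        raise ValidationError("droplet_id values must be unique")
    for col in ("blue", "green") + (("red",) if "red" in table.columns else ()):
        if not np.isfinite(table[col].to_numpy(dtype=float)).all():
            raise ValidationError(f"non-finite intensities in channel {col!r}")
    return table


def filter_by_fill_control(table: pd.DataFrame, red_floor: float) -> pd.DataFrame:
    """Drop droplets whose Alexa 647 fill-control intensity is below a floor.

    Optional droplet QC; by default no filtering is applied anywhere.
    """
    if "red" not in table.columns:
        raise ValidationError("no 'red' channel in the droplet table")
    return table[table["red"].to_numpy(dtype=float) >= red_floor].reset_index(
        drop=True
    )


def _kmeans_1d(values: np.ndarray, k: int, channel: str, n_iter: int = 100):
    """Deterministic 1-D k-means; returns sorted cluster centers.

    Centers are initialized at fixed quantiles, data are sorted internally
    (hence order-independent), assignment boundaries are midpoints between
    adjacent centers, and ties fall to the lower cluster.
    """
    x = np.sort(values.astype(float))
    if x[0] == x[-1]:
        raise ValidationError(
            f"cannot fit thresholds on channel {channel!r}: all intensities "
            f"identical ({x[0]:g})"
        )
    quantiles = {2: (25.0, 75.0), 3: (17.0, 50.0, 83.0)}[k]
    centers = np.percentile(x, quantiles)
    if np.any(np.diff(centers) <= 0):
        raise ValidationError(
            f"channel {channel!r}: fewer than {k} populations resolvable "
            f"(degenerate quantile initialization)"
        )
    csum = np.concatenate([[0.0], np.cumsum(x)])
    for _ in range(n_iter):
        boundaries = (centers[:-1] + centers[1:]) / 2.0
        # side='right' puts a droplet exactly on a boundary in the lower cluster
        splits = np.concatenate([[0], np.searchsorted(x, boundaries, side="right"),
                                 [x.size]])
        counts = np.diff(splits)
        if np.any(counts == 0):
            raise ValidationError(
                f"channel {channel!r}: fewer than {k} populations resolvable "
                f"(a cluster emptied during fitting)"
            )
        new_centers = (csum[splits[1:]] - csum[splits[:-1]]) / counts
        if np.allclose(new_centers, centers, rtol=0.0, atol=1e-12):
            centers = new_centers
            break
        centers = new_centers
    return centers


def fit_thresholds(table: pd.DataFrame, n_blue_populations: int = 3) -> GateSet:
    """Fit blue and green thresholds by deterministic 1-D clustering.

    ``n_blue_populations`` is 3 for the duplex assay (negative / CTG-only /
    JEM1) or 2 when only one blue split is wanted. The green channel is
    always split in two. Thresholds are placed at midpoints between adjacent
    cluster centers.
    """
    validate_droplet_table(table)
    if len(table) < 100:
        raise ValidationError("need at least 100 droplets to fit thresholds")
    if n_blue_populations not in (2, 3):
        raise ValidationError("n_blue_populations must be 2 or 3")
    blue_centers = _kmeans_1d(
        table["blue"].to_numpy(), n_blue_populations, channel="blue"
    )
    green_centers = _kmeans_1d(table["green"].to_numpy(), 2, channel="green")
    mids = (blue_centers[:-1] + blue_centers[1:]) / 2.0
    return GateSet(
        blue_low=float(mids[0]),
        blue_high=float(mids[1]) if n_blue_populations == 3 else None,
        green_threshold=float(np.mean(green_centers)),
        provenance="auto",
    )


def gate_counts(table: pd.DataFrame, gates: GateSet) -> dict[str, DropletCounts]:
    """Tally the gated populations of the duplex assay.

    Returns counts for the blue double population (above ``blue_low``), its
    JEM1 upper part (above ``blue_high``), the CTG-only middle part, and the
    green-positive population, all with ``n_total`` equal to the table size.
    The blue total always equals JEM1 + CTG-only by construction.
    """
    validate_droplet_table(table)
    if gates.blue_high is None:
        raise ValidationError(
            "gate_counts needs both blue thresholds; fit with "
            "n_blue_populations=3 or set blue_high manually"
        )
    n = len(table)
    blue = table["blue"].to_numpy(dtype=float)
    green = table["green"].to_numpy(dtype=float)
    k_total = int((blue > gates.blue_low).sum())
    k_upper = int((blue > gates.blue_high).sum())
    k_green = int((green > gates.green_threshold).sum())
    return {
        "blue_total": DropletCounts(n, k_total, "blue double population"),
        "blue_jem1": DropletCounts(n, k_upper, "blue upper population (JEM1)"),
        "blue_ctg_only": DropletCounts(
            n, k_total - k_upper, "blue middle population (unbroken CTG)"
        ),
        "green_jem1": DropletCounts(n, k_green, "green JEM1 (HEX probe)"),
    }


def cross_channel_check(table: pd.DataFrame, gates: GateSet) -> CrossChannelReport:
    """Find droplets ON in green but OFF in blue.

    Every probe-positive droplet contains an amplified JEM1 copy and must
    also fluoresce in the EvaGreen channel, so any violation indicates a
    gating or signal problem. Returns the offending droplet ids and the
    violation fraction among green-positive droplets (0 when none are
    green-positive).
    """
    validate_droplet_table(table)
    blue = table["blue"].to_numpy(dtype=float)
    green = table["green"].to_numpy(dtype=float)
    green_on = green > gates.green_threshold
    violations = green_on & (blue <= gates.blue_low)
    ids = tuple(int(i) for i in table.loc[violations, "droplet_id"])
    n_green = int(green_on.sum())
    return CrossChannelReport(
        violating_ids=ids,
        n_green_positive=n_green,
        violation_fraction=len(ids) / n_green if n_green else 0.0,
    )
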