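"""Synthetic droplet-partition data with known ground truth.

The generator reproduces the partitioning model the quantification assumes:
each droplet independently receives Poisson(c·v) copies of the control gene
JEM1 and of the CTG locus, each CTG copy is broken with probability f
(independently), and the droplet's latent class follows from its contents —
JEM1-containing if it holds ≥1 JEM1 copy, CTG-only if it holds none but ≥1
*unbroken* CTG copy, negative otherwise. Broken CTG copies never amplify
and contribute no signal.

Fluorescence is endpoint-plateau: intensity depends on the latent class
only, not on the copy number, giving the two discrete positive populations
seen in the blue channel. Intensities are Gaussian around per-class means
in arbitrary units chosen for clean separation; tighten them to study
gating under overlap.

Defaults mirror a published chip: 23,527 analyzable droplets, a 6.236e-4 µL
droplet volume, 206.6 copies/µL of each locus and a broken fraction of
0.346.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from ._util import ValidationError
from .dpcr import (
    DEFAULT_DROPLET_VOLUME_UL,
    DsbResult,
    quantify_dsb,
)
from .gating import fit_thresholds, gate_counts

#: Latent droplet classes, in increasing blue-intensity order.
CLASS_LABELS = ("negative", "ctg_only", "jem1")


@dataclass(frozen=True)
class IntensityModel:
    """Per-class Gaussian intensity parameters (arbitrary units)."""

    blue_means: tuple[float, float, float] = (1_000.0, 8_000.0, 20_000.0)
    blue_sd: float = 600.0
    green_means: tuple[float, float] = (1_000.0, 10_000.0)
    green_sd: float = 600.0

    def __post_init__(self) -> None:
        if not (self.blue_means[0] < self.blue_means[1] < self.blue_means[2]):
            raise ValidationError(
                "blue class means must increase: negative < CTG-only < JEM1"
            )
        if not self.green_means[0] < self.green_means[1]:
            raise ValidationError("green negative mean must be below positive")
        if self.blue_sd <= 0 or self.green_sd <= 0:
            raise ValidationError("intensity sds must be positive")


@dataclass(frozen=True)
class SimConfig:
    """Ground-truth parameters of one simulated chip."""

    n_droplets: int = 23_527
    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    c_jem1: float = 206.6
    c_ctg_total: float = 206.6
    fraction_broken: float = 0.346
    intensities: IntensityModel = field(default_factory=IntensityModel)
    seed: int = 0
    linked: bool = False

    def __post_init__(self) -> None:
        if self.n_droplets <= 0:
            raise ValidationError("n_droplets must be positive")
        if self.droplet_volume <= 0:
            raise ValidationError("droplet_volume must be positive")
        if self.c_jem1 < 0 or self.c_ctg_total < 0:
            raise ValidationError("concentrations must be non-negative")
        if not 0.0 <= self.fraction_broken <= 1.0:
            raise ValidationError("fraction_broken must lie in [0, 1]")
        if self.linked and self.c_jem1 != self.c_ctg_total:
            raise ValidationError(
                "linked mode co-assigns one JEM1 and one CTG copy per genome, "
                "so c_jem1 must equal c_ctg_total"
            )


@dataclass(frozen=True)
class SimTruth:
    """Latent per-droplet state: copy counts and realized class."""

    table: pd.DataFrame  # droplet_id, jem1_copies, ctg_unbroken, ctg_broken, class
    config: SimConfig


def simulate(config: SimConfig) -> tuple[pd.DataFrame, SimTruth]:
    """Draw one chip: a droplet fluorescence table plus its ground truth.

    Reproducible bit-for-bit for a fixed config (including seed). In
    ``linked`` mode the two loci co-partition (one JEM1 and one CTG copy per
    genome) instead of partitioning independently.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_droplets
    v = config.droplet_volume
    if config.linked:
        genomes = rng.poisson(config.c_jem1 * v, size=n)
        jem1 = genomes
        ctg_total = genomes.copy()
    else:
        jem1 = rng.poisson(config.c_jem1 * v, size=n)
        ctg_total = rng.poisson(config.c_ctg_total * v, size=n)
    broken = rng.binomial(ctg_total, config.fraction_broken)
    unbroken = ctg_total - broken

    cls = np.zeros(n, dtype=np.int8)
    cls[(jem1 == 0) & (unbroken >= 1)] = 1
    cls[jem1 >= 1] = 2

    im = config.intensities
    blue = np.asarray(im.blue_means)[cls] + rng.normal(0.0, im.blue_sd, size=n)
    green = np.asarray(im.green_means)[(jem1 >= 1).astype(np.int8)] + rng.normal(
        0.0, im.green_sd, size=n
    )

    table = pd.DataFrame(
        {"droplet_id": np.arange(n, dtype=np.int64), "blue": blue, "green": green}
    )
    truth = pd.DataFrame(
        {
            "droplet_id": np.arange(n, dtype=np.int64),
            "jem1_copies": jem1,
            "ctg_unbroken": unbroken,
            "ctg_broken": broken,
            "class": np.asarray(CLASS_LABELS)[cls],
        }
    )
    return table, SimTruth(table=truth, config=config)


@dataclass(frozen=True)
class RecoveryReport:
    """Bias and interval coverage of the broken-fraction estimator."""

    true_pct_broken: float
    mean_pct_broken: float
    bias: float
    sd_pct_broken: float
    coverage: float
    n_replicates: int
    estimates: tuple[float, ...]


def recover(
    config: SimConfig, replicates: int, confidence_level: float = 0.95
) -> RecoveryReport:
    """Close the loop: simulate → fit thresholds → gate → quantify, repeatedly.

    Each replicate gets an independent child seed derived from
    ``config.seed``. Reports the mean and spread of the recovered percent
    broken against the configured truth, and the empirical coverage of the
    per-replicate confidence intervals.
    """
    if replicates < 1:
        raise ValidationError("replicates must be >= 1")
    child_seeds = np.random.SeedSequence(config.seed).generate_state(replicates)
    true_pct = 100.0 * config.fraction_broken
    estimates = np.empty(replicates)
    covered = 0
    for i, s in enumerate(child_seeds):
        table, _ = simulate(replace(config, seed=int(s)))
        gates = fit_thresholds(table, n_blue_populations=3)
        counts = gate_counts(table, gates)
        result: DsbResult = quantify_dsb(
            counts["blue_total"],
            counts["blue_jem1"],
            counts["green_jem1"],
            droplet_volume=config.droplet_volume,
            confidence_level=confidence_level,
        )
        estimates[i] = result.pct_broken
        lo, hi = result.pct_broken_ci
        covered += int(lo <= true_pct <= hi)
    return RecoveryReport(
        true_pct_broken=true_pct,
        mean_pct_broken=float(estimates.mean()),
        bias=float(estimates.mean() - true_pct),
        sd_pct_broken=float(estimates.std(ddof=1)) if replicates > 1 else 0.0,
        coverage=covered / replicates,
        n_replicates=replicates,
        estimates=tuple(float(e) for e in estimates),
    )
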