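"""CSV/JSON readers and writers and the run configuration.

CSV dialect: comma-separated, UTF-8, dot decimal separator, mandatory header
row. Scanner exports often print thousands separators inside numbers
("1 595 996"); plain, non-breaking and narrow spaces and commas are stripped
from numeric fields on read.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import pandas as pd

from ._util import ValidationError
from .dpcr import DEFAULT_DROPLET_VOLUME_UL, DropletCounts, DsbResult
from .gating import GateSet, validate_droplet_table
from .qpcr import MeltCurve, StandardCurve, StandardPoint
from .simulate import IntensityModel, SimConfig, SimTruth
from .southern import LaneVolumes

_SEPARATORS = str.maketrans("", "", "   ,")

COUNTS_COLUMNS = ("population_label", "n_total", "n_positive")
LANE_COLUMNS = ("sample_id", "u1", "u2", "u3", "u4", "u5", "u6", "u7", "u8")


def _clean_number(value: Any) -> float:
    if isinstance(value, str):
        value = value.translate(_SEPARATORS)
    return float(value)


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{what}: missing column(s) {missing}; found {list(df.columns)}; "
            f"expected header {','.join(required)}"
        )


# ---------------------------------------------------------------------------
# dPCR inputs


def read_counts_csv(path: str | Path) -> dict[str, DropletCounts]:
    """Read pre-gated counts: header ``population_label,n_total,n_positive``.

    Returns a mapping keyed by population label. The dPCR pipeline expects
    the labels ``blue_total``, ``blue_jem1`` and ``green_jem1``.
    """
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, COUNTS_COLUMNS, f"counts CSV {path}")
    out: dict[str, DropletCounts] = {}
    for _, row in df.iterrows():
        label = str(row["population_label"]).strip()
        out[label] = DropletCounts(
            n_total=int(_clean_number(row["n_total"])),
            n_positive=int(_clean_number(row["n_positive"])),
            population_label=label,
        )
    return out


def read_droplet_csv(path: str | Path) -> pd.DataFrame:
    """Read a per-droplet table: header ``droplet_id,blue,green[,red]``."""
    df = pd.read_csv(path)
    try:
        return validate_droplet_table(df)
    except ValidationError as exc:
        raise ValidationError(f"droplet CSV {path}: {exc}") from exc


def write_droplet_csv(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, index=False, float_format="%.4f")


def write_truth_csv(truth: SimTruth, path: str | Path) -> None:
    truth.table.to_csv(path, index=False)


def true_pct_broken(truth_table: pd.DataFrame) -> float:
    """Realized percent broken CTG molecules in a simulator truth table."""
    broken = float(truth_table["ctg_broken"].sum())
    total = broken + float(truth_table["ctg_unbroken"].sum())
    if total == 0:
        raise ValidationError("truth table contains no CTG molecules")
    return 100.0 * broken / total


def write_dsb_report(
    result: DsbResult,
    prefix: str | Path,
    gates: GateSet | None = None,
    extra: dict[str, Any] | None = None,
) -> tuple[Path, Path]:
    """Write a quantification ledger as ``<prefix>.csv`` and ``<prefix>.json``.

    The CSV mirrors the instrument ledger (rounded values); the JSON carries
    both rounded and full-precision values, intervals, thresholds and any
    warnings.
    """
    prefix = Path(prefix)
    rounded = result.as_report()
    csv_path = prefix.with_suffix(".csv")
    json_path = prefix.with_suffix(".json")
    pd.DataFrame([rounded]).to_csv(csv_path, index=False)
    payload: dict[str, Any] = {
        "report": rounded,
        "full_precision": {
            "c_blue_total": result.c_blue_total,
            "c_jem1": result.c_jem1,
            "c_ctg_unbroken": result.c_ctg_unbroken,
            "pct_unbroken": result.pct_unbroken,
            "pct_broken": result.pct_broken,
            "consistency_delta": result.consistency_delta,
            "c_blue_jem1": result.c_blue_jem1,
            "c_green_jem1": result.c_green_jem1,
        },
        "pct_unbroken_ci": list(result.pct_unbroken_ci),
        "pct_broken_ci": list(result.pct_broken_ci),
        "droplet_volume_ul": result.droplet_volume,
        "confidence_level": result.confidence_level,
        "warnings": list(result.warnings),
    }
    if gates is not None:
        payload["gates"] = dataclasses.asdict(gates)
    if extra:
        payload.update(extra)
    json_path.write_text(json.dumps(payload, indent=2) + "\n")
    return csv_path, json_path


# ---------------------------------------------------------------------------
# Southern / qPCR inputs


def read_lanes_csv(path: str | Path) -> list[LaneVolumes]:
    """Read lane volumes: header ``sample_id,u1,...,u8``."""
    df = pd.read_csv(path, dtype=str)
    _require_columns(df, LANE_COLUMNS, f"lane CSV {path}")
    return [
        LaneVolumes(
            sample_id=str(row["sample_id"]),
            **{f"u{i}": _clean_number(row[f"u{i}"]) for i in range(1, 9)},
        )
        for _, row in df.iterrows()
    ]


def read_standards_csv(path: str | Path) -> list[StandardPoint]:
    """Read qPCR standards: header ``pct_dsb,ct``, one row per replicate."""
    df = pd.read_csv(path)
    _require_columns(df, ("pct_dsb", "ct"), f"standards CSV {path}")
    return [
        StandardPoint(pct_dsb=float(pct), ct_replicates=tuple(grp["ct"].astype(float)))
        for pct, grp in df.groupby("pct_dsb", sort=True)
    ]


def read_melt_csv(path: str | Path) -> list[MeltCurve]:
    """Read melt traces: header ``temperature,fluorescence[,sybr_x]``.

    Rows sharing a ``sybr_x`` value form one curve; without the column the
    file is one curve.
    """
    df = pd.read_csv(path)
    _require_columns(df, ("temperature", "fluorescence"), f"melt CSV {path}")
    groups = (
        [(None, df)] if "sybr_x" not in df.columns else df.groupby("sybr_x", sort=True)
    )
    curves = []
    for sybr, grp in groups:
        grp = grp.sort_values("temperature")
        curves.append(
            MeltCurve(
                temperatures=tuple(grp["temperature"].astype(float)),
                fluorescence=tuple(grp["fluorescence"].astype(float)),
                sybr_concentration=None if sybr is None else float(sybr),
            )
        )
    return curves


def standard_curve_to_dict(curve: StandardCurve) -> dict[str, Any]:
    return dataclasses.asdict(curve)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """Validated run-wide settings, loadable from JSON."""

    droplet_volume: float = DEFAULT_DROPLET_VOLUME_UL
    confidence_level: float = 0.95
    rounding: int = 1
    seed: int = 0
    end_agreement_tolerance: float = 5.0
    consistency_tolerance: float = 0.05
    jem1_reference: str = "green"
    blue_low: float | None = None
    blue_high: float | None = None
    green_threshold: float | None = None

    def __post_init__(self) -> None:
        if self.droplet_volume <= 0:
            raise ValidationError("droplet_volume must be positive")
        if not 0.0 < self.confidence_level < 1.0:
            raise ValidationError("confidence_level must lie in (0, 1)")
        if self.rounding < 0:
            raise ValidationError("rounding must be >= 0")
        if self.jem1_reference not in ("green", "blue"):
            raise ValidationError("jem1_reference must be 'green' or 'blue'")

    def manual_gates(self) -> GateSet | None:
        """Manual thresholds, if all required ones are configured."""
        if self.blue_low is None or self.green_threshold is None:
            return None
        return GateSet(
            blue_low=self.blue_low,
            blue_high=self.blue_high,
            green_threshold=self.green_threshold,
            provenance="manual",
        )


def load_run_config(path: str | Path) -> RunConfig:
    data = json.loads(Path(path).read_text())
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown run-config key(s): {sorted(unknown)}")
    return RunConfig(**data)


def load_sim_config(path: str | Path) -> SimConfig:
    """Load a simulator configuration from JSON (intensities nested)."""
    data = json.loads(Path(path).read_text())
    intens = data.pop("intensities", None)
    known = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown sim-config key(s): {sorted(unknown)}")
    if intens is not None:
        intens = {
            k: tuple(v) if isinstance(v, list) else v for k, v in intens.items()
        }
        data["intensities"] = IntensityModel(**intens)
    return SimConfig(**data)


def dump_sim_config(config: SimConfig, path: str | Path) -> None:
    data = dataclasses.asdict(config)
    Path(path).write_text(json.dumps(data, indent=2) + "\n")
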