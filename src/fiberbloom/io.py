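"""File formats and run configuration for the blooming analysis pipeline.

CSV observation tables, JSON/YAML run configuration (validated by a
strict schema: unknown keys are rejected), and machine- plus
human-readable reports.  Time columns may be given in seconds, hours or
days; everything is converted to seconds on read.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .diffusion import FiberGeometry, ReleaseCurve
from .inference import (
    DEFAULT_DENSITY_G_CM3,
    ROY_MOLAR_MASS_G_MOL,
    BeerLambertCalibration,
    FiberSample,
    absorbance_to_moles,
    bloomed_fraction,
)

__all__ = [
    "RunConfig",
    "SampleConfig",
    "CalibrationConfig",
    "read_observations",
    "observations_to_curve",
    "write_report",
]

_TIME_FACTORS = {"s": 1.0, "sec": 1.0, "seconds": 1.0, "h": 3600.0, "hr": 3600.0,
                 "hours": 3600.0, "d": 86400.0, "day": 86400.0, "days": 86400.0}


class CalibrationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    molar_absorptivity: float = Field(gt=0)
    path_length_cm: float = Field(default=1.0, gt=0)
    wavelength_nm: float | None = None

    def to_calibration(self) -> BeerLambertCalibration:
        return BeerLambertCalibration(
            self.molar_absorptivity, self.path_length_cm, self.wavelength_nm
        )


class SampleConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    radius_cm: float = Field(default=0.03, gt=0)
    length_cm: float = Field(default=2.0, gt=0)
    loading_wt_frac: float = Field(gt=0, lt=1)
    density_g_cm3: float = Field(default=DEFAULT_DENSITY_G_CM3, gt=0)
    molar_mass_g_mol: float = Field(default=ROY_MOLAR_MASS_G_MOL, gt=0)
    n_pieces: int = Field(default=1, gt=0)
    solvent_volume_L: float = Field(default=0.003, gt=0)

    def to_sample(self) -> FiberSample:
        return FiberSample(
            geometry=FiberGeometry(self.radius_cm, self.length_cm),
            loading_wt_frac=self.loading_wt_frac,
            density_g_cm3=self.density_g_cm3,
            molar_mass_g_mol=self.molar_mass_g_mol,
            n_pieces=self.n_pieces,
            solvent_volume_L=self.solvent_volume_L,
        )


class RunConfig(BaseModel):
    """Top-level pipeline configuration; unknown keys are rejected."""

    model_config = ConfigDict(extra="forbid")
    sample: SampleConfig | None = None
    calibration: CalibrationConfig | None = None
    raman_library: str | None = None
    cell_library: str | None = None
    shift_tol_cm1: float = Field(default=3.0, gt=0)
    len_tol: float = Field(default=0.02, gt=0)
    ang_tol_deg: float = Field(default=1.5, gt=0)
    max_w: float = Field(default=0.85, gt=0)
    seed: int = 0
    output_dir: str = "results"
    verbosity: int = 1

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yml", ".yaml") else json.loads(text)
        return cls.model_validate(data or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def read_observations(path: str | Path) -> pd.DataFrame:
    """Read a release-observation CSV into a typed table with time in seconds.

    Accepted time columns: ``time_s``, ``time_h``, ``time_d``, or
    ``time`` + ``time_unit``.  At least one of ``absorbance`` /
    ``fraction_w`` must be present; an optional boolean ``exclude``
    column flags points to drop from fits.  Malformed numeric rows are
    reported with their line numbers.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError(f"{path}: no observation rows")
    cols = set(df.columns)

    if "time_s" in cols:
        t = df["time_s"], 1.0
    elif "time_h" in cols:
        t = df["time_h"], 3600.0
    elif "time_d" in cols:
        t = df["time_d"], 86400.0
    elif "time" in cols:
        unit = str(df["time_unit"].iloc[0]).lower() if "time_unit" in cols else "s"
        if unit not in _TIME_FACTORS:
            raise ValueError(f"{path}: unknown time_unit {unit!r}")
        t = df["time"], _TIME_FACTORS[unit]
    else:
        raise ValueError(f"{path}: missing a time column (time_s/time_h/time_d/time)")
    if not ({"absorbance", "fraction_w"} & cols):
        raise ValueError(f"{path}: need an 'absorbance' or 'fraction_w' column")

    out = pd.DataFrame()
    series, factor = t
    numeric = pd.to_numeric(series, errors="coerce")
    bad = numeric.isna() & series.notna()
    if bad.any():
        lines = [str(i + 2) for i in bad[bad].index]  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable time values on line(s) {', '.join(lines)}")
    out["time_s"] = numeric * factor
    for col in ("absorbance", "fraction_w"):
        if col in cols:
            vals = pd.to_numeric(df[col], errors="coerce")
            bad = vals.isna() & df[col].notna()
            if bad.any():
                lines = [str(i + 2) for i in bad[bad].index]
                raise ValueError(f"{path}: unparseable {col} on line(s) {', '.join(lines)}")
            out[col] = vals
        else:
            out[col] = np.nan
    if "exclude" in cols:
        out["exclude"] = df["exclude"].map(
            lambda v: bool(v) and str(v).strip().lower() not in ("", "false", "0", "nan")
        ).astype(bool)
    else:
        out["exclude"] = False
    return out


def observations_to_curve(
    obs: pd.DataFrame,
    sample: FiberSample | None = None,
    calibration: BeerLambertCalibration | None = None,
) -> ReleaseCurve:
    """Build a ReleaseCurve from an observation table.

    Rows flagged ``exclude`` are dropped.  Rows without ``fraction_w``
    are converted from absorbance via Beer-Lambert, which requires the
    sample and calibration blocks.
    """
    keep = obs.loc[~obs["exclude"]].copy()
    w = keep["fraction_w"].to_numpy(dtype=float)
    need = np.isnan(w)
    if need.any():
        if sample is None or calibration is None:
            raise ValueError(
                "absorbance rows present: sample and calibration configs are required"
            )
        a = keep["absorbance"].to_numpy(dtype=float)
        if np.isnan(a[need]).any():
            raise ValueError("rows with neither fraction_w nor absorbance")
        conv = np.array(
            [
                bloomed_fraction(
                    absorbance_to_moles(ai, calibration, sample.solvent_volume_L), sample
                )
                for ai in a[need]
            ]
        )
        w[need] = conv
    order = np.argsort(keep["time_s"].to_numpy())
    return ReleaseCurve(
        times_s=keep["time_s"].to_numpy(dtype=float)[order], fractions=w[order]
    )


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _jsonify(getattr(obj, k)) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    return obj


def write_report(
    results: dict[str, Any],
    path: str | Path,
    config: RunConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write a JSON report plus a plain-text summary next to it.

    Every report records the package version, the configuration hash
    and the seed, so identical runs are byte-identical apart from
    nothing at all (no timestamps are written).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    doc = {
        "package_version": __version__,
        "config_hash": config.config_hash() if config is not None else None,
        "seed": seed if seed is not None else (config.seed if config else None),
        "results": _jsonify(results),
    }
    path.write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")
    lines = [f"fiberbloom {__version__} report", f"config_hash: {doc['config_hash']}",
             f"seed: {doc['seed']}", ""]
    for key, val in doc["results"].items():
        lines.append(f"{key}:")
        if isinstance(val, dict):
            lines.extend(f"  {k}: {v}" for k, v in val.items())
        else:
            lines.append(f"  {val}")
    path.with_suffix(".txt").write_text("\n".join(lines) + "\n")
    return path
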