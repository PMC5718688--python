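"""Run configuration (YAML, validated) and CSV file formats.

All tabular data are plain CSV with mandatory headers and ``#`` comment
lines; units are embedded in the column names (mm, degrees, mV, cGy).
Schemas:

* depth-dose curve:   ``depth_mm,relative_output`` (curve kind recorded in a
  leading ``# kind: ...`` comment);
* lateral profile:    ``x_mm,dose``;
* dose grid (long):   ``x_mm,y_mm,z_mm,dose``;
* detector readings:  ``id,x_mm,y_mm,z_mm,angle_deg,reading_mV``.

The run configuration is a single YAML document validated by pydantic with
unknown keys rejected; every field has a documented default, so a minimal
(empty) file resolves to the reference setup: 190 MeV-like pristine beam
peaking at 160 mm PE, 100 mm field radius with 1 mm pencil spacing, L-shaped
50/10 mm bolus, 1.4% reading noise and 0.72 mV/cGy sensitivity.
"""

from __future__ import annotations

import hashlib
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import pydantic
import yaml

from .beam_models import (
    DepthDoseCurve,
    SOBPSpec,
    fit_sobp_weights,
    make_pristine_bragg,
    synthesize_sobp,
)
from .correction import MOSFET_CF_MONO, MOSFET_CF_SOBP, PiecewiseCorrection
from .errors import ConfigError, CSVFormatError
from .pencil_beam import BolusGeometry, PencilBeamSet, SigmaModel, decompose_broad_beam
from .synthetic import MeasurementSet, NoiseModel

__all__ = [
    "RunConfig",
    "load_config",
    "save_config",
    "read_depth_dose",
    "write_depth_dose",
    "read_lateral_profile",
    "write_lateral_profile",
    "read_readings",
    "write_readings",
    "write_dose_grid",
    "write_run_log",
]


# ---------------------------------------------------------------------------
# Configuration schema
# ---------------------------------------------------------------------------

class _Base(pydantic.BaseModel):
    model_config = pydantic.ConfigDict(extra="forbid")


class BeamConfig(_Base):
    energy_label: str = "190MeV"
    field_radius_mm: float = pydantic.Field(100.0, gt=0, le=100.0)
    pencil_spacing_mm: float = pydantic.Field(1.0, gt=0)


class PristineConfig(_Base):
    peak_depth_mm: float = pydantic.Field(160.0, gt=0)
    entrance_to_peak_ratio: float = pydantic.Field(3.5, gt=1)
    distal_falloff_mm: float = pydantic.Field(3.0, gt=0)
    grid_step_mm: float = pydantic.Field(0.5, gt=0)


class SOBPComponent(_Base):
    shift_mm: float = pydantic.Field(ge=0)
    weight: float = pydantic.Field(ge=0)


class SOBPConfig(_Base):
    modulation_width_mm: float = pydantic.Field(80.0, gt=0)
    n_components: int = pydantic.Field(21, ge=2)
    components: Optional[list[SOBPComponent]] = None  # overrides the fit


class GeometryConfig(_Base):
    kind: Literal["l_shape", "uniform"] = "l_shape"
    thick_mm: float = pydantic.Field(50.0, ge=0)
    thin_mm: float = pydantic.Field(10.0, ge=0)
    thickness_mm: float = pydantic.Field(0.0, ge=0)  # uniform case


class SigmaConfig(_Base):
    sigma0_mm: float = pydantic.Field(3.0, gt=0)
    growth_coeff: float = pydantic.Field(5.6e-4, ge=0)
    growth_power: float = pydantic.Field(1.8, gt=0)
    bolus_coeff: float = pydantic.Field(0.04, ge=0)


class CorrectionSegment(_Base):
    lower_mm: float = pydantic.Field(ge=0)
    coefficients: list[float]  # ascending power


class CorrectionConfig(_Base):
    kind: Literal["mono", "sobp", "custom"] = "mono"
    segments: Optional[list[CorrectionSegment]] = None


class NoiseConfig(_Base):
    relative_sd: float = pydantic.Field(0.014, ge=0)
    seed: int = pydantic.Field(0, ge=0, lt=2**31)


class CalibrationConfig(_Base):
    sensitivity_mv_per_cgy: float = pydantic.Field(0.72, gt=0)
    dose_per_exposure_cgy: float = pydantic.Field(200.0, gt=0)
    n_exposures: int = pydantic.Field(5, ge=1)


class ScanConfig(_Base):
    x_min_mm: float = -60.0
    x_max_mm: float = 60.0
    x_step_mm: float = pydantic.Field(5.0, gt=0)
    slab_depths_mm: list[float] = pydantic.Field(
        default_factory=lambda: [0.0, 100.0, 105.0, 110.0, 115.0]
    )

    @pydantic.model_validator(mode="after")
    def _ordered(self) -> "ScanConfig":
        if self.x_max_mm <= self.x_min_mm:
            raise ValueError("x_max_mm must exceed x_min_mm")
        if any(d < 0 for d in self.slab_depths_mm):
            raise ValueError("slab depths must be non-negative")
        return self


class RunConfig(_Base):
    """Validated run configuration; see module docstring for defaults."""

    beam: BeamConfig = pydantic.Field(default_factory=BeamConfig)
    pristine: PristineConfig = pydantic.Field(default_factory=PristineConfig)
    sobp: SOBPConfig = pydantic.Field(default_factory=SOBPConfig)
    geometry: GeometryConfig = pydantic.Field(default_factory=GeometryConfig)
    sigma: SigmaConfig = pydantic.Field(default_factory=SigmaConfig)
    correction: CorrectionConfig = pydantic.Field(default_factory=CorrectionConfig)
    noise: NoiseConfig = pydantic.Field(default_factory=NoiseConfig)
    calibration: CalibrationConfig = pydantic.Field(default_factory=CalibrationConfig)
    scan: ScanConfig = pydantic.Field(default_factory=ScanConfig)

    # -- builders -----------------------------------------------------------

    def build_pristine(self) -> DepthDoseCurve:
        p = self.pristine
        return make_pristine_bragg(
            p.peak_depth_mm, p.entrance_to_peak_ratio, p.distal_falloff_mm, p.grid_step_mm
        )

    def build_sobp_spec(self, pristine: DepthDoseCurve) -> SOBPSpec:
        s = self.sobp
        if s.components is not None:
            return SOBPSpec(
                shifts=np.array([c.shift_mm for c in s.components]),
                weights=np.array([c.weight for c in s.components]),
                modulation_width=s.modulation_width_mm,
            )
        return fit_sobp_weights(pristine, s.modulation_width_mm, s.n_components)

    def build_sobp(self, pristine: DepthDoseCurve) -> DepthDoseCurve:
        return synthesize_sobp(pristine, self.build_sobp_spec(pristine))

    def build_geometry(self) -> BolusGeometry:
        g = self.geometry
        if g.kind == "l_shape":
            return BolusGeometry.l_shape(g.thick_mm, g.thin_mm)
        return BolusGeometry.uniform(g.thickness_mm)

    def build_sigma_model(self) -> SigmaModel:
        s = self.sigma
        return SigmaModel(s.sigma0_mm, s.growth_coeff, s.growth_power, s.bolus_coeff)

    def build_correction(self) -> PiecewiseCorrection:
        c = self.correction
        if c.kind == "mono":
            return MOSFET_CF_MONO
        if c.kind == "sobp":
            return MOSFET_CF_SOBP
        if not c.segments:
            raise ConfigError("correction.kind=custom requires correction.segments")
        return PiecewiseCorrection(
            lowers=np.array([s.lower_mm for s in c.segments]),
            coeffs=tuple(np.array(s.coefficients) for s in c.segments),
            label="custom",
        )

    def build_pencils(self, geometry: BolusGeometry | None = None) -> PencilBeamSet:
        return decompose_broad_beam(
            self.beam.field_radius_mm,
            self.beam.pencil_spacing_mm,
            geometry=geometry if geometry is not None else self.build_geometry(),
        )

    def build_noise(self, seed: int | None = None) -> NoiseModel:
        return NoiseModel(
            relative_sd=self.noise.relative_sd,
            seed=self.noise.seed if seed is None else seed,
        )

    def x_grid(self) -> np.ndarray:
        s = self.scan
        return np.arange(s.x_min_mm, s.x_max_mm + s.x_step_mm / 2, s.x_step_mm)


def load_config(path: str | Path | None) -> RunConfig:
    """Load and validate a YAML run configuration (``None`` -> all defaults).

    Raises :class:`ConfigError` listing every offending key on violation.
    """
    if path is None:
        return RunConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")
    try:
        return RunConfig.model_validate(raw)
    except pydantic.ValidationError as exc:
        keys = "; ".join(
            f"{'.'.join(str(p) for p in err['loc'])}: {err['msg']}" for err in exc.errors()
        )
        raise ConfigError(f"invalid configuration ({keys})") from exc


def save_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.model_dump(), sort_keys=False))


# ---------------------------------------------------------------------------
# CSV formats
# ---------------------------------------------------------------------------

def _read_table(path: str | Path, required: tuple[str, ...]) -> pd.DataFrame:
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, comment="#", skip_blank_lines=True, float_precision="round_trip"
        )
    except Exception as exc:  # pragma: no cover - pandas message forwarded
        raise CSVFormatError(f"{path}: cannot parse ({exc})") from exc
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise CSVFormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    numeric = [c for c in required if c != "id"]
    for col in numeric:
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[coerced.isna() & frame[col].notna()]
        if len(bad):
            raise CSVFormatError(
                f"{path}: non-numeric value in column {col!r} at data row {int(bad[0]) + 1}"
            )
        if frame[col].isna().any():
            raise CSVFormatError(f"{path}: empty cell in column {col!r}")
        frame[col] = coerced
    return frame


def _comment_fields(path: Path) -> dict[str, str]:
    fields: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            if ":" in line:
                key, _, val = line.lstrip("# ").partition(":")
                fields[key.strip()] = val.strip()
    return fields


def write_depth_dose(curve: DepthDoseCurve, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# kind: {curve.kind}\n")
        if curve.plateau is not None:
            fh.write(f"# plateau_mm: {curve.plateau[0]} {curve.plateau[1]}\n")
        fh.write("depth_mm,relative_output\n")
        for d, o in zip(curve.depths, curve.outputs):
            fh.write(f"{float(d)!r},{float(o)!r}\n")


def read_depth_dose(path: str | Path) -> DepthDoseCurve:
    path = Path(path)
    frame = _read_table(path, ("depth_mm", "relative_output"))
    meta = _comment_fields(path)
    plateau = None
    if "plateau_mm" in meta:
        lo, hi = meta["plateau_mm"].split()
        plateau = (float(lo), float(hi))
    return DepthDoseCurve(
        depths=frame["depth_mm"].to_numpy(),
        outputs=frame["relative_output"].to_numpy(),
        kind=meta.get("kind", "pristine"),
        plateau=plateau,
    )


def write_lateral_profile(x_mm: np.ndarray, dose: np.ndarray, path: str | Path,
                          header_comments: dict | None = None) -> None:
    with open(path, "w") as fh:
        for key, val in (header_comments or {}).items():
            fh.write(f"# {key}: {val}\n")
        fh.write("x_mm,dose\n")
        for x, d in zip(np.asarray(x_mm, float), np.asarray(dose, float)):
            fh.write(f"{float(x)!r},{float(d)!r}\n")


def read_lateral_profile(path: str | Path) -> pd.DataFrame:
    return _read_table(path, ("x_mm", "dose"))


def write_readings(measurements: MeasurementSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for key, val in measurements.metadata.items():
            fh.write(f"# {key}: {val}\n")
        measurements.frame.to_csv(fh, index=False, columns=list(MeasurementSet.COLUMNS))


def read_readings(path: str | Path) -> MeasurementSet:
    frame = _read_table(Path(path), MeasurementSet.COLUMNS)
    return MeasurementSet(frame=frame, metadata=dict(_comment_fields(Path(path))))


def write_dose_grid(grid, path: str | Path) -> None:
    """Dose grid in long format: ``x_mm,y_mm,z_mm,dose``."""
    gx, gy, gz = np.meshgrid(grid.x, grid.y, grid.z, indexing="ij")
    frame = pd.DataFrame(
        {
            "x_mm": gx.ravel(),
            "y_mm": gy.ravel(),
            "z_mm": gz.ravel(),
            "dose": grid.dose.ravel(),
        }
    )
    frame.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Run log
# ---------------------------------------------------------------------------

def write_run_log(path: str | Path, config: RunConfig, seed: int, command: str) -> None:
    """Reproducibility record: package version, command, seed and the full
    resolved configuration with its SHA-256 hash."""
    from . import __version__

    resolved = config.model_dump()
    digest = hashlib.sha256(
        yaml.safe_dump(resolved, sort_keys=True).encode()
    ).hexdigest()
    Path(path).write_text(
        yaml.safe_dump(
            {
                "mosdose_version": __version__,
                "command": command,
                "seed": seed,
                "config_sha256": digest,
                "resolved_config": resolved,
            },
            sort_keys=False,
        )
    )
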