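"""Synthetic IC ground truth and raw MOSFET measurements.

Every experiment the correction pipeline supports can be emulated here, so
the full chain (calibration -> dose engine -> dose-weighted correction) is
testable without beam time:

* calibration sessions (repeated fixed-dose exposures at a plateau depth,
  where the detector response is LET-independent);
* depth-output scans of pristine or SOBP beams with paired IC / raw-MOSFET
  tables whose ratio is the depth correction function by construction;
* lateral scans behind a step bolus, where the raw MOSFET dose is the
  engine dose divided by the dose-weighted correction field computed with
  the same engine.

The ionization chamber is treated as exact dose plus reading noise; MOSFET
reading noise is multiplicative Gaussian with the detector's measured
reproducibility (1.4% relative, 1 s.d.) as default.  All generators are
deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .beam_models import DepthDoseCurve
from .correction import PiecewiseCorrection, correction_field
from .errors import InvalidParameterError, OutOfRangeError
from .pencil_beam import (
    BolusGeometry,
    PencilBeamSet,
    SigmaModel,
    compute_lateral_profile,
)

__all__ = [
    "DEFAULT_SENSITIVITY_MV_PER_CGY",
    "DEFAULT_RELATIVE_SD",
    "NoiseModel",
    "MeasurementSet",
    "SensitivityEstimate",
    "gen_calibration",
    "estimate_sensitivity",
    "gen_depth_scan",
    "gen_lateral_scan",
]

#: Measured detector sensitivity used as generator default, mV/cGy.
DEFAULT_SENSITIVITY_MV_PER_CGY = 0.72
#: Measured reading reproducibility (1 s.d., relative) used as default noise.
DEFAULT_RELATIVE_SD = 0.014


@dataclass(frozen=True)
class NoiseModel:
    """Multiplicative Gaussian reading noise: value * (1 + eps),
    eps ~ N(0, relative_sd), independent per exposure, seeded."""

    relative_sd: float = DEFAULT_RELATIVE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.relative_sd < 0:
            raise InvalidParameterError("relative noise s.d. must be non-negative")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        values = np.asarray(values, float)
        if self.relative_sd == 0.0:
            return values.copy()
        return values * (1.0 + rng.normal(0.0, self.relative_sd, size=values.shape))

    @classmethod
    def off(cls) -> "NoiseModel":
        return cls(relative_sd=0.0, seed=0)


@dataclass(frozen=True)
class MeasurementSet:
    """Detector readings with positions/angles, backed by a DataFrame with
    the readings-CSV schema ``id,x_mm,y_mm,z_mm,angle_deg,reading_mV`` plus
    exposure metadata."""

    frame: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    COLUMNS = ("id", "x_mm", "y_mm", "z_mm", "angle_deg", "reading_mV")

    def __post_init__(self) -> None:
        missing = [c for c in self.COLUMNS if c not in self.frame.columns]
        if missing:
            raise InvalidParameterError(f"measurement set missing columns {missing}")
        if (self.frame["reading_mV"] < 0).any():
            raise InvalidParameterError("readings must be non-negative")
        if ((self.frame["angle_deg"] < 0) | (self.frame["angle_deg"] > 180)).any():
            raise InvalidParameterError("angles must lie in [0, 180] degrees")

    @property
    def readings(self) -> np.ndarray:
        return self.frame["reading_mV"].to_numpy()

    def __len__(self) -> int:
        return len(self.frame)


@dataclass(frozen=True)
class SensitivityEstimate:
    """Sensitivity estimate in mV/cGy with its standard error (None when a
    single exposure gives no spread information)."""

    value: float
    stderr: float | None
    n: int


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def gen_calibration(
    n_exposures: int = 5,
    dose_per_exposure: float = 200.0,
    sensitivity: float = DEFAULT_SENSITIVITY_MV_PER_CGY,
    noise: NoiseModel = NoiseModel(),
) -> MeasurementSet:
    """Repeated fixed-dose calibration exposures at a plateau depth.

    Each reading is ``dose * sensitivity * (1 + eps)``; defaults reproduce a
    five-exposure 200 cGy session with a 0.72 mV/cGy detector.
    """
    if n_exposures < 1:
        raise InvalidParameterError("at least one exposure required")
    if dose_per_exposure <= 0 or sensitivity <= 0:
        raise InvalidParameterError("dose and sensitivity must be positive")
    rng = noise.rng()
    readings = noise.perturb(
        np.full(n_exposures, dose_per_exposure * sensitivity), rng
    )
    frame = pd.DataFrame(
        {
            "id": [f"cal{k:02d}" for k in range(n_exposures)],
            "x_mm": 0.0,
            "y_mm": 0.0,
            "z_mm": 0.0,
            "angle_deg": 0.0,
            "reading_mV": readings,
        }
    )
    return MeasurementSet(
        frame=frame,
        metadata={
            "scenario": "calibration",
            "dose_per_exposure_cGy": dose_per_exposure,
            "true_sensitivity_mV_per_cGy": sensitivity,
            "noise_relative_sd": noise.relative_sd,
            "seed": noise.seed,
        },
    )


def estimate_sensitivity(
    measurements: MeasurementSet, doses_cgy: Sequence[float] | float
) -> SensitivityEstimate:
    """Sensitivity = mean(reading / dose) over exposures, with the standard
    error of that mean (sample s.d. / sqrt(n))."""
    readings = measurements.readings
    doses = np.broadcast_to(np.asarray(doses_cgy, float), readings.shape)
    if np.any(doses <= 0):
        raise InvalidParameterError("exposure doses must be positive")
    per = readings / doses
    n = len(per)
    stderr = float(per.std(ddof=1) / np.sqrt(n)) if n >= 2 else None
    return SensitivityEstimate(value=float(per.mean()), stderr=stderr, n=n)


# ---------------------------------------------------------------------------
# Depth-output scans
# ---------------------------------------------------------------------------

def gen_depth_scan(
    dd_ic: DepthDoseCurve,
    cf: PiecewiseCorrection,
    depths: np.ndarray,
    noise: NoiseModel = NoiseModel(),
) -> pd.DataFrame:
    """Paired IC / raw-MOSFET depth-output tables.

    IC(d) = dd_ic(d) (1 + eps); MOSFET_raw(d) = dd_ic(d) / cf(d) (1 + eps'),
    with independent seeded noise draws, so the noise-free IC/MOSFET ratio
    reproduces cf(d) exactly.  Columns: depth_mm, ic, mosfet_raw.
    """
    depths = np.asarray(depths, float)
    lo, hi = dd_ic.span
    if np.any(depths < lo) or np.any(depths > hi):
        raise OutOfRangeError(f"scan depths must lie within the curve span [{lo}, {hi}] mm")
    rng = noise.rng()
    ic_true = dd_ic(depths)
    ic = noise.perturb(ic_true, rng)
    mos = noise.perturb(ic_true / cf(depths), rng)
    return pd.DataFrame({"depth_mm": depths, "ic": ic, "mosfet_raw": mos})


# ---------------------------------------------------------------------------
# Lateral scans behind a step bolus
# ---------------------------------------------------------------------------

def gen_lateral_scan(
    geometry: BolusGeometry,
    dd: DepthDoseCurve,
    cf: PiecewiseCorrection,
    slab_depth: float,
    x_positions: np.ndarray,
    pencils: PencilBeamSet,
    sigma_model: SigmaModel = SigmaModel(),
    noise: NoiseModel = NoiseModel(),
    truth_pencils: PencilBeamSet | None = None,
) -> pd.DataFrame:
    """Paired IC / raw-MOSFET lateral profiles at one slab depth.

    The engine dose D(x) is computed by pencil summation; the generated raw
    MOSFET dose is D(x) / CF_true(x), with CF_true the dose-weighted
    correction field evaluated with the same engine (or, in stress mode,
    with the finer ``truth_pencils`` decomposition to emulate model
    mismatch).  Independent multiplicative noise is applied to both columns.
    Columns: x_mm, ic, mosfet_raw, cf_true.
    """
    x_positions = np.asarray(x_positions, float)
    gen_pencils = pencils if truth_pencils is None else truth_pencils
    gen_pencils = PencilBeamSet(
        gen_pencils.x0, gen_pencils.y0, gen_pencils.fluence,
        geometry.thickness(gen_pencils.x0, gen_pencils.y0),
    )
    dose = compute_lateral_profile(
        gen_pencils, None, dd, sigma_model, x_positions, slab_depth
    )
    pts = np.column_stack(
        [x_positions, np.zeros_like(x_positions), np.full_like(x_positions, slab_depth)]
    )
    cf_true = correction_field(pts, gen_pencils, cf, dd, sigma_model)
    rng = noise.rng()
    ic = noise.perturb(dose, rng)
    mos = noise.perturb(dose / cf_true, rng)
    return pd.DataFrame(
        {"x_mm": x_positions, "ic": ic, "mosfet_raw": mos, "cf_true": cf_true}
    )
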