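"""MOSFET LET-correction mathematics.

A MOSFET dosimeter under-responds where the proton linear energy transfer
(LET) is high, i.e. near the end of the proton range.  The correction
strategy implemented here sidesteps explicit LET spectra:

1. calibration converts a reading R (mV) into raw dose, D_raw = F_calib * R;
2. a measured ionization-chamber-to-MOSFET response ratio, expressed as a
   piecewise polynomial cf(d_PE) of PE-equivalent penetration depth, encodes
   the depth (residual-range) dependence — one table for a mono-energetic
   beam, one for an 80 mm SOBP beam;
3. at a point fed by many pencil beams with different residual ranges, the
   point correction CF is the dose-weighted mean of per-pencil cf values,
   with each pencil's cf evaluated at its effective PE depth (slab depth +
   upstream bolus WET):

       CF(x,y,z) = sum_i cf(z + wet_i) F_i(x,y,z) / sum_i F_i(x,y,z);

4. corrected dose D = CF * D_raw, and an independent polynomial correction
   CV_ang(theta) handles the detector's cable-axis angular response.

The SOBP correction table can also be *derived* from the mono-energetic one
by simulating the SOBP stepwise from shifted pristine components, dividing
each component by cf_mono, and refitting the simulated IC/MOSFET ratio.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import linprog

from .beam_models import DepthDoseCurve, SOBPSpec, _stack_components
from .errors import (
    FittingError,
    InvalidParameterError,
    OutOfRangeError,
    UndefinedDoseError,
)
from .pencil_beam import PencilBeamSet, SigmaModel, pencil_dose_matrix

__all__ = [
    "CalibrationFactor",
    "PiecewiseCorrection",
    "MOSFET_CF_MONO",
    "MOSFET_CF_SOBP",
    "raw_dose",
    "cf_mono",
    "cf_sobp",
    "correction_field",
    "corrected_dose",
    "angular_cv",
    "fit_piecewise_correction",
    "derive_cf_sobp",
]

logger = logging.getLogger("mosdose")


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationFactor:
    """Dose calibration factor F_calib (cGy/mV); its reciprocal is the
    detector sensitivity (mV/cGy)."""

    fcalib: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.fcalib > 0:
            raise InvalidParameterError("calibration factor must be positive")

    @property
    def sensitivity(self) -> float:
        return 1.0 / self.fcalib

    @classmethod
    def from_sensitivity(cls, sensitivity_mv_per_cgy: float, source: str = "") -> "CalibrationFactor":
        if not sensitivity_mv_per_cgy > 0:
            raise InvalidParameterError("sensitivity must be positive")
        return cls(fcalib=1.0 / sensitivity_mv_per_cgy, source=source)


def raw_dose(reading_mv: float | np.ndarray, cal: CalibrationFactor) -> float | np.ndarray:
    """Raw (uncorrected) dose in cGy: D_raw = F_calib * R."""
    r = np.asarray(reading_mv, float)
    if np.any(r < 0):
        raise InvalidParameterError("MOSFET reading must be non-negative")
    out = cal.fcalib * r
    return float(out) if np.isscalar(reading_mv) else out


# ---------------------------------------------------------------------------
# Piecewise correction functions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PiecewiseCorrection:
    """Piecewise-polynomial depth correction cf(d_PE).

    ``lowers`` are the segment lower bounds (first must be 0); segment k
    applies on [lowers[k], lowers[k+1]) — lower-closed, upper-open — and the
    last segment extends upward.  ``coeffs`` holds ascending-power polynomial
    coefficients in absolute depth.  The first segment must be the constant 1
    (shallow depths need no correction).  If ``domain_max`` is set, the last
    segment is continued linearly beyond it (tangent at ``domain_max``) with
    a logged warning — the table was not characterised out there.
    """

    lowers: np.ndarray
    coeffs: tuple[np.ndarray, ...]
    label: str = "custom"
    domain_max: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        lowers = np.asarray(self.lowers, float)
        object.__setattr__(self, "lowers", lowers)
        object.__setattr__(
            self, "coeffs", tuple(np.asarray(c, float) for c in self.coeffs)
        )
        if lowers.ndim != 1 or len(lowers) != len(self.coeffs):
            raise InvalidParameterError("one coefficient list per segment required")
        if lowers[0] != 0.0 or np.any(np.diff(lowers) <= 0):
            raise InvalidParameterError("segment lower bounds must start at 0 and increase")
        first = self.coeffs[0]
        if len(first) != 1 or abs(first[0] - 1.0) > 1e-9:
            raise InvalidParameterError("first segment must be the constant 1")

    def __call__(self, d_pe: float | np.ndarray) -> float | np.ndarray:
        d = np.asarray(d_pe, float)
        if np.any(d < 0):
            raise OutOfRangeError("PE depth must be non-negative")
        seg = np.searchsorted(self.lowers, d, side="right") - 1
        out = np.empty(d.shape if d.ndim else (1,), float)
        dflat, segflat = np.atleast_1d(d), np.atleast_1d(seg)
        for k, ck in enumerate(self.coeffs):
            m = segflat == k
            if m.any():
                out[m] = np.polynomial.polynomial.polyval(dflat[m], ck)
        if self.domain_max is not None and np.any(dflat > self.domain_max):
            ck = self.coeffs[-1]
            dck = np.polynomial.polynomial.polyder(ck)
            v0 = np.polynomial.polynomial.polyval(self.domain_max, ck)
            s0 = np.polynomial.polynomial.polyval(self.domain_max, dck)
            m = dflat > self.domain_max
            out[m] = v0 + s0 * (dflat[m] - self.domain_max)
            logger.warning(
                "correction %r evaluated beyond its fitted domain (%.1f mm); "
                "linear continuation used", self.label, self.domain_max,
            )
        return float(out[0]) if d.ndim == 0 else out.reshape(d.shape)

    def continuity_mismatch(self) -> np.ndarray:
        """|left - right| value gap at each interior breakpoint."""
        gaps = []
        for k in range(1, len(self.lowers)):
            b = self.lowers[k]
            left = np.polynomial.polynomial.polyval(b, self.coeffs[k - 1])
            right = np.polynomial.polynomial.polyval(b, self.coeffs[k])
            gaps.append(abs(left - right))
        return np.asarray(gaps)

    def validate(self, max_mismatch: float = 1e-3) -> None:
        gaps = self.continuity_mismatch()
        if gaps.size and gaps.max() >= max_mismatch:
            raise InvalidParameterError(
                f"correction {self.label!r} discontinuous at a breakpoint "
                f"(gap {gaps.max():.2e} >= {max_mismatch:g})"
            )

    @classmethod
    def unity(cls, label: str = "unity") -> "PiecewiseCorrection":
        return cls(lowers=np.array([0.0]), coeffs=(np.array([1.0]),), label=label)


#: Mono-energetic (pristine 190 MeV) correction: 1 below 100.421 mm, then two
#: linear segments meeting near the Bragg peak.
MOSFET_CF_MONO = PiecewiseCorrection(
    lowers=np.array([0.0, 100.421, 154.784]),
    coeffs=(
        np.array([1.0]),
        np.array([0.781885, 0.002172]),
        np.array([-2.94139, 0.0262266]),
    ),
    label="mono",
)

#: 80 mm SOBP correction: 1 below 40 mm, linear to 140 mm, quadratic beyond.
MOSFET_CF_SOBP = PiecewiseCorrection(
    lowers=np.array([0.0, 40.0, 140.0]),
    coeffs=(
        np.array([1.0]),
        np.array([0.94639, 0.00134025]),
        np.array([6.59257, -0.0793194, 0.00028807]),
    ),
    label="sobp",
)


def cf_mono(d_pe: float | np.ndarray) -> float | np.ndarray:
    """Mono-energetic-beam correction factor at PE depth ``d_pe`` (mm)."""
    return MOSFET_CF_MONO(d_pe)


def cf_sobp(d_pe: float | np.ndarray) -> float | np.ndarray:
    """80 mm SOBP-beam correction factor at PE depth ``d_pe`` (mm)."""
    return MOSFET_CF_SOBP(d_pe)


# ---------------------------------------------------------------------------
# Dose-weighted correction field and corrected dose
# ---------------------------------------------------------------------------

def correction_field(
    points: np.ndarray,
    pencils: PencilBeamSet,
    cf: PiecewiseCorrection,
    dd: DepthDoseCurve,
    sigma_model: SigmaModel,
) -> np.ndarray:
    """Dose-weighted mean correction CF at each point.

    Each pencil's cf is evaluated at its effective PE depth (slab depth z
    plus the pencil's bolus WET offset) and weighted by the pencil's dose
    contribution at the point.  Points receiving zero total dose are outside
    the field and have no defined correction.
    """
    pts = np.atleast_2d(np.asarray(points, float))
    F = pencil_dose_matrix(pts, pencils, dd, sigma_model)
    total = F.sum(axis=1)
    if np.any(total <= 0.0):
        bad = pts[total <= 0.0][0]
        raise UndefinedDoseError(
            f"zero total dose at point {tuple(bad)}; correction undefined outside the field"
        )
    cfdd = cf(pts[:, 2:3] + pencils.wet_offset[None, :])
    out = (cfdd * F).sum(axis=1) / total
    return out if np.asarray(points).ndim == 2 else float(out[0])


def corrected_dose(cf_value: float | np.ndarray, draw: float | np.ndarray) -> float | np.ndarray:
    """Corrected dose D = CF * D_raw (cGy)."""
    cf_arr = np.asarray(cf_value, float)
    if np.any(cf_arr <= 0):
        raise InvalidParameterError("correction factor must be positive")
    out = cf_arr * np.asarray(draw, float)
    return float(out) if np.isscalar(cf_value) and np.isscalar(draw) else out


def angular_cv(theta_deg: float | np.ndarray) -> float | np.ndarray:
    """Angular correction value CV(theta) = 1 - 0.00197 theta + 0.0000109 theta^2,
    for the cable-axis mounting angle theta in degrees on [0, 180].

    Applied multiplicatively to the reading before calibration."""
    th = np.asarray(theta_deg, float)
    if np.any((th < 0) | (th > 180)):
        raise OutOfRangeError("angle must be within [0, 180] degrees")
    out = 1.0 - 0.00197 * th + 0.0000109 * th**2
    return float(out) if np.isscalar(theta_deg) else out


# ---------------------------------------------------------------------------
# Fitting correction functions from IC/MOSFET ratio samples
# ---------------------------------------------------------------------------

def fit_piecewise_correction(
    d_pe: np.ndarray,
    ratios: np.ndarray,
    breakpoint_hints: Sequence[float],
    degrees: Sequence[int] | None = None,
) -> PiecewiseCorrection:
    """Per-segment least-squares fit of IC/MOSFET ratio samples.

    ``breakpoint_hints`` are the fixed lower bounds of the non-unity
    segments (depths are not searched: the breakpoints are an empirical
    input).  ``degrees`` gives the polynomial degree of each non-unity
    segment (default: linear).  The first segment (below the first hint) is
    pinned to the constant 1; continuity is *reported* in
    ``metadata["continuity_residuals"]``, not enforced.
    """
    d = np.asarray(d_pe, float)
    r = np.asarray(ratios, float)
    if d.shape != r.shape or d.ndim != 1:
        raise InvalidParameterError("d_pe and ratios must be equal-length 1-D arrays")
    hints = sorted(float(b) for b in breakpoint_hints)
    if not hints:
        # constant-ratio data: a single unity segment
        if np.abs(r - 1.0).max() > 0.05:
            raise FittingError("no breakpoints given but ratios deviate from 1")
        return PiecewiseCorrection.unity(label="fitted")
    degrees = [1] * len(hints) if degrees is None else list(degrees)
    if len(degrees) != len(hints):
        raise InvalidParameterError("one degree per non-unity segment required")

    lowers = [0.0] + hints
    uppers = hints + [np.inf]
    coeffs: list[np.ndarray] = [np.array([1.0])]
    for lo, hi, deg in zip(lowers[1:], uppers[1:], degrees):
        m = (d >= lo) & (d < hi)
        need = max(3, deg + 1)
        if m.sum() < need:
            raise FittingError(
                f"segment [{lo}, {hi}) has {int(m.sum())} samples; at least {need} required"
            )
        # plain LS in absolute depth, as the breakpoints are trusted
        c = np.polynomial.polynomial.polyfit(d[m], r[m], deg)
        coeffs.append(np.asarray(c))
    pw = PiecewiseCorrection(
        lowers=np.asarray(lowers), coeffs=tuple(coeffs), label="fitted"
    )
    object.__setattr__(
        pw, "metadata", {"continuity_residuals": pw.continuity_mismatch()}
    )
    return pw


# ---------------------------------------------------------------------------
# Deriving the SOBP correction from the mono-energetic one
# ---------------------------------------------------------------------------

def _minimax_piecewise(
    z: np.ndarray, r: np.ndarray, b1: float, b2: float, deg_last: int
) -> tuple[np.ndarray, float] | tuple[None, float]:
    """Continuity-constrained minimax fit of (1 | linear | poly deg_last) to
    ratio samples, with a non-decreasing shape constraint.  Returns the
    parameter vector [slope, c1..c_deg] (segments in shifted bases anchored
    at their breakpoints) and the max relative error, or (None, inf) if the
    breakpoints leave a segment under-determined."""
    seg2 = (z >= b1) & (z < b2)
    seg3 = z >= b2
    if seg2.sum() < 3 or seg3.sum() < deg_last + 1:
        return None, np.inf
    npar = 1 + deg_last
    rows = np.zeros((seg2.sum() + seg3.sum(), npar))
    rows[: seg2.sum(), 0] = z[seg2] - b1
    rows[seg2.sum():, 0] = b2 - b1
    x3 = z[seg3] - b2
    for k in range(deg_last):
        rows[seg2.sum():, 1 + k] = x3 ** (k + 1)
    r_all = np.concatenate([r[seg2], r[seg3]])
    # |(1 + rows@theta - r)| / r <= t
    A_fit = np.vstack(
        [
            np.hstack([rows / r_all[:, None], -np.ones((len(r_all), 1))]),
            np.hstack([-rows / r_all[:, None], -np.ones((len(r_all), 1))]),
        ]
    )
    b_fit = np.concatenate([(r_all - 1.0) / r_all, -(r_all - 1.0) / r_all])
    # monotone: slope >= 0 and last-segment derivative >= 0 at the samples
    deriv = np.zeros((1 + seg3.sum(), npar + 1))
    deriv[0, 0] = -1.0
    for j, xv in enumerate(x3, start=1):
        for k in range(deg_last):
            deriv[j, 1 + k] = -(k + 1) * xv**k
    res = linprog(
        c=np.r_[np.zeros(npar), 1.0],
        A_ub=np.vstack([A_fit, deriv]),
        b_ub=np.r_[b_fit, np.zeros(len(deriv))],
        bounds=[(None, None)] * npar + [(0, None)],
        method="highs",
    )
    if not res.success:
        return None, np.inf
    return res.x[:npar], float(res.x[-1])


def _params_to_piecewise(
    theta: np.ndarray, b1: float, b2: float, deg_last: int,
    domain_max: float, err: float,
) -> PiecewiseCorrection:
    P = np.polynomial.Polynomial
    shift_b1 = P([-b1, 1.0])
    shift_b2 = P([-b2, 1.0])
    lin = P([1.0, theta[0]])(shift_b1)  # 1 + m (d - b1)
    v2 = 1.0 + theta[0] * (b2 - b1)
    last = P(np.r_[v2, theta[1:]])(shift_b2)
    return PiecewiseCorrection(
        lowers=np.array([0.0, b1, b2]),
        coeffs=(np.array([1.0]), lin.coef, last.coef),
        label="sobp_derived",
        domain_max=float(domain_max),
        metadata={"max_rel_fit_error": err, "breakpoints": (b1, b2)},
    )


def derive_cf_sobp(
    cf_mono_table: PiecewiseCorrection,
    pristine: DepthDoseCurve,
    spec: SOBPSpec,
    deg_last: int = 3,
) -> PiecewiseCorrection:
    """Derive an SOBP correction table from the mono-energetic one.

    The SOBP is simulated stepwise from the pristine curve: the IC curve is
    ``sum_k w_k p(z + s_k)`` and the uncorrected MOSFET curve is
    ``sum_k w_k p(z + s_k) / cf_mono(z + s_k)``.  Their ratio, tabulated on
    the depths where the IC dose exceeds 1% of the plateau level, is fitted
    with a continuous, non-decreasing minimax piecewise model (unity segment,
    linear segment, degree-``deg_last`` distal segment) whose two breakpoints
    are scanned coarsely and then refined.

    Degenerate inputs reduce exactly: a unity ``cf_mono_table`` returns the
    unity correction, and a single zero-shift component (the SOBP *is* the
    pristine beam) returns ``cf_mono_table`` itself.
    """
    if len(spec.shifts) == 1 and abs(spec.shifts[0]) < 1e-12:
        return cf_mono_table

    z = pristine.depths
    comps = _stack_components(pristine, spec.shifts, z)
    ic = comps @ spec.weights
    mos = (comps / cf_mono_table(z[:, None] + spec.shifts[None, :])) @ spec.weights

    peak = pristine.peak_depth
    on_plateau = (z >= peak - spec.modulation_width) & (z <= peak)
    plateau_level = float(ic[on_plateau].mean()) if on_plateau.any() else float(ic.max())
    dom = ic > 0.01 * plateau_level
    zt, rt = z[dom], ic[dom] / mos[dom]

    if np.abs(rt - 1.0).max() < 1e-9:
        return PiecewiseCorrection.unity(label="sobp_derived")

    lo, hi = float(zt.min()), float(zt.max())
    best: tuple[np.ndarray | None, float, tuple[float, float]] = (None, np.inf, (0.0, 0.0))

    def scan(b1s: np.ndarray, b2s: np.ndarray) -> None:
        nonlocal best
        for b1 in b1s:
            for b2 in b2s:
                if b2 - b1 < 15.0:
                    continue
                theta, err = _minimax_piecewise(zt, rt, b1, b2, deg_last)
                if err < best[1]:
                    best = (theta, err, (float(b1), float(b2)))

    scan(np.arange(lo + 5.0, hi - 25.0, 4.0), np.arange(lo + 25.0, hi - 3.0, 4.0))
    if best[0] is None:
        raise FittingError("could not fit a piecewise correction to the simulated ratio")
    b1c, b2c = best[2]
    scan(np.arange(b1c - 3.0, b1c + 3.5, 1.0), np.arange(b2c - 3.0, b2c + 3.5, 1.0))

    theta, err, (b1, b2) = best
    logger.info(
        "derived SOBP correction: breakpoints %.1f/%.1f mm, max relative fit "
        "error %.3f%%, domain up to %.1f mm", b1, b2, 100 * err, hi,
    )
    return _params_to_piecewise(theta, b1, b2, deg_last, domain_max=hi, err=err)
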