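"""Depth-dose models: pristine Bragg curves, SOBP synthesis, unit conversions.

A proton beam stopping in matter deposits most of its dose in a sharp maximum
(the Bragg peak) at the end of its range.  Clinical beams flatten that peak
into a spread-out Bragg peak (SOBP) by summing range-shifted copies of the
pristine curve with ridge-filter weights.  This module provides

* an analytic pristine-curve family (slow entrance build-up, Gaussian peak,
  sigmoidal distal edge) parameterised by peak depth, entrance-to-peak ratio
  and distal fall-off, so the whole pipeline is testable without measured
  beam data;
* stepwise SOBP synthesis from shifted, weighted pristine components and a
  non-negative least-squares fit of the component weights that flattens the
  plateau;
* the polyethylene-to-water equivalent-thickness conversion (factor 1.02).

Depths are polyethylene-equivalent millimetres throughout unless a function
says otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, nnls
from scipy.special import erfc

from .errors import FittingError, InvalidParameterError, OutOfRangeError

__all__ = [
    "PE_TO_WATER_FACTOR",
    "DepthDoseCurve",
    "SOBPSpec",
    "make_pristine_bragg",
    "synthesize_sobp",
    "fit_sobp_weights",
    "pe_to_water",
]

#: Water-equivalent thickness per mm of polyethylene.
PE_TO_WATER_FACTOR = 1.02


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DepthDoseCurve:
    """Tabulated relative output versus depth (PE-equivalent mm).

    ``kind`` is ``"pristine"`` (entrance-normalised, output 1 at depth 0,
    unique global maximum) or ``"sobp"`` (plateau-mean-normalised, contiguous
    flat-top).  Evaluation interpolates linearly; depths beyond the grid are
    past distal extinction and evaluate to 0, negative depths are upstream of
    the entrance and raise.
    """

    depths: np.ndarray
    outputs: np.ndarray
    kind: str = "pristine"
    #: for SOBP curves: (proximal, distal) edge of the nominal plateau, PE mm
    plateau: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "depths", np.asarray(self.depths, dtype=float))
        object.__setattr__(self, "outputs", np.asarray(self.outputs, dtype=float))
        self.validate()

    def validate(self) -> None:
        if self.kind not in ("pristine", "sobp"):
            raise InvalidParameterError(f"unknown curve kind {self.kind!r}")
        if self.depths.ndim != 1 or self.depths.shape != self.outputs.shape:
            raise InvalidParameterError("depths and outputs must be equal-length 1-D arrays")
        if np.any(np.diff(self.depths) <= 0):
            raise InvalidParameterError("depths must be strictly increasing")
        if np.any(self.outputs < 0) or not np.all(np.isfinite(self.outputs)):
            raise InvalidParameterError("outputs must be finite and non-negative")
        if self.kind == "pristine" and abs(self.outputs[0] - 1.0) > 1e-9:
            raise InvalidParameterError(
                f"pristine curve must be entrance-normalised (got {self.outputs[0]!r} at depth 0)"
            )

    def __call__(self, z: float | np.ndarray) -> np.ndarray:
        z = np.asarray(z, dtype=float)
        if np.any(z < self.depths[0]):
            raise OutOfRangeError(
                f"depth below curve entrance {self.depths[0]} mm requested"
            )
        # beyond the grid = past distal extinction -> 0
        return np.interp(z, self.depths, self.outputs, right=0.0)

    @property
    def peak_depth(self) -> float:
        """Depth of the global maximum (mm)."""
        return float(self.depths[int(np.argmax(self.outputs))])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.depths[0]), float(self.depths[-1])


@dataclass(frozen=True)
class SOBPSpec:
    """Ridge-filter-style recipe for an SOBP: per-component range pullbacks
    (``shifts``, mm, >= 0) and non-negative fluence ``weights``."""

    shifts: np.ndarray
    weights: np.ndarray
    modulation_width: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "shifts", np.asarray(self.shifts, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.shifts.shape != self.weights.shape or self.shifts.ndim != 1:
            raise InvalidParameterError("shifts and weights must be equal-length 1-D arrays")
        if np.any(self.shifts < 0):
            raise InvalidParameterError("range pullbacks must be non-negative")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise InvalidParameterError("weights must be non-negative and not all zero")
        if self.modulation_width < 0:
            raise InvalidParameterError("modulation width must be non-negative")


# ---------------------------------------------------------------------------
# Pristine Bragg curve
# ---------------------------------------------------------------------------

def make_pristine_bragg(
    peak_depth: float,
    entrance_to_peak_ratio: float = 3.5,
    distal_falloff: float = 3.0,
    grid_step: float = 0.5,
    buildup: float = 0.4,
) -> DepthDoseCurve:
    """Analytic pristine Bragg curve on a uniform depth grid.

    The shape is a slowly rising entrance plateau ``1 + buildup*(z/peak)^2``
    cut off by a sigmoidal distal edge of width ``distal_falloff``, plus an
    asymmetric Gaussian peak at ``peak_depth`` whose amplitude is solved so
    that the peak-to-entrance ratio equals ``entrance_to_peak_ratio``.  The
    distal peak width is tied to ``distal_falloff`` so the output drops below
    1% of entrance past ``peak_depth + 5*distal_falloff``.

    Parameters
    ----------
    peak_depth : float
        Depth of the Bragg peak, PE-equivalent mm.
    entrance_to_peak_ratio : float
        Peak output over entrance output; must exceed 1.
    distal_falloff : float
        Length scale (mm) of the distal dose fall-off.
    grid_step : float
        Depth grid spacing, mm.
    buildup : float
        Fractional rise of the entrance plateau just proximal to the peak.
    """
    if peak_depth <= 0 or distal_falloff <= 0:
        raise InvalidParameterError("peak_depth and distal_falloff must be positive")
    if entrance_to_peak_ratio <= 1:
        raise InvalidParameterError("entrance_to_peak_ratio must exceed 1")
    if grid_step <= 0:
        raise InvalidParameterError("grid_step must be positive")

    z = np.arange(0.0, peak_depth + 5.0 * distal_falloff + grid_step / 2, grid_step)
    width_prox = 0.06 * peak_depth + 2.0
    width_dist = 1.4 * distal_falloff
    edge = peak_depth + 2.0 * distal_falloff

    # sigmoid narrower than the fall-off scale keeps the entrance plateau
    # flat at the peak (so the maximum stays on peak_depth) while still
    # extinguishing the output within 5 fall-off lengths
    base = (1.0 + buildup * (z / peak_depth) ** 2) * 0.5 * erfc(
        (z - edge) / (np.sqrt(2.0) * 0.7 * distal_falloff)
    )
    peak_shape = np.exp(
        -((z - peak_depth) ** 2)
        / (2.0 * np.where(z <= peak_depth, width_prox, width_dist) ** 2)
    )

    def ratio_of(amplitude: float) -> float:
        u = base + amplitude * peak_shape
        return float(u.max() / u[0])

    amplitude = brentq(
        lambda a: ratio_of(a) - entrance_to_peak_ratio, 0.0, 10.0 * entrance_to_peak_ratio
    )
    u = base + amplitude * peak_shape
    return DepthDoseCurve(depths=z, outputs=u / u[0], kind="pristine")


# ---------------------------------------------------------------------------
# SOBP synthesis
# ---------------------------------------------------------------------------

def _stack_components(
    pristine: DepthDoseCurve, shifts: np.ndarray, z: np.ndarray
) -> np.ndarray:
    """Matrix of shifted pristine components, shape (len(z), len(shifts))."""
    return np.stack([pristine(z + s) for s in shifts], axis=1)


def synthesize_sobp(pristine: DepthDoseCurve, spec: SOBPSpec) -> DepthDoseCurve:
    """Stepwise SOBP: weighted sum of range-shifted pristine components.

    The raw sum ``sum_k w_k * pristine(z + shift_k)`` is linear in the
    weights; the returned curve is renormalised so the mean over the nominal
    plateau ``[peak - modulation_width, peak]`` is 1.
    """
    lo, hi = pristine.span
    if np.any(spec.shifts > hi - lo):
        raise OutOfRangeError("a range pullback exceeds the pristine grid span")
    z = pristine.depths
    raw = _stack_components(pristine, spec.shifts, z) @ spec.weights
    peak = pristine.peak_depth
    prox = max(peak - spec.modulation_width, lo)
    on_plateau = (z >= prox) & (z <= peak)
    level = float(raw[on_plateau].mean()) if on_plateau.any() else float(raw.max())
    if level <= 0:
        raise FittingError("SOBP plateau level is zero; check shifts/weights")
    return DepthDoseCurve(
        depths=z, outputs=raw / level, kind="sobp", plateau=(prox, peak)
    )


def fit_sobp_weights(
    pristine: DepthDoseCurve,
    modulation_width: float,
    n_components: int = 21,
) -> SOBPSpec:
    """Non-negative least-squares ridge-filter weights for a flat plateau.

    Components are pristine curves pulled back by equally spaced shifts over
    ``[0, modulation_width]``; weights minimise the squared deviation of the
    summed dose from flat on the plateau ``[peak - modulation_width, peak]``.
    """
    if n_components < 2:
        raise FittingError("cannot flatten a plateau with fewer than 2 components")
    peak = pristine.peak_depth
    if not 0 < modulation_width < peak:
        raise FittingError(
            f"modulation width {modulation_width} mm infeasible for a curve "
            f"peaking at {peak} mm"
        )
    shifts = np.linspace(0.0, modulation_width, n_components)
    step = min(1.0, float(np.diff(pristine.depths).min()))
    z_plateau = np.arange(peak - modulation_width, peak + step / 2, step)
    design = _stack_components(pristine, shifts, z_plateau)
    weights, residual = nnls(design, np.ones_like(z_plateau))
    if not np.any(weights > 0):
        raise FittingError(f"weight fit degenerate (residual {residual:.3g})")
    flat = design @ weights
    worst = float(np.abs(flat / flat.mean() - 1.0).max())
    if worst > 0.05:
        raise FittingError(
            f"fitted plateau deviates {worst:.1%} from flat; "
            f"increase n_components or shrink modulation width"
        )
    return SOBPSpec(shifts=shifts, weights=weights, modulation_width=modulation_width)


# ---------------------------------------------------------------------------
# Unit conversion
# ---------------------------------------------------------------------------

def pe_to_water(thickness_pe: float | np.ndarray) -> float | np.ndarray:
    """Convert polyethylene thickness (mm) to water-equivalent thickness (mm)
    by the standard factor 1.02."""
    arr = np.asarray(thickness_pe, dtype=float)
    if np.any(arr < 0):
        raise InvalidParameterError("thickness must be non-negative")
    out = arr * PE_TO_WATER_FACTOR
    return float(out) if np.isscalar(thickness_pe) else out
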