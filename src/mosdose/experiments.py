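"""Reference experiment protocols run end-to-end through the library.

These functions reproduce the bench experiments the package models — the
L-shaped-bolus lateral scans and the mono-energetic / SOBP depth-output
round trips — with the default study conditions: a pristine curve peaking at
160 mm PE (the bare-beam peak consistent with 110/150 mm behind the
50/10 mm bolus branches), an 80 mm modulation SOBP, a 100 mm field radius
decomposed at 1 mm pencil spacing, a 5 mm lateral grid over [-60, 60] mm,
0.72 mV/cGy sensitivity and 1.4% reading reproducibility.  They are the
programmatic form of the workflows the CLI exposes and the basis of the
package's accuracy claims.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .beam_models import fit_sobp_weights, make_pristine_bragg, synthesize_sobp
from .correction import (
    MOSFET_CF_MONO,
    MOSFET_CF_SOBP,
    PiecewiseCorrection,
    correction_field,
    derive_cf_sobp,
)
from .pencil_beam import BolusGeometry, SigmaModel, decompose_broad_beam
from .synthetic import NoiseModel, gen_depth_scan, gen_lateral_scan

__all__ = [
    "ReferenceSetup",
    "lateral_scan_residuals",
    "depth_output_roundtrip",
    "sobp_simulation_roundtrip",
]

DEFAULT_PEAK_DEPTH_MM = 160.0
DEFAULT_MODULATION_MM = 80.0
DEFAULT_X_GRID = np.arange(-60.0, 61.0, 5.0)


@dataclass(frozen=True)
class ReferenceSetup:
    """Lazily built reference beam/geometry/engine for the experiments."""

    field_radius_mm: float = 100.0
    pencil_spacing_mm: float = 1.0

    def build(self) -> dict:
        pristine = make_pristine_bragg(DEFAULT_PEAK_DEPTH_MM)
        spec = fit_sobp_weights(pristine, DEFAULT_MODULATION_MM)
        geometry = BolusGeometry.l_shape()
        return {
            "pristine": pristine,
            "sobp_spec": spec,
            "sobp": synthesize_sobp(pristine, spec),
            "geometry": geometry,
            "sigma": SigmaModel(),
            "pencils": decompose_broad_beam(
                self.field_radius_mm, self.pencil_spacing_mm, geometry=geometry
            ),
        }


def _sub_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministic per-scan child seeds below 2**31."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


def lateral_scan_residuals(
    beam: str,
    slab_depths_mm: Sequence[float],
    seed: int,
    relative_sd: float = 0.014,
    setup: ReferenceSetup = ReferenceSetup(),
) -> np.ndarray:
    """Relative residuals (corrected - IC)/IC of the full L-bolus pipeline.

    For each slab depth a noisy synthetic lateral scan is generated (raw
    MOSFET = engine dose over the dose-weighted correction field, IC = engine
    dose, both with independent multiplicative reading noise), then corrected
    with the pencil-beam correction field and the printed table for the
    chosen beam (``"pristine"`` -> mono-energetic, ``"sobp"`` -> SOBP).
    Residuals are pooled over all scan points.
    """
    parts = setup.build()
    if beam == "pristine":
        dd, cf = parts["pristine"], MOSFET_CF_MONO
    elif beam == "sobp":
        dd, cf = parts["sobp"], MOSFET_CF_SOBP
    else:
        raise ValueError(f"unknown beam {beam!r}")
    x = DEFAULT_X_GRID
    seeds = _sub_seeds(seed, len(slab_depths_mm))
    residuals = []
    for depth, sub in zip(slab_depths_mm, seeds):
        tab = gen_lateral_scan(
            parts["geometry"], dd, cf, float(depth), x, parts["pencils"],
            parts["sigma"], NoiseModel(relative_sd, int(sub)),
        )
        pts = np.column_stack([x, np.zeros_like(x), np.full_like(x, float(depth))])
        cf_vals = correction_field(pts, parts["pencils"], cf, dd, parts["sigma"])
        corrected = cf_vals * tab["mosfet_raw"].to_numpy()
        ic = tab["ic"].to_numpy()
        residuals.append((corrected - ic) / ic)
    return np.concatenate(residuals)


def depth_output_roundtrip(
    cf: PiecewiseCorrection = MOSFET_CF_MONO,
    depth_step_mm: float = 1.0,
    max_depth_mm: float = 170.0,
) -> float:
    """Max relative deviation of the corrected noise-free depth-output curve
    from the IC pristine curve (raw = IC/cf, corrected = cf * raw)."""
    pristine = make_pristine_bragg(DEFAULT_PEAK_DEPTH_MM)
    depths = np.arange(0.0, max_depth_mm + depth_step_mm / 2, depth_step_mm)
    tab = gen_depth_scan(pristine, cf, depths, NoiseModel.off())
    ic = tab["ic"].to_numpy()
    corrected = np.asarray(cf(depths)) * tab["mosfet_raw"].to_numpy()
    nz = ic > 0
    return float(np.abs(corrected[nz] / ic[nz] - 1.0).max())


def sobp_simulation_roundtrip() -> tuple[float, int]:
    """Stepwise-SOBP round trip through the derived correction function.

    The IC SOBP is composed from shifted pristine components; the simulated
    uncorrected MOSFET SOBP divides each component by the mono-energetic
    correction at its effective depth; the SOBP correction is then derived
    from the two simulated curves and applied.  Returns the maximum relative
    deviation of the corrected curve from the IC SOBP over depths with dose
    above 1% of the plateau level, and the number of depths compared.
    """
    pristine = make_pristine_bragg(DEFAULT_PEAK_DEPTH_MM)
    spec = fit_sobp_weights(pristine, DEFAULT_MODULATION_MM)
    z = pristine.depths
    comps = np.stack([pristine(z + s) for s in spec.shifts], axis=1)
    ic = comps @ spec.weights
    mos = (comps / MOSFET_CF_MONO(z[:, None] + spec.shifts[None, :])) @ spec.weights
    derived = derive_cf_sobp(MOSFET_CF_MONO, pristine, spec)
    peak = pristine.peak_depth
    on_plateau = (z >= peak - spec.modulation_width) & (z <= peak)
    dom = ic > 0.01 * ic[on_plateau].mean()
    corrected = np.asarray(derived(z[dom])) * mos[dom]
    return float(np.abs(corrected / ic[dom] - 1.0).max()), int(dom.sum())
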