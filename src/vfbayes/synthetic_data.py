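"""Synthetic "measured" GAWs with known ground truth.

The generator stands in for a high-speed-video recording of silicone
folds: it runs the forward model at known material properties, samples
the result the way a camera would (integer-stride decimation to the frame
rate, start-up transient trimmed), and adds unbiased i.i.d. Gaussian
noise to each area sample, floored at zero because a segmented area
cannot be negative.  Noise is applied after downsampling -- measurement
noise lives at the camera rate.

What it does not emulate: segmentation artifacts, pixel quantisation,
left-right asymmetry, or the small residual opening real folds show
during the closed phase; recovery results on this data therefore probe
the inference machinery under the assumed error model, not robustness to
model error.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dynamics import simulate, DEFAULT_H_MS, DEFAULT_DURATION_MS
from .fe_core import MaterialProperties
from .geometry import build_default_geometry, triangulate
from .observation import GAWSeries, compute_gaw, downsample, trim_transient

__all__ = ["SyntheticSpec", "GenerationError", "generate_observation", "reference_truth"]


class GenerationError(RuntimeError):
    pass


def reference_truth() -> MaterialProperties:
    """Ground-truth silicone properties: body 11.8 kPa, cover 600 Pa,
    ligament 2 kPa, p_sub 1000 Pa, rho 1049.75 kg/m^3, nu 0.4995,
    p_sup 0, no medial compression.  No measured viscosity exists for the
    silicone; 3 Poise is used, the value the estimates consistently land on.
    """
    return MaterialProperties(
        rho=1049.75,
        eta_poise=3.0,
        e_bdy=11.8e3,
        e_cvr=600.0,
        e_lig=2.0e3,
        nu=0.4995,
        p_sub=1000.0,
        p_sup=0.0,
        x0_mm=8.40,
    )


@dataclass
class SyntheticSpec:
    """Conditions for one synthetic recording."""

    true_props: MaterialProperties
    noise_sd: float = 1.0  # mm^2, the generative counterpart of sigma_e
    fps: float = 2000.0
    duration_ms: float = DEFAULT_DURATION_MS  # simulated, pre-trim
    trim_ms: float = 250.0
    seed: int = 0
    mesh_target: int = 205
    h_ms: float = DEFAULT_H_MS

    def __post_init__(self):
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.duration_ms - self.trim_ms < 300.0 - 1e-9:
            raise ValueError("need at least 300 ms of signal after the trim")


def generate_observation(spec: SyntheticSpec, mesh=None) -> tuple[GAWSeries, dict]:
    """Simulate, sample like a camera, add noise; return (series, truth record).

    Raises :class:`GenerationError` when the true properties do not sustain
    oscillation (so a caller can pick a different truth).
    """
    if mesh is None:
        mesh = triangulate(build_default_geometry(), spec.mesh_target)
    result = simulate(
        spec.true_props,
        mesh,
        duration_ms=spec.duration_ms,
        h_ms=spec.h_ms,
        catch_blowup=True,
    )
    if not result.ok:
        raise GenerationError(f"simulation failed at step {result.failed_step}")
    gaw = trim_transient(downsample(compute_gaw(result), spec.fps), spec.trim_ms)
    n = len(gaw)
    # sustained-oscillation gate: the waveform must keep swinging at the end
    half = n // 2
    pp_late = np.ptp(gaw.area[half:])
    pp_early = np.ptp(gaw.area[:half])
    if pp_late < 0.5 or pp_late < 0.25 * pp_early:
        raise GenerationError("no sustained oscillation at the true properties")
    rng = np.random.default_rng(spec.seed)
    clean = gaw.area
    noisy = np.maximum(0.0, clean + rng.normal(0.0, spec.noise_sd, size=n))
    peak = float(clean.max())
    series = GAWSeries(
        t=gaw.t,
        area=noisy,
        fps=spec.fps,
        meta={
            "provenance": "simulated",
            "noise_sd_mm2": spec.noise_sd,
            "noise_to_peak": spec.noise_sd / peak if peak > 0 else np.inf,
        },
    )
    truth = {
        "props": spec.true_props,
        "noise_sd": spec.noise_sd,
        "fps": spec.fps,
        "duration_ms": spec.duration_ms,
        "trim_ms": spec.trim_ms,
        "seed": spec.seed,
        "mesh_target": spec.mesh_target,
        "h_ms": spec.h_ms,
        "peak_area_mm2": peak,
        "realized_noise_to_peak": spec.noise_sd / peak if peak > 0 else np.inf,
    }
    return series, truth
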