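"""Glottal area waveform (GAW) handling: extraction, sampling, metrics.

The observable shared by the simulator and high-speed videoendoscopy is
the projected open area between the folds.  For the symmetric 2D model the
glottal width is twice the gap between the midline and the most medial
free-surface node, and the area is that width times the glottal length:

    W_gl(t) = 2 * max(0, midline_x - max_i x_i(t)),   A_s = l_gl * W_gl.

Measured series come from camera frames (e.g. 2000 fps, 24.4 px/mm);
simulated series are produced at the solver rate (20,000 fps at the
default step) and are decimated by an integer stride to the camera rate,
trimmed of the start-up transient, and phase-aligned to the measurement by
cross-correlating the first two cycles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "GAWSeries",
    "WindowError",
    "AlignmentError",
    "MetricsError",
    "GAWParseError",
    "compute_gaw",
    "pixel_area",
    "downsample",
    "trim_transient",
    "phase_align",
    "gaw_metrics",
    "read_gaw_csv",
    "write_gaw_csv",
]

OPEN_THRESHOLD_FRAC = 0.01  # cycle-detection threshold, fraction of max area


class WindowError(ValueError):
    pass


class AlignmentError(ValueError):
    pass


class MetricsError(ValueError):
    pass


class GAWParseError(ValueError):
    pass


@dataclass
class GAWSeries:
    """Uniformly sampled glottal area vs time (s, mm^2)."""

    t: np.ndarray
    area: np.ndarray
    fps: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, float)
        self.area = np.asarray(self.area, float)
        if self.t.shape != self.area.shape:
            raise ValueError("time and area must have equal length")
        if len(self.t) > 1:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fps) > 1e-9):
                raise ValueError("sampling must be uniform at 1/fps")
        if np.any(self.area < 0):
            raise ValueError("areas must be non-negative")

    def __len__(self) -> int:
        return len(self.t)


def compute_gaw(result, geom=None) -> GAWSeries:
    """Simulated GAW at the solver rate from a :class:`SimulationResult`."""
    return GAWSeries(
        t=result.times,
        area=result.gaw_raw,
        fps=result.fps,
        meta={"provenance": "simulated"},
    )


def pixel_area(resolution_px_per_mm: float) -> float:
    """Physical area of one camera pixel in mm^2 (24.4 px/mm -> 1.680e-3)."""
    if resolution_px_per_mm <= 0:
        raise ValueError("resolution must be positive")
    return (1.0 / resolution_px_per_mm) ** 2


def downsample(gaw: GAWSeries, target_fps: float) -> GAWSeries:
    """Integer-stride decimation (keep every k-th sample, k = fps/target).

    No anti-alias filtering and no interpolation: the source is a smooth
    simulated signal and the decimation ratio must be an integer.
    """
    ratio = gaw.fps / target_fps
    k = int(round(ratio))
    if abs(ratio - k) > 1e-9 or k < 1:
        raise ValueError(
            f"fps ratio {gaw.fps}/{target_fps} is not a positive integer"
        )
    return GAWSeries(
        t=gaw.t[::k], area=gaw.area[::k], fps=target_fps, meta=dict(gaw.meta)
    )


def trim_transient(gaw: GAWSeries, trim_ms: float) -> GAWSeries:
    """Drop samples with t < trim and reset the time origin to zero."""
    keep = gaw.t >= trim_ms * 1e-3 - 1e-12
    if not np.any(keep):
        raise WindowError(f"trim of {trim_ms} ms leaves no samples")
    t = gaw.t[keep]
    return GAWSeries(t=t - t[0], area=gaw.area[keep], fps=gaw.fps, meta=dict(gaw.meta))


def _cycle_onsets(area: np.ndarray) -> np.ndarray:
    """Indices where the signal crosses the 1%-of-max threshold upward."""
    thr = OPEN_THRESHOLD_FRAC * area.max()
    above = area > thr
    onsets = np.nonzero(~above[:-1] & above[1:])[0] + 1
    return onsets


def _period_estimate(area: np.ndarray) -> int:
    """Fundamental period in samples from the autocorrelation peak.

    More robust against measurement noise than threshold crossings (a
    noise standard deviation comparable to the 1% open threshold makes
    crossing counts chatter).  Raises :class:`AlignmentError` when no
    periodicity is detectable.
    """
    a = area - area.mean()
    n = len(a)
    if n < 8 or np.allclose(a, 0.0):
        raise AlignmentError("signal too short or constant")
    ac = np.correlate(a, a, mode="full")[n - 1 :]
    if ac[0] <= 0:
        raise AlignmentError("degenerate autocorrelation")
    # step past the zero-lag main lobe before looking for the cycle peak
    below = np.nonzero(ac < 0.5 * ac[0])[0]
    if below.size == 0:
        raise AlignmentError("no periodicity detected")
    lo = int(below[0])
    hi = n // 2
    if hi <= lo:
        raise AlignmentError("signal too short for period detection")
    seg = ac[lo:hi]
    imax = int(np.argmax(seg))
    if imax == 0 or seg[imax] < 0.2 * ac[0]:
        # no rebound after the main lobe: monotone or aperiodic signal
        raise AlignmentError("no periodicity detected")
    return lo + imax


def phase_align(sim: GAWSeries, meas: GAWSeries) -> GAWSeries:
    """Shift the simulated series by the integer-sample lag that maximises
    the cross-correlation of the mean-removed first-two-cycle windows.

    The lag is searched within a single fundamental period (estimated from
    the measurement's autocorrelation): whole-period shifts are
    unidentifiable for a near-periodic signal, and accepting one would
    compare unrelated cycles downstream.  Falls back to zero shift (with
    ``meta['alignment_warning']``) when two cycles cannot be detected in
    both signals.  The returned series is the shifted simulation cropped
    to the overlap with the measurement.
    """
    if abs(sim.fps - meas.fps) > 1e-9:
        raise AlignmentError("series must share a sampling rate")
    try:
        period = _period_estimate(meas.area)
        win = 2 * period
        if len(_cycle_onsets(sim.area)) < 3 and _period_estimate(sim.area) > len(sim) // 2:
            raise AlignmentError("fewer than two cycles in the simulation")
    except AlignmentError:
        warnings.warn("phase_align: fewer than two cycles; zero shift", stacklevel=2)
        n = min(len(sim), len(meas))
        meta = dict(sim.meta, alignment_warning=True, alignment_shift=0)
        return GAWSeries(sim.t[:n], sim.area[:n], sim.fps, meta)
    win = min(win, len(sim), len(meas))
    a = meas.area[:win] - meas.area[:win].mean()
    # lag >= 0 means the simulation leads and is advanced by `lag` samples
    max_lag = min(period - 1, len(sim) - win)
    lags = np.arange(0, max(max_lag, 0) + 1)
    scores = np.array(
        [
            np.dot(a, sim.area[k : k + win] - sim.area[k : k + win].mean())
            for k in lags
        ]
    )
    shift = int(lags[np.argmax(scores)])
    n = min(len(sim) - shift, len(meas))
    meta = dict(sim.meta, alignment_shift=shift)
    return GAWSeries(sim.t[:n], sim.area[shift : shift + n], sim.fps, meta)


def gaw_metrics(gaw: GAWSeries) -> dict:
    """Per-cycle waveform metrics averaged over complete cycles.

    Cycles are delimited by upward crossings of 1% of the maximum area;
    OQ = open time / period, SQ = opening time / closing time with the
    in-cycle peak splitting the open phase, f0 from the mean period.
    """
    area = gaw.area
    onsets = _cycle_onsets(area)
    if len(onsets) < 4:
        raise MetricsError("need at least three complete cycles")
    thr = OPEN_THRESHOLD_FRAC * area.max()
    periods, oqs, sqs = [], [], []
    for a, b in zip(onsets[:-1], onsets[1:]):
        seg = area[a:b]
        open_mask = seg > thr
        peak = int(np.argmax(seg))
        open_len = int(open_mask.sum())
        offs = np.nonzero(~open_mask)[0]
        close_idx = int(offs[offs > peak][0]) if np.any(offs > peak) else len(seg)
        periods.append(b - a)
        oqs.append(open_len / (b - a))
        opening = max(peak, 1)
        closing = max(close_idx - peak, 0)
        sqs.append(opening / closing if closing > 0 else np.inf)
    dt = 1.0 / gaw.fps
    return {
        "f0": 1.0 / (np.mean(periods) * dt),
        "max_area": float(area.max()),
        "open_quotient": float(np.mean(oqs)),
        "speed_quotient": float(np.mean(sqs)),
        "n_cycles": len(periods),
    }


# ---------------------------------------------------------------------------
# CSV I/O: two columns (time_s, area_mm2), comment header with fps/calibration


def write_gaw_csv(gaw: GAWSeries, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# fps = {gaw.fps:.12g}\n")
        for key, val in gaw.meta.items():
            fh.write(f"# {key} = {val}\n")
        fh.write("time_s,area_mm2\n")
        for t, a in zip(gaw.t, gaw.area):
            fh.write(f"{t:.12g},{a:.12g}\n")


def read_gaw_csv(path) -> GAWSeries:
    meta, rows = {}, []
    fps = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if "=" in line:
                    key, val = (s.strip() for s in line[1:].split("=", 1))
                    if key == "fps":
                        fps = float(val)
                    else:
                        meta[key] = val
                continue
            if line.startswith("time_s"):
                continue
            parts = line.split(",")
            if len(parts) != 2:
                raise GAWParseError(f"ragged row: {line!r}")
            rows.append((float(parts[0]), float(parts[1])))
    if not rows:
        raise GAWParseError("empty GAW file")
    arr = np.array(rows)
    t, area = arr[:, 0], arr[:, 1]
    if np.any(np.diff(t) <= 0):
        raise GAWParseError("time column must increase monotonically")
    if fps is None:
        fps = 1.0 / np.median(np.diff(t))
        warnings.warn("no fps header; inferred from median dt", stacklevel=2)
    dt = np.diff(t)
    if len(t) > 1 and np.any(np.abs(dt - 1.0 / fps) > 1e-9):
        raise GAWParseError("non-uniform timestamps")
    return GAWSeries(t=t, area=area, fps=fps, meta=meta)
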