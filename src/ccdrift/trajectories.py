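"""Endpoint detection on noisy FUCCI trajectories.

Division times and G1->S transitions are recovered from the marker
traces of a tracked cell line:

1. the noise level is estimated and the traces smoothed by local
   weighted least squares with a degree-2 polynomial (Savitzky-Golay),
2. the Geminin trace is differentiated numerically,
3. divisions are the sharp drops of Geminin — local minima of its
   derivative below a prominence threshold,
4. within each division interval, the G1->S transition is the maximum of
   the smoothed Cdt1 trace (the peak just before its rapid drop).

Traces failing quality control (flat signal, extreme noise, boundary
peaks, missing divisions) are flagged with a reason rather than
silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks, savgol_filter

from .proteins import Trajectory

__all__ = [
    "DetectionParams",
    "EndpointAnnotation",
    "smooth_trajectory",
    "numerical_derivative",
    "detect_divisions",
    "detect_g1s_transition",
    "extract_phase_durations",
    "annotate_trajectory",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable knobs of the endpoint-detection procedure.

    window_h           smoothing window (hours); if None, chosen from the
                       estimated relative noise as clamp(8*sigma_rel, 1, 4)
    min_separation_h   minimum spacing between detected divisions
    prominence_factor  division minima must dip below prominence_factor x
                       median |dG/dt|
    high_noise_rel     relative-noise level above which a trace fails QC
    flat_rel           relative dynamic range below which a trace is "flat"
    """

    window_h: float | None = 2.0
    min_separation_h: float = 5.0
    prominence_factor: float = 2.0
    high_noise_rel: float = 0.5
    flat_rel: float = 0.05


@dataclass
class EndpointAnnotation:
    """Detected events of one trace plus a pass/fail quality flag."""

    cell_id: str
    division_times: list[float]
    g1s_times: list[float]
    quality_flag: str = "pass"
    reasons: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.quality_flag == "pass"


def _grid_step(time: np.ndarray) -> float:
    steps = np.diff(time)
    if len(steps) == 0 or not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise ValueError("trajectory requires a uniform time grid")
    return float(steps[0])


def estimate_relative_noise(series: np.ndarray, window_pts: int = 9) -> float:
    """Median relative residual of a first-pass local-quadratic fit."""
    n = len(series)
    w = min(window_pts if window_pts % 2 else window_pts + 1, n - (1 - n % 2))
    if w < 5:
        return 0.0
    resid = series - savgol_filter(series, w, 2)
    scale = max(float(np.median(np.abs(series))), 1e-12)
    return float(np.median(np.abs(resid)) / scale)


def smooth_trajectory(traj: Trajectory, window_h: float | None = None) -> Trajectory:
    """Local weighted least-squares smoothing with a degree-2 polynomial.

    Window defaults to the noise-adaptive rule clamp(8*sigma_rel, 1 h, 4 h).
    Constants and exact quadratics pass through unchanged.
    """
    dt = _grid_step(traj.time)
    n = len(traj.time)
    if window_h is None:
        sig = max(
            estimate_relative_noise(traj.cdt1), estimate_relative_noise(traj.geminin)
        )
        window_h = float(np.clip(8.0 * sig, 1.0, 4.0))
    w = int(round(window_h / dt))
    w = w + 1 if w % 2 == 0 else w
    w = max(w, 5)
    if n < 2 * w:
        raise ValueError(f"series too short ({n} points) for window of {w} points")
    return Trajectory(
        time=traj.time.copy(),
        cdt1=savgol_filter(traj.cdt1, w, 2),
        geminin=savgol_filter(traj.geminin, w, 2),
        cell_id=traj.cell_id,
    )


def numerical_derivative(series: np.ndarray, dt: float) -> np.ndarray:
    """Central differences in the interior, one-sided at the ends."""
    series = np.asarray(series, dtype=float)
    if len(series) < 3:
        raise ValueError("need at least 3 points to differentiate")
    d = np.empty_like(series)
    d[1:-1] = (series[2:] - series[:-2]) / (2 * dt)
    d[0] = (series[1] - series[0]) / dt
    d[-1] = (series[-1] - series[-2]) / dt
    return d


def detect_divisions(
    geminin_derivative: np.ndarray,
    time: np.ndarray,
    params: DetectionParams = DetectionParams(),
) -> list[float]:
    """Division times: local minima of dG/dt below the prominence threshold.

    Minima closer than ``min_separation_h`` are resolved in favour of the
    deeper one.  Returns an empty list for monotone traces.
    """
    dt = _grid_step(time)
    thresh = params.prominence_factor * float(np.median(np.abs(geminin_derivative)))
    idx, _ = find_peaks(
        -geminin_derivative,
        height=max(thresh, 1e-12),
        distance=max(1, int(round(params.min_separation_h / dt))),
    )
    return [float(time[i]) for i in idx]


def detect_g1s_transition(
    cdt1_series: np.ndarray,
    time: np.ndarray,
    division_interval: tuple[float, float],
    flat_rel: float = 0.05,
) -> tuple[float | None, str]:
    """G1->S transition: argmax of smoothed Cdt1 within a division interval.

    Returns ``(time, "ok")`` or ``(None, reason)`` where reason is
    ``"no peak"`` for flat signal or ``"peak at boundary"`` when the
    maximum sits on the interval edge (truncated peak).
    """
    lo, hi = division_interval
    mask = (time > lo) & (time < hi)
    if not np.any(mask):
        raise ValueError(f"empty division interval ({lo}, {hi})")
    seg = cdt1_series[mask]
    tseg = time[mask]
    rng_rel = (seg.max() - seg.min()) / max(abs(seg.max()), 1e-12)
    if rng_rel < flat_rel:
        return None, "no peak"
    i = int(np.argmax(seg))
    if i == 0 or i == len(seg) - 1:
        return None, "peak at boundary"
    return float(tseg[i]), "ok"


def extract_phase_durations(annotation: EndpointAnnotation) -> list[tuple[float, float]]:
    """Per complete cycle (t_g1, t_sg2m) from detected events.

    A complete cycle has both a birth (preceding division) and a division
    plus one G1->S time strictly inside; incomplete cycles are excluded.
    """
    out = []
    divs = sorted(annotation.division_times)
    for birth, division in zip(divs[:-1], divs[1:]):
        inside = [g for g in annotation.g1s_times if birth < g < division]
        if len(inside) != 1:
            continue
        g1s = inside[0]
        out.append((g1s - birth, division - g1s))
    return out


def annotate_trajectory(
    traj: Trajectory, params: DetectionParams = DetectionParams()
) -> EndpointAnnotation:
    """Full endpoint-detection pipeline for one trace."""
    reasons: list[str] = []
    dt = _grid_step(traj.time)
    sig_rel = max(
        estimate_relative_noise(traj.cdt1), estimate_relative_noise(traj.geminin)
    )
    if sig_rel > params.high_noise_rel:
        reasons.append("high-noise")
    span_g = traj.geminin.max() - traj.geminin.min()
    span_c = traj.cdt1.max() - traj.cdt1.min()
    if span_g < params.flat_rel * max(traj.geminin.max(), 1e-12) and span_c < (
        params.flat_rel * max(traj.cdt1.max(), 1e-12)
    ):
        reasons.append("flat-signal")
        return EndpointAnnotation(traj.cell_id, [], [], "fail", reasons)

    smoothed = smooth_trajectory(traj, params.window_h)
    dgem = numerical_derivative(smoothed.geminin, dt)
    divisions = detect_divisions(dgem, smoothed.time, params)
    if len(divisions) < 2:
        reasons.append("missing-division")
        return EndpointAnnotation(traj.cell_id, divisions, [], "fail", reasons)

    g1s_times = []
    for lo, hi in zip(divisions[:-1], divisions[1:]):
        t_peak, why = detect_g1s_transition(
            smoothed.cdt1, smoothed.time, (lo, hi), params.flat_rel
        )
        if t_peak is None:
            reasons.append(why)
        else:
            g1s_times.append(t_peak)
    flag = "fail" if reasons else "pass"
    return EndpointAnnotation(traj.cell_id, divisions, g1s_times, flag, reasons)
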