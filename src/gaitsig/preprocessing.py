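"""Raw-signal preprocessing: filtering, gait events, cycle normalization,
and spatiotemporal parameters.

Units throughout: angles in degrees, lengths in metres, forces in
newtons, times in seconds.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, interp1d
from scipy.signal import butter, filtfilt

if TYPE_CHECKING:  # pragma: no cover
    from .synthetic import GaitTrial

__all__ = [
    "GaitEvents",
    "AngleWaveformSet",
    "butterworth_lowpass",
    "detect_gait_events",
    "normalize_cycle",
    "spatiotemporal_params",
]


@dataclass
class GaitEvents:
    """Ordered heel-strike and toe-off times per side.

    ``provenance`` is "force" for events detected from the vertical GRF
    and "manual" for externally supplied events (the fallback when force
    data are unusable).
    """

    heel_strikes: dict = field(default_factory=dict)   # side -> sorted times
    toe_offs: dict = field(default_factory=dict)
    provenance: str | None = None

    def validate(self):
        for side, hs in self.heel_strikes.items():
            hs = np.asarray(hs)
            to = np.asarray(self.toe_offs.get(side, []))
            if np.any(np.diff(hs) <= 0) or np.any(np.diff(to) <= 0):
                raise ValueError(f"GaitEvents: {side} event times not increasing")
            # toe-offs must interleave: each toe-off follows its heel strike
            for t in to:
                if not np.any(hs <= t):
                    raise ValueError(f"GaitEvents: {side} toe-off before first heel strike")
        return self


@dataclass
class AngleWaveformSet:
    """One participant's joint-angle continua on a fixed gait-cycle grid.

    ``curves`` maps (joint, plane, side, stride) to a vector of
    ``node_count`` angles in degrees at nodes 0..100 %GC.
    """

    participant_id: str
    curves: dict
    node_count: int = 101

    def __post_init__(self):
        for key, v in self.curves.items():
            v = np.asarray(v, dtype=float)
            if v.size != self.node_count or np.any(~np.isfinite(v)):
                raise ValueError(
                    f"AngleWaveformSet[{self.participant_id}]: curve {key} must "
                    f"have {self.node_count} finite values"
                )
            self.curves[key] = v

    def mean_curve(self, joint: str, plane: str, sides=("left", "right")) -> np.ndarray:
        """Participant mean curve over strides and the requested sides."""
        stack = [
            v for (j, p, s, _), v in self.curves.items()
            if j == joint and p == plane and s in sides
        ]
        if not stack:
            raise KeyError(f"no curves for ({joint}, {plane}) in {self.participant_id}")
        return np.mean(stack, axis=0)

    def joint_planes(self):
        return sorted({(j, p) for (j, p, _, _) in self.curves})


def butterworth_lowpass(
    signal, fs: float, fc: float, order: int = 4, dual_pass: bool = True
):
    """Zero-lag Butterworth low-pass filter.

    ``order`` is the single-pass order; with ``dual_pass`` the filter is
    applied forward and backward (zero net phase shift, attenuation equal
    to the squared single-pass magnitude: -6 dB at fc for order 4).
    Reflective padding of three filter lengths suppresses edge
    transients.
    """
    x = np.asarray(signal, dtype=float)
    if fc >= fs / 2:
        raise ValueError("butterworth_lowpass: fc must be below Nyquist")
    if dual_pass and order % 2 != 0:
        raise ValueError("butterworth_lowpass: dual_pass needs an even order")
    b, a = butter(order, fc, fs=fs, btype="low")
    padlen = 3 * (max(len(a), len(b)) - 1)
    if x.shape[-1] <= padlen:
        raise ValueError(
            f"butterworth_lowpass: series of length {x.shape[-1]} shorter than "
            f"filter warm-up ({padlen + 1} samples)"
        )
    if dual_pass:
        return filtfilt(b, a, x, padtype="even", padlen=padlen)
    from scipy.signal import lfilter

    return lfilter(b, a, x)


def _interp_crossing(t0, t1, y0, y1, level):
    # linear interpolation of a threshold crossing between two samples
    if y1 == y0:
        return t0
    return t0 + (level - y0) * (t1 - t0) / (y1 - y0)


def detect_gait_events(
    trial: "GaitTrial",
    threshold: float = 0.05,
    min_stance: float = 0.1,
    debounce: float = 0.05,
) -> GaitEvents:
    """Detect heel strikes and toe-offs from vertical GRF.

    Heel strike is an upward crossing of ``threshold`` x body weight
    sustained for at least ``min_stance`` seconds; toe-off is the
    subsequent downward crossing.  Sub-threshold gaps shorter than
    ``debounce`` are bridged, and above-threshold bursts shorter than
    ``min_stance`` discarded.  Crossing times are refined by linear
    interpolation between samples.  With no crossings at all the result
    is empty with no provenance flag (caller supplies manual events).
    """
    if not (0 < threshold <= 0.2):
        raise ValueError("detect_gait_events: threshold must be in (0, 0.2]")
    level = threshold * trial.body_weight
    t = trial.time
    events = GaitEvents(provenance=None)
    any_events = False
    for side, f in trial.grf_vert.items():
        above = f > level
        runs = []
        start = None
        for i in range(t.size):
            if above[i] and start is None:
                start = i
            elif not above[i] and start is not None:
                runs.append((start, i))
                start = None
        if start is not None:
            runs.append((start, t.size))
        merged = []
        for run in runs:
            if merged and t[run[0]] - t[merged[-1][1] - 1] < debounce:
                merged[-1] = (merged[-1][0], run[1])
            else:
                merged.append(run)
        hs_list, to_list = [], []
        for i0, i1 in merged:
            if t[min(i1, t.size - 1)] - t[i0] < min_stance:
                continue
            hs = (
                _interp_crossing(t[i0 - 1], t[i0], f[i0 - 1], f[i0], level)
                if i0 > 0 else t[i0]
            )
            hs_list.append(hs)
            if i1 < t.size:
                to_list.append(
                    _interp_crossing(t[i1 - 1], t[i1], f[i1 - 1], f[i1], level)
                )
        if hs_list:
            any_events = True
        events.heel_strikes[side] = hs_list
        events.toe_offs[side] = to_list
    if any_events:
        events.provenance = "force"
    else:
        warnings.warn(
            "detect_gait_events: no threshold crossings found; supply manual events"
        )
    return events.validate()


def normalize_cycle(
    times, values, hs_start: float, hs_next: float, node_count: int = 101
) -> np.ndarray:
    """Resample one gait cycle onto ``node_count`` evenly spaced nodes.

    Node k holds the interpolated value at
    ``hs_start + (k / (node_count-1)) * (hs_next - hs_start)``; nodes 0
    and 100 therefore equal the series values at the two heel strikes.
    Piecewise cubic interpolation, with a linear fallback when fewer than
    4 samples fall in the cycle.
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if not (hs_start < hs_next):
        raise ValueError("normalize_cycle: hs_start must precede hs_next")
    if hs_start < times[0] or hs_next > times[-1]:
        raise ValueError("normalize_cycle: events outside series support")
    nodes = hs_start + np.linspace(0.0, 1.0, node_count) * (hs_next - hs_start)
    n_inside = int(np.sum((times >= hs_start) & (times <= hs_next)))
    if n_inside >= 4:
        return CubicSpline(times, values)(nodes)
    return interp1d(times, values)(nodes)


@dataclass(frozen=True)
class SpatioTemporal:
    gait_speed_ms: float
    cycle_time_s: float
    stride_length_m: float
    stride_width_m: float | None
    cadence_spm: float


def spatiotemporal_params(trial: "GaitTrial", events: GaitEvents):
    """Per-stride spatiotemporal parameters and their participant means.

    Per stride (consecutive ipsilateral heel strikes): cycle time is the
    heel-strike interval; stride length the anterior-posterior heel
    displacement over it; stride width the absolute medio-lateral
    distance between the two feet's heel positions at their respective
    heel strikes within the cycle; speed = stride length / cycle time;
    cadence = 120 / cycle time (steps/min).  Cycles without a
    contralateral heel strike report stride width as missing.

    Returns ``(per_stride_df, means_dict)``.
    """
    t = trial.time
    rows = []
    other = {"left": "right", "right": "left"}
    for side, hs in events.heel_strikes.items():
        hs = np.asarray(hs, dtype=float)
        if hs.size < 2:
            continue
        ap = interp1d(t, trial.heel_ap[side])
        ml = interp1d(t, trial.heel_ml[side])
        contra = np.asarray(events.heel_strikes.get(other[side], []), dtype=float)
        if contra.size:
            ml_contra = interp1d(t, trial.heel_ml[other[side]])
        for k in range(hs.size - 1):
            t0, t1 = hs[k], hs[k + 1]
            cycle = t1 - t0
            length = float(abs(ap(t1) - ap(t0)))
            inside = contra[(contra > t0) & (contra < t1)] if contra.size else []
            if len(inside):
                width = float(abs(ml(t0) - ml_contra(inside[0])))
            else:
                width = None
            rows.append(
                {
                    "side": side,
                    "stride": k,
                    "cycle_time_s": cycle,
                    "stride_length_m": length,
                    "stride_width_m": width,
                    "gait_speed_ms": length / cycle,
                    "cadence_spm": 120.0 / cycle,
                }
            )
    if not rows:
        raise ValueError("spatiotemporal_params: no complete gait cycle")
    df = pd.DataFrame(rows)
    means = {
        k: float(df[k].dropna().mean()) if df[k].notna().any() else None
        for k in (
            "gait_speed_ms", "cycle_time_s", "stride_length_m",
            "stride_width_m", "cadence_spm",
        )
    }
    return df, means
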