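"""Synthetic gait-cohort generator.

Generates complete study-shaped datasets — demographics, joint-angle
waveforms on a 101-node gait-cycle grid, and raw walking-trial signals
(heel-marker trajectories and vertical ground reaction force) — with the
statistical structure the downstream analyses assume:

* two groups (cases with iNPH-like gait, healthy controls) of
  configurable size, defaulting to 23 vs 18;
* per-participant mean curves = a normative Fourier template
  + a group effect on selected gait-cycle regions (cases only)
  + a smooth subject-level deviation (white Gaussian noise convolved
    with a Gaussian kernel of configurable FWHM, rescaled to a target
    SD) — a stationary smooth random field, which random field theory
    assumes;
* independent smooth stride-to-stride noise per recorded stride;
* spatiotemporal parameters and demographics drawn from configurable
  group means/SDs (defaults follow the reference study's summaries).

Randomness: one master seed; each participant consumes dedicated
substreams keyed by (seed, participant index, stream), so changing the
cohort size never reshuffles existing participants.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .datasets import DEMOGRAPHICS_SUMMARY, SPATIOTEMPORAL_SUMMARY, STUDY_REGIONS

__all__ = [
    "SimConfig",
    "EffectSpec",
    "ParticipantRecord",
    "GaitTrial",
    "DEFAULT_TEMPLATES",
    "study_effect_presets",
    "generate_participants",
    "generate_spatiotemporal",
    "generate_waveforms",
    "generate_trial_signals",
    "smooth_gaussian_field",
]

_FWHM_TO_SIGMA = 1.0 / math.sqrt(8.0 * math.log(2.0))

# Normative mean-curve templates: (joint, plane) -> (a0, [(a_k, b_k), ...])
# evaluated as a0 + sum_k a_k cos(2 pi k x) + b_k sin(2 pi k x), x = node/100.
# Coefficients are truncated Fourier series of hand-sketched curves that
# qualitatively match adult gait (knee sagittal: stance flexion wave plus a
# large swing flexion peak near 70 %GC; ankle sagittal: dorsiflexion through
# stance, plantarflexion burst at push-off; pelvis curves near-sinusoidal).
DEFAULT_TEMPLATES: dict[tuple[str, str], tuple[float, list[tuple[float, float]]]] = {
    ("pelvis", "sagittal"): (11.800, [(-0.568, 0.234), (0.637, -0.314), (0.126, 0.062), (-0.002, -0.001), (0.000, 0.000)]),
    ("pelvis", "frontal"): (0.329, [(2.795, 0.190), (-1.635, 1.084), (-0.275, 0.170), (-0.166, 0.025), (-0.015, -0.011)]),
    ("pelvis", "transverse"): (0.000, [(5.913, 0.000), (0.000, 0.000), (0.073, 0.000), (0.000, 0.000), (0.009, 0.000)]),
    ("hip", "sagittal"): (12.853, [(20.280, -3.543), (-2.973, -1.989), (-0.212, 0.427), (0.143, -0.077), (-0.064, -0.025)]),
    ("hip", "frontal"): (0.943, [(3.026, 5.473), (-0.702, -0.740), (-0.259, 0.233), (0.010, -0.029), (-0.015, 0.000)]),
    ("hip", "transverse"): (-1.492, [(0.513, 1.574), (-1.637, -1.664), (-0.277, -0.003), (-0.055, 0.040), (-0.048, 0.022)]),
    ("knee", "sagittal"): (20.530, [(-2.254, -19.949), (-13.061, 7.807), (0.765, 6.083), (-0.074, 0.094), (-0.533, -0.403)]),
    ("knee", "frontal"): (0.878, [(0.365, -0.502), (-1.351, 0.777), (0.133, 0.043), (-0.012, -0.064), (0.000, -0.006)]),
    ("knee", "transverse"): (-0.356, [(-0.276, -0.804), (-3.277, -0.514), (-0.066, 0.203), (0.038, -0.052), (-0.022, 0.014)]),
    ("ankle", "sagittal"): (0.887, [(1.104, 1.458), (-0.793, -10.160), (-2.193, 2.351), (1.211, -0.334), (-0.255, -0.176)]),
    ("ankle", "frontal"): (0.358, [(-0.463, 3.213), (-0.515, -2.919), (-0.439, 0.630), (0.094, -0.062), (-0.031, 0.031)]),
    ("ankle", "transverse"): (-0.712, [(-4.456, -0.396), (0.208, 0.201), (-0.031, -0.038), (-0.003, 0.004), (-0.003, -0.005)]),
}

_DEFAULT_JOINTS = [
    (joint, plane, side)
    for (joint, plane) in DEFAULT_TEMPLATES
    for side in ("left", "right")
]


@dataclass(frozen=True)
class EffectSpec:
    """Additive group effect on a gait-cycle region of one joint-plane.

    ``shape`` is "bump" (raised cosine over the region, zero at its
    edges — keeps the field smooth) or "boxcar" (constant over the
    region; used for unit tests of cluster localisation).
    """

    joint: str
    plane: str
    start_pct: float
    end_pct: float
    amplitude_deg: float
    shape: str = "bump"
    side: str = "both"

    def __post_init__(self):
        if not (0 <= self.start_pct < self.end_pct <= 100):
            raise ValueError(
                "EffectSpec: need 0 <= start_pct < end_pct <= 100, got "
                f"[{self.start_pct}, {self.end_pct}]"
            )
        if not np.isfinite(self.amplitude_deg):
            raise ValueError("EffectSpec: amplitude_deg must be finite")
        if self.shape not in ("bump", "boxcar"):
            raise ValueError(f"EffectSpec: unknown shape {self.shape!r}")

    def profile(self, node_count: int) -> np.ndarray:
        x = np.linspace(0.0, 100.0, node_count)
        y = np.zeros(node_count)
        inside = (x >= self.start_pct) & (x <= self.end_pct)
        if self.shape == "boxcar":
            y[inside] = self.amplitude_deg
        else:
            tau = (x[inside] - self.start_pct) / (self.end_pct - self.start_pct)
            y[inside] = self.amplitude_deg * 0.5 * (1 - np.cos(2 * np.pi * tau))
        return y


def study_effect_presets(amplitude_scale: float = 1.0) -> list[EffectSpec]:
    """Effect specs at the gait-cycle regions the reference study reported.

    The default amplitude of 3 degrees (signed by the reported direction
    of the case-minus-control difference) yields peak t statistics near 3
    at the study's group sizes with the default 3-degree subject noise,
    matching the magnitude of the reported effects.
    """
    return [
        EffectSpec(joint, plane, start, end, 3.0 * direction * amplitude_scale)
        for joint, plane, start, end, direction in STUDY_REGIONS
    ]


def _group_spec(summary, key):
    return {g: summary[g][key] for g in ("case", "control")}


@dataclass(frozen=True)
class SimConfig:
    """All generator parameters, with study-shaped defaults."""

    n_group_a: int = 23                    # cases
    n_group_b: int = 18                    # controls
    node_count: int = 101
    joints: list = field(default_factory=lambda: list(_DEFAULT_JOINTS))
    templates: dict = field(default_factory=lambda: dict(DEFAULT_TEMPLATES))
    effect_specs: list = field(default_factory=study_effect_presets)
    subject_noise_sd: float = 3.0          # degrees, between-subject
    subject_noise_fwhm: float = 15.0       # nodes
    stride_noise_sd: float = 1.0           # degrees, per stride
    strides_per_subject: int = 4
    sampling_rate_hz: float = 100.0
    stance_fraction: float = 0.6
    # per-group (mean, sd[, n]) for gait parameters and demographics
    spatiotemporal: dict = field(
        default_factory=lambda: {
            g: {k: v[:2] for k, v in SPATIOTEMPORAL_SUMMARY[g].items()}
            for g in ("case", "control")
        }
    )
    demographics: dict = field(
        default_factory=lambda: {
            g: {
                "p_male": DEMOGRAPHICS_SUMMARY[g]["males"]
                / DEMOGRAPHICS_SUMMARY[g]["n"],
                "sex_counts": (
                    DEMOGRAPHICS_SUMMARY[g]["males"],
                    DEMOGRAPHICS_SUMMARY[g]["females"],
                ),
                "age": DEMOGRAPHICS_SUMMARY[g]["age"],
                "mass": DEMOGRAPHICS_SUMMARY[g]["mass"],
                "height": DEMOGRAPHICS_SUMMARY[g]["height"],
            }
            for g in ("case", "control")
        }
    )
    seed: int = 0

    def __post_init__(self):
        for name in ("n_group_a", "n_group_b"):
            if getattr(self, name) < 2:
                raise ValueError(f"SimConfig: {name} must be >= 2")
        if self.node_count < 11:
            raise ValueError("SimConfig: node_count must be >= 11")
        for name in ("subject_noise_sd", "stride_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"SimConfig: {name} must be >= 0")
        if self.strides_per_subject < 2:
            raise ValueError("SimConfig: strides_per_subject must be >= 2")
        if self.sampling_rate_hz <= 0:
            raise ValueError("SimConfig: sampling_rate_hz must be positive")
        present = {(j, p) for j, p, _ in self.joints}
        for e in self.effect_specs:
            if (e.joint, e.plane) not in present:
                raise ValueError(
                    f"SimConfig: effect targets ({e.joint}, {e.plane}) which is "
                    "not among the configured joints"
                )
        for j, p, _ in self.joints:
            if (j, p) not in self.templates:
                raise ValueError(f"SimConfig: no template for ({j}, {p})")

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class ParticipantRecord:
    id: str
    index: int
    group: str                 # "case" | "control"
    sex: str                   # "M" | "F"
    age: float                 # years
    mass: float                # kg
    height: float              # m
    inph_scale: float | None = None   # 0-100
    mrs: int | None = None            # 0-6
    ace: float | None = None          # 0-100
    evans_index: float | None = None
    radscale: float | None = None

    def __post_init__(self):
        if self.age <= 0 or self.mass <= 0 or self.height <= 0:
            raise ValueError("ParticipantRecord: age/mass/height must be positive")


@dataclass(frozen=True)
class GaitTrial:
    """A raw overground walking trial (heel markers + vertical GRF)."""

    fs: float                       # Hz
    time: np.ndarray                # s, uniform
    heel_ap: dict                   # side -> anterior-posterior position (m)
    heel_ml: dict                   # side -> medio-lateral position (m)
    heel_vert: dict                 # side -> vertical position (m)
    grf_vert: dict                  # side -> vertical GRF (N), >= 0
    body_weight: float              # N

    def __post_init__(self):
        n = self.time.size
        for d in (self.heel_ap, self.heel_ml, self.heel_vert, self.grf_vert):
            for side, arr in d.items():
                if arr.size != n:
                    raise ValueError(f"GaitTrial: {side} series length mismatch")
        if any(np.any(v < 0) for v in self.grf_vert.values()):
            raise ValueError("GaitTrial: GRF must be nonnegative")


def _rng(config: SimConfig, index: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence((config.seed, index, stream))
    )


def _truncated_normal(rng, mean, sd, low, high, size=None):
    for _ in range(1000):
        x = rng.normal(mean, sd, size=size)
        if np.all((x > low) & (x < high)):
            return x
    return np.clip(x, low + 1e-9, high - 1e-9)


def generate_participants(config: SimConfig) -> list[ParticipantRecord]:
    """Draw demographics (and, for cases, clinical scores) per participant.

    When the group's demographic spec carries exact ``sex_counts`` (the
    default, mirroring the study's 18:5 vs 4:14 split) sexes are a
    deterministic permutation of that composition; otherwise Bernoulli
    draws at ``p_male``.
    """
    participants: list[ParticipantRecord] = []
    index = 0
    for group, n in (("case", config.n_group_a), ("control", config.n_group_b)):
        spec = config.demographics[group]
        counts = spec.get("sex_counts")
        if counts is not None and sum(counts) == n:
            sexes = ["M"] * counts[0] + ["F"] * counts[1]
            _rng(config, 0 if group == "case" else 1, 9).shuffle(sexes)
        else:
            sexes = None
        for k in range(n):
            rng = _rng(config, index, 0)
            sex = sexes[k] if sexes is not None else (
                "M" if rng.random() < spec["p_male"] else "F"
            )
            age = float(_truncated_normal(rng, *spec["age"], 40, 105))
            mass = float(_truncated_normal(rng, *spec["mass"], 35, 160))
            height = float(_truncated_normal(rng, *spec["height"], 1.3, 2.1))
            clinical = {}
            if group == "case":
                clinical = {
                    "inph_scale": float(np.clip(rng.normal(51, 16.5), 0, 100)),
                    "mrs": int(np.clip(round(rng.normal(2.39, 0.9)), 0, 6)),
                    "ace": float(np.clip(rng.normal(78, 10.5), 0, 100)),
                    "evans_index": float(np.clip(rng.normal(0.38, 0.04), 0.2, 0.6)),
                    "radscale": float(np.clip(rng.normal(9.26, 1.63), 0, 12)),
                }
            participants.append(
                ParticipantRecord(
                    id=f"P{index + 1:03d}", index=index, group=group,
                    sex=sex, age=age, mass=mass, height=height, **clinical,
                )
            )
            index += 1
    return participants


def _gait_params(participant: ParticipantRecord, config: SimConfig) -> dict:
    """Per-participant spatiotemporal parameters (dedicated substream)."""
    rng = _rng(config, participant.index, 2)
    spec = config.spatiotemporal[participant.group]
    cycle = float(_truncated_normal(rng, *spec["cycle_time_s"][:2], 0.4, 4.0))
    length = float(_truncated_normal(rng, *spec["stride_length_m"][:2], 0.05, 2.5))
    width = float(_truncated_normal(rng, *spec["stride_width_m"][:2], 0.02, 0.6))
    return {
        "cycle_time_s": cycle,
        "stride_length_m": length,
        "stride_width_m": width,
        "gait_speed_ms": length / cycle,
        "cadence_spm": 120.0 / cycle,
    }


def generate_spatiotemporal(participants, config: SimConfig) -> pd.DataFrame:
    """Per-participant spatiotemporal table (one row per participant)."""
    rows = []
    for p in participants:
        rows.append({"id": p.id, "group": p.group, **_gait_params(p, config)})
    return pd.DataFrame(rows)


def smooth_gaussian_field(
    rng: np.random.Generator, node_count: int, fwhm: float, sd: float,
    size: int = 1,
) -> np.ndarray:
    """Stationary smooth Gaussian field: white noise convolved with a
    Gaussian kernel of the given FWHM (nodes), rescaled to pointwise SD.

    The white noise is padded well beyond the kernel support and the
    interior cropped, so the field is stationary with no edge effects.
    Returns shape (size, node_count).
    """
    if sd == 0:
        return np.zeros((size, node_count))
    sigma = fwhm * _FWHM_TO_SIGMA
    pad = int(np.ceil(4 * sigma)) + 1
    white = rng.standard_normal((size, node_count + 2 * pad))
    smooth = gaussian_filter1d(white, sigma, axis=1, mode="constant", truncate=6.0)
    # pointwise SD of the convolved field = ||kernel||_2 for unit white noise
    impulse = np.zeros(8 * pad + 1)
    impulse[4 * pad] = 1.0
    kernel = gaussian_filter1d(impulse, sigma, mode="constant", truncate=6.0)
    norm = math.sqrt(float(np.sum(kernel**2)))
    out = smooth[:, pad : pad + node_count] * (sd / norm)
    return out


def _template_curve(config: SimConfig, joint: str, plane: str) -> np.ndarray:
    a0, harmonics = config.templates[(joint, plane)]
    x = np.linspace(0.0, 1.0, config.node_count)
    y = np.full(config.node_count, float(a0))
    for k, (a, b) in enumerate(harmonics, start=1):
        y += a * np.cos(2 * np.pi * k * x) + b * np.sin(2 * np.pi * k * x)
    return y


def generate_waveforms(participants, config: SimConfig) -> dict:
    """Per-participant joint-angle waveforms.

    Returns ``{participant id: AngleWaveformSet}`` where each curve
    (joint, plane, side, stride) = template + group effect (cases only)
    + smooth subject deviation (per joint-plane-side) + independent
    smooth stride noise.
    """
    from .preprocessing import AngleWaveformSet

    q = config.node_count
    effects_by_jp: dict[tuple[str, str], list[EffectSpec]] = {}
    for e in config.effect_specs:
        effects_by_jp.setdefault((e.joint, e.plane), []).append(e)

    out = {}
    for p in participants:
        rng = _rng(config, p.index, 1)
        curves = {}
        for joint, plane, side in config.joints:
            base = _template_curve(config, joint, plane).copy()
            if p.group == "case":
                for e in effects_by_jp.get((joint, plane), []):
                    if e.side in ("both", side):
                        base = base + e.profile(q)
            subj = smooth_gaussian_field(
                rng, q, config.subject_noise_fwhm, config.subject_noise_sd
            )[0]
            strides = smooth_gaussian_field(
                rng, q, config.subject_noise_fwhm, config.stride_noise_sd,
                size=config.strides_per_subject,
            )
            for s in range(config.strides_per_subject):
                curves[(joint, plane, side, s)] = base + subj + strides[s]
        out[p.id] = AngleWaveformSet(participant_id=p.id, curves=curves,
                                     node_count=q)
    return out


def generate_trial_signals(participant: ParticipantRecord, config: SimConfig):
    """Synthesize one raw walking trial with ground-truth events.

    Vertical GRF per foot is zero in swing and a smooth double-bump
    (1.2 sin(pi tau) + 0.3 sin(3 pi tau), tau = stance phase) during
    stance; the heel's anterior-posterior position is stationary in
    stance and advances one stride length per cycle via a smoothstep in
    swing; medio-lateral positions sit at +/- half the stride width.

    Returns ``(GaitTrial, truth)`` where truth maps each side to its
    ground-truth heel-strike and toe-off times (seconds).
    """
    if config.strides_per_subject < 2:
        raise ValueError("generate_trial_signals: strides_per_subject must be >= 2")
    if config.sampling_rate_hz <= 0:
        raise ValueError("generate_trial_signals: non-positive sampling rate")
    params = _gait_params(participant, config)
    T = params["cycle_time_s"]
    L = params["stride_length_m"]
    W = params["stride_width_m"]
    fs = config.sampling_rate_hz
    stance = config.stance_fraction * T
    n_strides = config.strides_per_subject
    lead = 0.5
    bw = participant.mass * 9.81

    duration = lead + (n_strides + 1.0) * T + lead
    t = np.arange(0.0, duration, 1.0 / fs)

    heel_ap, heel_ml, heel_vert, grf, truth = {}, {}, {}, {}, {}
    for side, offset, ml in (("left", 0.0, -W / 2), ("right", 0.5 * T, W / 2)):
        hs_times = lead + offset + T * np.arange(n_strides + 1)
        to_times = hs_times + stance
        truth[side] = {
            "heel_strike_s": hs_times.tolist(),
            "toe_off_s": to_times.tolist(),
        }
        f = np.zeros_like(t)
        ap = np.zeros_like(t)
        vert = np.full_like(t, 0.03)
        # before the first heel strike the foot is held at its start position
        ap[:] = 0.0
        for k in range(n_strides + 1):
            hs = hs_times[k]
            pos = k * L
            in_stance = (t >= hs) & (t < hs + stance)
            tau = (t[in_stance] - hs) / stance
            f[in_stance] = bw * (1.2 * np.sin(np.pi * tau)
                                 + 0.3 * np.sin(3 * np.pi * tau))
            ap[in_stance] = pos
            if k < n_strides:
                nxt = hs_times[k + 1]
                in_swing = (t >= hs + stance) & (t < nxt)
                s = (t[in_swing] - hs - stance) / (nxt - hs - stance)
                ap[in_swing] = pos + L * (3 * s**2 - 2 * s**3)
                vert[in_swing] = 0.03 + 0.05 * np.sin(np.pi * s)
            else:
                ap[t >= hs + stance] = pos
        ap[t < hs_times[0]] = 0.0
        np.clip(f, 0.0, None, out=f)
        heel_ap[side] = ap
        heel_ml[side] = np.full_like(t, ml)
        heel_vert[side] = vert
        grf[side] = f

    trial = GaitTrial(
        fs=fs, time=t, heel_ap=heel_ap, heel_ml=heel_ml,
        heel_vert=heel_vert, grf_vert=grf, body_weight=bw,
    )
    return trial, truth
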