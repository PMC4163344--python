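"""Synthetic CPR sessions with per-cycle ground truth.

Emulates the bench study design: 20 rescuers deliver 60 s of uninterrupted
compressions for every combination of target rate (80, 100, 120,
140 min^-1) and target depth (30, 50 mm), once with the sensor axis normal
to the chest ("regular") and once misaligned by 18 degrees ("tilt") --
320 records in total.

Each compression cycle is a raised-sine (sin^2) displacement pulse:
continuous first derivative at cycle boundaries, hence bounded
acceleration, and a duty cycle below 1 produces the multi-harmonic
structure that motivates using three harmonics.  Per-cycle period and
depth are jittered; acceleration is the exact second difference of the
displacement mapped into a (possibly tilted) sensor frame with gravity,
per-axis offset and white noise added.  Every random draw is seeded.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
import pandas as pd

from .signal_io import AccelerationRecord, DisplacementRecord, SessionMeta

__all__ = [
    "SimulationConfig",
    "BenchmarkRecord",
    "generate_displacement",
    "displacement_to_acceleration",
    "generate_session",
    "generate_benchmark",
]


@dataclass
class SimulationConfig:
    """Full parameterisation of one synthetic session.

    Parameters
    ----------
    target_rate : float
        Mean compression rate, min^-1.
    target_depth : float
        Mean peak compression depth, mm.
    duration : float
        Session length in seconds (60 s in the emulated design).
    fs : float
        Acquisition sampling rate, Hz (500 Hz, matching the emulated
        acquisition chain; analysis later resamples to 100 Hz).
    rate_jitter_cv, depth_jitter_cv : float
        Coefficient of variation of per-cycle period and depth draws.
    duty_cycle : float
        Fraction of each cycle occupied by the compression pulse; 1.0 is
        a continuous sinusoidal motion, lower values insert a hold at the
        released position and add harmonic content.
    leaning_mm : float
        Residual depth at release (incomplete recoil); 0 by default.
    tilt_deg : float
        Sensor misalignment from the chest normal.
    gravity : float
        Gravity magnitude added as a constant vector in the sensor frame.
    noise_std : float
        White Gaussian noise per acceleration axis, m/s^2.
    offset : (float, float, float)
        Constant per-axis accelerometer bias, m/s^2.
    seed : int
        Seeds every random draw; identical config + seed gives a
        bit-identical session.
    """

    target_rate: float = 100.0
    target_depth: float = 50.0
    duration: float = 60.0
    fs: float = 500.0
    rate_jitter_cv: float = 0.03
    depth_jitter_cv: float = 0.05
    duty_cycle: float = 1.0
    leaning_mm: float = 0.0
    tilt_deg: float = 0.0
    gravity: float = 9.81
    noise_std: float = 0.3
    offset: tuple[float, float, float] = (0.0, 0.0, 0.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.duty_cycle <= 1:
            raise ValueError("duty_cycle must be in (0, 1]")
        if self.rate_jitter_cv < 0 or self.depth_jitter_cv < 0:
            raise ValueError("jitter CVs must be non-negative")
        if not self.duration > 0:
            raise ValueError("duration must be positive")
        if not self.fs > 0:
            raise ValueError("fs must be positive")


@dataclass
class BenchmarkRecord:
    """One benchmark session: signals, ground truth and metadata."""

    meta: SessionMeta
    config: SimulationConfig
    accel: AccelerationRecord
    displacement: DisplacementRecord
    truth: pd.DataFrame  # columns: cycle_start_s, rate_min, depth_mm


def generate_displacement(cfg: SimulationConfig) -> tuple[DisplacementRecord, pd.DataFrame]:
    """Concatenate jittered sin^2 compression cycles.

    Cycle i has period T_i = (60 / target_rate) * (1 + eps_i) with
    eps_i ~ N(0, rate_jitter_cv), and depth jittered likewise.  Within a
    cycle of period T the displacement is

        leaning + (depth - leaning) * sin^2(pi t / (duty * T))   t < duty*T
        leaning                                                  otherwise

    Returns the displacement record and a per-cycle truth table with
    columns ``cycle_start_s``, ``rate_min`` (60 / T_i) and ``depth_mm``.
    Cycles are generated only while they fit entirely inside the session;
    any remaining tail stays at the released position.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    n = int(round(cfg.duration * cfg.fs))
    s = np.full(n, cfg.leaning_mm, dtype=float)
    rows = []
    t = 0.0
    mean_period = 60.0 / cfg.target_rate
    while True:
        period = mean_period * (1.0 + rng.normal(0.0, cfg.rate_jitter_cv))
        period = max(period, 0.2 * mean_period)
        depth = cfg.target_depth * (1.0 + rng.normal(0.0, cfg.depth_jitter_cv))
        depth = max(depth, cfg.leaning_mm)
        if t + period > cfg.duration + 1e-12:
            break
        i0 = int(np.ceil(t * cfg.fs - 1e-9))
        i1 = int(np.ceil((t + cfg.duty_cycle * period) * cfg.fs - 1e-9))
        i1 = min(i1, n)
        tt = i0 / cfg.fs + np.arange(i1 - i0) / cfg.fs - t
        s[i0:i1] = cfg.leaning_mm + (depth - cfg.leaning_mm) * np.sin(
            np.pi * tt / (cfg.duty_cycle * period)
        ) ** 2
        rows.append((t, 60.0 / period, depth))
        t += period
    truth = pd.DataFrame(rows, columns=["cycle_start_s", "rate_min", "depth_mm"])
    return DisplacementRecord(s, fs=cfg.fs), truth


def _compression_direction(tilt_deg: float) -> np.ndarray:
    """Unit vector of the chest normal in the sensor frame (tilt about y)."""
    tau = np.deg2rad(tilt_deg)
    return np.array([np.sin(tau), 0.0, np.cos(tau)])


def displacement_to_acceleration(
    disp: DisplacementRecord, cfg: SimulationConfig
) -> AccelerationRecord:
    """Exact discrete second derivative of displacement, in the sensor frame.

    The compression-direction acceleration is the second central
    difference of the displacement (mm -> m) scaled by fs^2, with edge
    samples mirrored.  It is mapped onto the (tilted) chest-normal
    direction; the gravity vector (rotated into the same frame), the
    per-axis offset and white Gaussian noise are then added.
    """
    if len(disp) < 3:
        raise ValueError("need at least 3 samples to differentiate twice")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    s_m = disp.samples / 1000.0
    a = np.empty_like(s_m)
    a[1:-1] = (s_m[2:] - 2 * s_m[1:-1] + s_m[:-2]) * disp.fs**2
    a[0] = a[1]
    a[-1] = a[-2]
    u = _compression_direction(cfg.tilt_deg)
    samples = np.outer(a, u)
    samples += cfg.gravity * u  # gravity along the chest normal, rotated likewise
    samples += np.asarray(cfg.offset, dtype=float)
    if cfg.noise_std > 0:
        samples = samples + rng.normal(0.0, cfg.noise_std, size=samples.shape)
    return AccelerationRecord(samples, fs=disp.fs, t0=disp.t0)


def generate_session(cfg: SimulationConfig) -> tuple[AccelerationRecord, DisplacementRecord, pd.DataFrame]:
    """Displacement, matching acceleration and truth table for one config."""
    disp, truth = generate_displacement(cfg)
    accel = displacement_to_acceleration(disp, cfg)
    return accel, disp, truth


# Per-rescuer skill model for the benchmark.  Jitter CVs and small
# systematic rate/depth biases vary across rescuers so that record-level
# spreads resemble guided-but-human performance; duty cycle varies so
# waveforms range from near-sinusoidal to mildly pulse-like.
_RATE_JITTER_MEAN, _RATE_JITTER_SD = 0.03, 0.008
_DEPTH_JITTER_MEAN, _DEPTH_JITTER_SD = 0.05, 0.012
_RATE_BIAS_SD = 0.015
_DEPTH_BIAS_SD = 0.05
_DUTY_RANGE = (0.8, 1.0)


def _rescuer_skill(rng: np.random.Generator) -> dict:
    return {
        "rate_jitter_cv": float(np.clip(rng.normal(_RATE_JITTER_MEAN, _RATE_JITTER_SD), 0.01, 0.06)),
        "depth_jitter_cv": float(np.clip(rng.normal(_DEPTH_JITTER_MEAN, _DEPTH_JITTER_SD), 0.02, 0.09)),
        "rate_bias": float(rng.normal(1.0, _RATE_BIAS_SD)),
        "depth_bias": float(rng.normal(1.0, _DEPTH_BIAS_SD)),
        "duty_cycle": float(rng.uniform(*_DUTY_RANGE)),
    }


def generate_benchmark(
    n_rescuers: int = 20,
    rates: Sequence[float] = (80.0, 100.0, 120.0, 140.0),
    depths: Sequence[float] = (30.0, 50.0),
    sessions: Sequence[str] = ("regular", "tilt"),
    duration: float = 60.0,
    fs: float = 500.0,
    tilt_deg: float = 18.0,
    seed: int = 0,
) -> list[BenchmarkRecord]:
    """Full benchmark: n_rescuers x (rates x depths) x session kinds.

    Per-rescuer skill parameters are drawn from seeded distributions so
    rescuers differ reproducibly; every record gets an independent
    sub-seed derived from ``seed``.  Defaults give the 320-record design
    (20 x 8 x 2).
    """
    if not rates or not depths:
        raise ValueError("rate/depth grid must be non-empty")
    records: list[BenchmarkRecord] = []
    for r in range(n_rescuers):
        skill_rng = np.random.default_rng(np.random.SeedSequence([int(seed), 1000 + r]))
        skill = _rescuer_skill(skill_rng)
        cond = 0
        for rate in rates:
            for depth in depths:
                for s_i, kind in enumerate(sessions):
                    tilt = tilt_deg if kind == "tilt" else 0.0
                    sub = np.random.SeedSequence([int(seed), r, cond, s_i])
                    record_seed = int(sub.generate_state(1)[0] % 2**31)
                    cfg = SimulationConfig(
                        target_rate=rate * skill["rate_bias"],
                        target_depth=depth * skill["depth_bias"],
                        duration=duration,
                        fs=fs,
                        rate_jitter_cv=skill["rate_jitter_cv"],
                        depth_jitter_cv=skill["depth_jitter_cv"],
                        duty_cycle=skill["duty_cycle"],
                        tilt_deg=tilt,
                        seed=record_seed,
                    )
                    accel, disp, truth = generate_session(cfg)
                    meta = SessionMeta(
                        rescuer_id=f"r{r:02d}",
                        target_rate=rate,
                        target_depth=depth,
                        session_kind=kind,
                        tilt_deg=tilt,
                    )
                    records.append(
                        BenchmarkRecord(
                            meta=meta, config=cfg, accel=accel, displacement=disp, truth=truth
                        )
                    )
                cond += 1
    return records
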