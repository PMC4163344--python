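"""Spectral estimation of compression rate and depth from acceleration.

The core method.  Within a short analysis window the compression signals
are quasi-periodic, so acceleration and displacement are modelled by the
first N harmonics of their Fourier series (no DC term):

    a(t) = sum_k A_k cos(2 pi k f_cc t + theta_k)      [m/s^2]
    s(t) = sum_k S_k cos(2 pi k f_cc t + phi_k)        [mm]

Because a(t) is the second derivative of s(t), the harmonics are related in
closed form:

    S_k = 1000 * A_k / (2 pi k f_cc)^2,   phi_k = theta_k + pi

so displacement never has to be obtained by double integration -- the step
that introduces drift in conventional accelerometer feedback devices.

Pipeline per window: Hamming taper -> zero-padded 2048-point FFT ->
fundamental-frequency pick in the compression band (with a subharmonic
guard) -> harmonic amplitude/phase read-off -> closed-form conversion ->
one reconstructed displacement cycle.  Then

    rate [min^-1] = 60 * f_cc,   depth [mm] = max s(t) - min s(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
from scipy import fft as sp_fft

from .errors import (
    NoCompressionActivityError,
    NoPeriodicityError,
    WindowAnalysisError,
)
from .signal_io import AccelerationRecord

__all__ = [
    "AnalysisWindow",
    "HarmonicSet",
    "FeedbackEstimate",
    "SpectralConfig",
    "Spectrum",
    "WindowGap",
    "project_axes",
    "window_and_spectrum",
    "estimate_fundamental",
    "estimate_harmonics",
    "reconstruct_cycle",
    "feedback_from_window",
    "analyze_session",
]


@dataclass
class AnalysisWindow:
    """Scalar acceleration segment over which one feedback value is produced."""

    start: float
    duration: float
    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).reshape(-1)
        if not self.duration > 0:
            raise ValueError("window duration must be positive")
        if len(self.samples) < 8:
            raise ValueError(f"window too short ({len(self.samples)} samples, need >= 8)")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("window samples must be finite")


@dataclass
class HarmonicSet:
    """Fundamental frequency plus harmonic amplitudes/phases.

    ``A`` (m/s^2) and ``theta`` (rad) describe the acceleration harmonics;
    ``S`` (mm) and ``phi`` (rad) the displacement harmonics derived from
    them via S_k = 1000 A_k / (2 pi k f_cc)^2 and phi_k = theta_k + pi.
    """

    fcc: float
    A: np.ndarray
    theta: np.ndarray
    S: np.ndarray = field(default=None)  # type: ignore[assignment]
    phi: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if not self.fcc > 0:
            raise ValueError("fundamental frequency must be positive")
        self.A = np.asarray(self.A, dtype=float)
        self.theta = np.asarray(self.theta, dtype=float)
        if np.any(self.A < 0):
            raise ValueError("harmonic amplitudes must be non-negative")
        k = np.arange(1, len(self.A) + 1)
        if self.S is None:
            self.S = 1000.0 * self.A / (2 * np.pi * k * self.fcc) ** 2
        if self.phi is None:
            self.phi = np.mod(self.theta + np.pi, 2 * np.pi)
        self.S = np.asarray(self.S, dtype=float)
        self.phi = np.asarray(self.phi, dtype=float)

    @property
    def n_harmonics(self) -> int:
        return len(self.A)


@dataclass
class FeedbackEstimate:
    """One (rate, depth) feedback value for one analysis window."""

    rate: float
    depth: float
    window_start: float
    duration: float
    source: str = "spectral"

    def __post_init__(self) -> None:
        if not self.rate > 0:
            raise ValueError("rate must be positive")
        if self.depth < 0:
            raise ValueError("depth must be non-negative")
        if self.source not in ("spectral", "reference", "baseline"):
            raise ValueError(f"unknown source {self.source!r}")


@dataclass
class WindowGap:
    """Marker for a window that produced no estimate (pause, dropout)."""

    window_start: float
    duration: float
    reason: str


@dataclass
class SpectralConfig:
    """Tunables of the spectral estimator.

    Parameters
    ----------
    n_fft : int
        Zero-padded FFT length (2048 by default: ~0.049 Hz bin spacing at
        100 Hz, i.e. ~2.9 min^-1 rate resolution).
    n_harmonics : int
        Harmonics used to reconstruct displacement (3 by default).
    band : (float, float)
        Fundamental search band in Hz; 0.6-3.5 Hz covers 36-210 min^-1.
    harmonic_halfwidth_hz : float or None
        Search half-width around k*f_cc for harmonic peaks; None means
        max(1.5 bins, 0.1 * f_cc), tolerant of jitter-broadened peaks.
    subharmonic_ratio : float
        A spectral peak near half the candidate fundamental wins if its
        magnitude is at least this fraction of the candidate's, which
        prevents locking onto the 2nd harmonic of pulse-like waveforms.
    noise_band : (float, float)
        Frequency strip used to estimate the noise floor.  11-14 Hz by
        default: inside the 15 Hz anti-noise passband but above the third
        harmonic of any fundamental in the search band, so it contains no
        compression energy.  (The in-band median is no use as a floor --
        during compressions it is dominated by spectral leakage.)
    noise_floor_factor : float
        The fundamental peak must exceed this multiple of the median
        noise-band magnitude, else "no periodicity detected".
    harmonic_min_fraction : float
        Harmonic read-offs below this fraction of the fundamental's
        magnitude are zeroed; guards against picking up window sidelobes
        of the fundamental (Hamming sidelobes near 2 f_cc sit near or
        below 1% of the peak, genuine harmonics of compression waveforms
        are several percent).
    refine_peak : bool
        Three-point parabolic interpolation of the fundamental.  Off by
        default: plain FFT-bin resolution.
    """

    n_fft: int = 2048
    n_harmonics: int = 3
    band: tuple[float, float] = (0.6, 3.5)
    harmonic_halfwidth_hz: float | None = None
    subharmonic_ratio: float = 0.3
    noise_band: tuple[float, float] = (11.0, 14.0)
    noise_floor_factor: float = 5.0
    harmonic_min_fraction: float = 0.02
    refine_peak: bool = False

    def __post_init__(self) -> None:
        if self.n_fft < 8:
            raise ValueError("n_fft too small")
        if not 0 < self.band[0] < self.band[1]:
            raise ValueError("band must satisfy 0 < f_min < f_max")
        if not 0 < self.subharmonic_ratio < 1:
            raise ValueError("subharmonic_ratio must be in (0, 1)")
        if self.n_harmonics < 1:
            raise ValueError("need at least one harmonic")


@dataclass
class Spectrum:
    """Zero-padded spectrum of a mean-removed, Hamming-tapered window."""

    X: np.ndarray
    freqs: np.ndarray
    fs: float
    coherent_sum: float  # sum of the taper; divides peak magnitudes into amplitudes
    n_samples: int

    @property
    def df(self) -> float:
        return self.freqs[1] - self.freqs[0]

    def magnitude(self) -> np.ndarray:
        return np.abs(self.X)


def project_axes(
    accel: AccelerationRecord,
    start: float,
    duration: float,
    mode: Union[str, int] = "principal",
) -> AnalysisWindow:
    """Collapse a triaxial window to the scalar compression-axis signal.

    Modes
    -----
    ``"principal"``
        Remove the per-channel mean and project onto the direction of
        maximal variance within the window.  Rotation-invariant, so a
        tilted sensor needs no special handling.  The sign is fixed so the
        first local extremum of the projection is positive.
    ``0 | 1 | 2``
        A fixed sensor axis (mean kept; removed later in the spectrum step).
    ``"magnitude"``
        Euclidean norm of the acceleration vector.

    Raises
    ------
    ValueError
        Window not fully inside the record.
    NoCompressionActivityError
        Zero-variance window under principal mode.
    """
    i0 = int(np.floor(start * accel.fs))
    n = int(round(duration * accel.fs))
    if i0 < 0 or i0 + n > len(accel):
        raise ValueError(
            f"window [{start}, {start + duration}) s exceeds record bounds "
            f"(0, {accel.duration}) s"
        )
    seg = accel.samples[i0 : i0 + n]
    if isinstance(mode, (int, np.integer)):
        scalar = seg[:, int(mode)].copy()
    elif mode == "magnitude":
        scalar = np.linalg.norm(seg, axis=1)
    elif mode == "principal":
        centered = seg - seg.mean(axis=0)
        cov = centered.T @ centered
        if not np.any(cov.diagonal() > 0):
            raise NoCompressionActivityError(
                f"no compression activity in window at {start} s (zero variance)"
            )
        eigvals, eigvecs = np.linalg.eigh(cov)
        direction = eigvecs[:, -1]
        scalar = centered @ direction
        scalar = _fix_sign(scalar)
    else:
        raise ValueError(f"unknown projection mode {mode!r}")
    return AnalysisWindow(start=start, duration=duration, samples=scalar, fs=accel.fs)


def _fix_sign(x: np.ndarray) -> np.ndarray:
    """Deterministic sign: first local extremum positive."""
    d = np.diff(x)
    turns = np.nonzero(d[:-1] * d[1:] < 0)[0]
    pivot = x[turns[0] + 1] if len(turns) else x[np.argmax(np.abs(x))]
    return -x if pivot < 0 else x


def window_and_spectrum(win: AnalysisWindow, cfg: SpectralConfig | None = None) -> Spectrum:
    """Mean removal, Hamming taper, zero-padded FFT.

    The taper sum (coherent gain times window length) is recorded so that
    peak magnitudes can be corrected back to true sinusoid amplitudes:
    A = 2 |X_peak| / sum(taper).
    """
    cfg = cfg or SpectralConfig()
    n = len(win.samples)
    if n > cfg.n_fft:
        raise ValueError(
            f"window of {n} samples exceeds n_fft={cfg.n_fft}; increase n_fft"
        )
    taper = np.hamming(n)
    x = (win.samples - win.samples.mean()) * taper
    X = sp_fft.rfft(x, n=cfg.n_fft)
    freqs = sp_fft.rfftfreq(cfg.n_fft, d=1.0 / win.fs)
    return Spectrum(X=X, freqs=freqs, fs=win.fs, coherent_sum=float(taper.sum()), n_samples=n)


def _parabolic_refine(mag: np.ndarray, i: int, df: float, freqs: np.ndarray) -> float:
    if i <= 0 or i >= len(mag) - 1:
        return freqs[i]
    y0, y1, y2 = mag[i - 1], mag[i], mag[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return freqs[i]
    delta = 0.5 * (y0 - y2) / denom
    return freqs[i] + np.clip(delta, -0.5, 0.5) * df


def _local_peak_in(mag: np.ndarray, lo: int, hi: int) -> int | None:
    """Index of the largest bin in [lo, hi] that is a local maximum."""
    lo = max(lo, 1)
    hi = min(hi, len(mag) - 2)
    if hi < lo:
        return None
    idx = np.arange(lo, hi + 1)
    is_peak = (mag[idx] >= mag[idx - 1]) & (mag[idx] >= mag[idx + 1])
    if not np.any(is_peak):
        return None
    candidates = idx[is_peak]
    return int(candidates[np.argmax(mag[candidates])])


def _noise_floor(spectrum: Spectrum, cfg: SpectralConfig) -> float:
    """Median magnitude in the harmonic-free noise strip."""
    lo = min(cfg.noise_band[0], 0.7 * spectrum.fs / 2)
    hi = min(cfg.noise_band[1], 0.9 * spectrum.fs / 2)
    sel = (spectrum.freqs >= lo) & (spectrum.freqs <= hi)
    if not np.any(sel):
        return 0.0
    return float(np.median(np.abs(spectrum.X[sel])))


def estimate_fundamental(spectrum: Spectrum, cfg: SpectralConfig | None = None) -> float:
    """Pick the mean compression frequency f_cc from the spectrum.

    The largest in-band bin is the candidate; if a local peak near half its
    frequency reaches ``subharmonic_ratio`` of its magnitude, the lower
    peak wins (the candidate was a 2nd harmonic).  Optionally refined by
    parabolic interpolation.

    Raises
    ------
    NoPeriodicityError
        If the winning peak does not exceed ``noise_floor_factor`` times
        the median magnitude of the harmonic-free noise strip.
    """
    cfg = cfg or SpectralConfig()
    mag = spectrum.magnitude()
    band = (spectrum.freqs >= cfg.band[0]) & (spectrum.freqs <= cfg.band[1])
    if not np.any(band):
        raise NoPeriodicityError("search band contains no FFT bins")
    band_idx = np.nonzero(band)[0]
    floor = _noise_floor(spectrum, cfg)
    peak_i = band_idx[np.argmax(mag[band_idx])]
    if mag[peak_i] <= cfg.noise_floor_factor * floor or mag[peak_i] == 0:
        raise NoPeriodicityError(
            "no periodicity detected: in-band peak below the noise floor"
        )
    # Subharmonic guard: strong pulse-like waveforms can put more energy at
    # 2 f_cc than at f_cc; check for a credible peak at half the frequency.
    f_peak = spectrum.freqs[peak_i]
    half = f_peak / 2.0
    if half >= cfg.band[0]:
        halfwidth = max(1.5 * spectrum.df, 0.1 * half)
        lo = int(np.floor((half - halfwidth) / spectrum.df))
        hi = int(np.ceil((half + halfwidth) / spectrum.df))
        sub_i = _local_peak_in(mag, lo, hi)
        if sub_i is not None and mag[sub_i] >= cfg.subharmonic_ratio * mag[peak_i]:
            peak_i = sub_i
    if cfg.refine_peak:
        return float(_parabolic_refine(mag, peak_i, spectrum.df, spectrum.freqs))
    return float(spectrum.freqs[peak_i])


def estimate_harmonics(
    spectrum: Spectrum, fcc: float, cfg: SpectralConfig | None = None
) -> HarmonicSet:
    """Read amplitudes and phases of the first N harmonics off the spectrum.

    For each k the local magnitude maximum within the search half-width of
    k*f_cc is used (jitter broadens and shifts harmonic peaks slightly).
    Amplitudes are corrected for the Hamming coherent gain.  Harmonics at
    or above Nyquist, or below the noise floor, are zeroed.
    """
    cfg = cfg or SpectralConfig()
    mag = spectrum.magnitude()
    floor = _noise_floor(spectrum, cfg)
    A = np.zeros(cfg.n_harmonics)
    theta = np.zeros(cfg.n_harmonics)
    halfwidth = cfg.harmonic_halfwidth_hz
    if halfwidth is None:
        halfwidth = max(1.5 * spectrum.df, 0.1 * fcc)
    fundamental_mag = None
    for k in range(1, cfg.n_harmonics + 1):
        f_k = k * fcc
        if f_k >= spectrum.fs / 2 - spectrum.df:
            continue
        lo = int(np.floor((f_k - halfwidth) / spectrum.df))
        hi = int(np.ceil((f_k + halfwidth) / spectrum.df))
        i = _local_peak_in(mag, lo, hi)
        if i is None:
            i = int(np.clip(round(f_k / spectrum.df), 0, len(mag) - 1))
        if k == 1:
            fundamental_mag = mag[i]
        elif mag[i] <= cfg.noise_floor_factor * floor or (
            fundamental_mag is not None
            and mag[i] < cfg.harmonic_min_fraction * fundamental_mag
        ):
            continue
        A[k - 1] = 2.0 * mag[i] / spectrum.coherent_sum
        theta[k - 1] = float(np.angle(spectrum.X[i]))
    return HarmonicSet(fcc=fcc, A=A, theta=theta)


def reconstruct_cycle(h: HarmonicSet, samples_per_cycle: int = 256) -> np.ndarray:
    """Evaluate one full period of s(t) [mm] on a uniform grid."""
    t = np.arange(samples_per_cycle) / (samples_per_cycle * h.fcc)
    k = np.arange(1, h.n_harmonics + 1)
    return (h.S[None, :] * np.cos(2 * np.pi * np.outer(t, k * h.fcc) + h.phi[None, :])).sum(
        axis=1
    )


def feedback_from_window(
    win: AnalysisWindow,
    cfg: SpectralConfig | None = None,
    samples_per_cycle: int = 256,
) -> FeedbackEstimate:
    """Full per-window chain: spectrum -> f_cc -> harmonics -> cycle -> (rate, depth)."""
    cfg = cfg or SpectralConfig()
    spectrum = window_and_spectrum(win, cfg)
    fcc = estimate_fundamental(spectrum, cfg)
    harmonics = estimate_harmonics(spectrum, fcc, cfg)
    cycle = reconstruct_cycle(harmonics, samples_per_cycle)
    return FeedbackEstimate(
        rate=60.0 * fcc,
        depth=float(cycle.max() - cycle.min()),
        window_start=win.start,
        duration=win.duration,
        source="spectral",
    )


def analyze_session(
    accel: AccelerationRecord,
    tw: float,
    cfg: SpectralConfig | None = None,
    mode: Union[str, int] = "principal",
) -> list[FeedbackEstimate | WindowGap]:
    """Nonoverlapping consecutive windows over a whole record.

    Returns floor(duration / tw) entries at starts 0, tw, 2*tw, ...;
    windows that cannot produce an estimate yield :class:`WindowGap`
    markers rather than fabricated values.
    """
    cfg = cfg or SpectralConfig()
    if accel.duration < tw:
        raise ValueError(f"record of {accel.duration} s shorter than tw={tw} s")
    n_windows = int(np.floor(accel.duration / tw + 1e-9))
    out: list[FeedbackEstimate | WindowGap] = []
    for i in range(n_windows):
        start = i * tw
        try:
            win = project_axes(accel, start, tw, mode=mode)
            out.append(feedback_from_window(win, cfg))
        except WindowAnalysisError as exc:
            out.append(WindowGap(window_start=start, duration=tw, reason=str(exc)))
    return out
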