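"""Synthetic in-cabin FMCW radar scenes.

Generates raw baseband recordings of a seated person's thorax as observed by
a single-channel chirped 60 GHz radar, together with the ground-truth heart
rate trace.  The chest displacement is modelled as a superposition of

* a cardiac pulse train (0.2--0.6 mm peak displacement),
* a respiratory oscillation (4--12 mm at 0.1--0.5 Hz), and
* band-limited vehicle vibration (0.5--5 Hz),

riding on a nominal sensor-to-chest distance of ~0.5 m.  Each radar frame is
one real-valued sampled chirp whose beat frequency encodes the range and
whose phase encodes the sub-wavelength micro-motion, phi = 4*pi*R/lambda.

All randomness is driven by a single integer seed: the same configuration
always produces a bit-identical recording.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Callable, Sequence

import h5py
import numpy as np
import pandas as pd
from scipy import signal
from scipy.integrate import cumulative_trapezoid

C_LIGHT = 299792458.0  # m/s

HR_MIN_BPM = 30.0
HR_MAX_BPM = 220.0
CARDIAC_AMP_MAX = 1e-3   # m, physiological upper bound with margin
RESP_AMP_MAX = 2e-2      # m


@dataclass(frozen=True)
class RadarConfig:
    """Chirp and frame timing of the radar front end.

    Defaults follow a commercial 60 GHz sensor operated with a single chirp
    per frame: 58--63.5 GHz sweep, 3 MHz ADC rate, 128 samples per chirp,
    50 ms frame repetition (20 Hz slow-time rate).
    """

    f_start: float = 58e9
    f_end: float = 63.5e9
    fs_fast: float = 3e6
    n_samples: int = 128
    frame_rep: float = 0.05
    n_chirps_per_frame: int = 1
    duration: float = 90.0

    def __post_init__(self) -> None:
        if self.f_end <= self.f_start:
            raise ValueError("f_end must exceed f_start (positive sweep bandwidth)")
        if self.n_samples < 2 or self.fs_fast <= 0:
            raise ValueError("need at least 2 ADC samples at a positive rate")
        if self.frame_rep <= 0 or self.duration <= 0:
            raise ValueError("frame_rep and duration must be positive")
        # slow-time rate must support the 0.5-3 Hz heart band
        if 1.0 / self.frame_rep <= 2 * 3.0:
            raise ValueError("slow-time rate must exceed 6 Hz (Nyquist for the HR band)")
        if self.chirp_time > self.frame_rep:
            raise ValueError("chirp duration n_samples/fs_fast must fit within frame_rep")

    @property
    def bandwidth(self) -> float:
        return self.f_end - self.f_start

    @property
    def f_center(self) -> float:
        return 0.5 * (self.f_start + self.f_end)

    @property
    def wavelength(self) -> float:
        return C_LIGHT / self.f_center

    @property
    def chirp_time(self) -> float:
        """Sampled sweep duration T_c (s); the slope is bandwidth/T_c."""
        return self.n_samples / self.fs_fast

    @property
    def fs_slow(self) -> float:
        return 1.0 / self.frame_rep

    @property
    def n_frames(self) -> int:
        return int(round(self.duration / self.frame_rep))

    @property
    def range_bin_spacing(self) -> float:
        """Range covered by one fast-time FFT bin, c/(2B)."""
        return C_LIGHT / (2.0 * self.bandwidth)

    @property
    def max_range(self) -> float:
        """Largest unambiguous range (beat frequency below fast-time Nyquist)."""
        return C_LIGHT * self.n_samples / (4.0 * self.bandwidth)

    def t_slow(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_rep


def _as_hr_function(hr: float | Sequence | Callable) -> Callable[[np.ndarray], np.ndarray]:
    """Coerce a heart-rate specification into a callable time -> bpm.

    Accepts a scalar (constant HR), a pair of arrays (control-point times and
    bpm values, interpolated piecewise-linearly), or an arbitrary callable.
    """
    if callable(hr):
        return hr
    if np.isscalar(hr):
        value = float(hr)
        return lambda t: np.full_like(np.asarray(t, dtype=float), value)
    t_pts, hr_pts = (np.asarray(a, dtype=float) for a in hr)
    if t_pts.shape != hr_pts.shape or t_pts.ndim != 1:
        raise ValueError("hr control points must be two equal-length 1-D arrays")
    return lambda t: np.interp(np.asarray(t, dtype=float), t_pts, hr_pts)


@dataclass(frozen=True)
class SceneConfig:
    """Physical scene in front of the radar.

    ``hr`` may be a constant bpm value, ``(times, bpm_values)`` control
    points, or a callable; ``cardiac_shape`` selects a sinusoid or a
    raised-cosine pulse train (the pulse generates the harmonics seen in
    real cardiac spectra).
    """

    range0: float = 0.5
    hr: float | Sequence | Callable = 72.0
    cardiac_amp: float = 0.4e-3
    cardiac_shape: str = "pulse"
    resp_rate: float = 0.25
    resp_amp: float = 8e-3
    vib_band: tuple[float, float] = (0.5, 5.0)
    vib_rms: float = 0.0
    noise_snr: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.range0 <= 0:
            raise ValueError("range0 must be positive")
        if not 0 <= self.cardiac_amp <= CARDIAC_AMP_MAX:
            raise ValueError(f"cardiac_amp must lie in [0, {CARDIAC_AMP_MAX}] m")
        if not 0 <= self.resp_amp <= RESP_AMP_MAX:
            raise ValueError(f"resp_amp must lie in [0, {RESP_AMP_MAX}] m")
        if self.vib_rms < 0:
            raise ValueError("vib_rms must be non-negative")
        if self.cardiac_shape not in ("sinusoid", "pulse"):
            raise ValueError("cardiac_shape must be 'sinusoid' or 'pulse'")
        if not 0 < self.vib_band[0] < self.vib_band[1]:
            raise ValueError("vib_band must be an increasing positive pair")

    def hr_at(self, t: np.ndarray) -> np.ndarray:
        hr = np.asarray(_as_hr_function(self.hr)(t), dtype=float)
        if np.any(hr < HR_MIN_BPM) or np.any(hr > HR_MAX_BPM):
            raise ValueError(
                f"heart-rate trace leaves the physiological band [{HR_MIN_BPM}, {HR_MAX_BPM}] bpm"
            )
        return hr


@dataclass
class RadarCube:
    """Raw recording: one real sampled chirp per frame plus metadata."""

    data: np.ndarray          # float32, n_frames x n_samples
    config: RadarConfig
    t_slow: np.ndarray        # s, length n_frames

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        self.t_slow = np.asarray(self.t_slow, dtype=float)
        if self.data.shape != (len(self.t_slow), self.config.n_samples):
            raise ValueError("cube shape inconsistent with t_slow/config")


@dataclass
class GroundTruthTrace:
    """Reference heart-rate trace (chest-strap style), 1 Hz by default."""

    t: np.ndarray
    hr: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.hr = np.asarray(self.hr, dtype=float)
        if self.t.shape != self.hr.shape:
            raise ValueError("t and hr must have equal length")
        if np.any(self.hr < HR_MIN_BPM) or np.any(self.hr > HR_MAX_BPM):
            raise ValueError("reference HR outside [30, 220] bpm")

    def to_csv(self, path: str | os.PathLike) -> None:
        pd.DataFrame({"time_s": self.t, "hr_bpm": self.hr}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | os.PathLike) -> "GroundTruthTrace":
        df = pd.read_csv(path)
        return cls(df["time_s"].to_numpy(), df["hr_bpm"].to_numpy())


def _cardiac_waveform(theta: np.ndarray, shape: str) -> np.ndarray:
    """Unit-amplitude, zero-mean periodic cardiac waveform in phase theta."""
    if shape == "sinusoid":
        return np.sin(theta)
    # raised-cosine pulse train: ((1+cos)/2)^4 has Fourier weights
    # (35, 56, 28, 8, 1)/128 -> dominant fundamental plus decaying harmonics
    w = (0.5 * (1.0 + np.cos(theta))) ** 4
    return (w - 35.0 / 128.0) / (93.0 / 128.0)


def simulate_displacement(
    scene: SceneConfig, t_slow: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Chest displacement R(t) in metres and the true HR (bpm) per sample.

    R(t) = range0 + cardiac(t) + respiration(t) + vibration(t).  The cardiac
    component's instantaneous frequency follows the configured HR trace; the
    vibration is Gaussian noise band-limited to ``vib_band`` and scaled to
    ``vib_rms``.
    """
    t_slow = np.asarray(t_slow, dtype=float)
    if t_slow.size == 0:
        raise ValueError("t_slow must be non-empty")
    if t_slow.size > 1:
        steps = np.diff(t_slow)
        if not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise ValueError("t_slow must be uniformly spaced")

    hr = scene.hr_at(t_slow)
    r = np.full(t_slow.shape, scene.range0, dtype=float)

    if scene.cardiac_amp > 0:
        theta = 2 * np.pi * cumulative_trapezoid(hr / 60.0, t_slow, initial=0.0)
        r += scene.cardiac_amp * _cardiac_waveform(theta, scene.cardiac_shape)
    if scene.resp_amp > 0:
        r += scene.resp_amp * np.sin(2 * np.pi * scene.resp_rate * t_slow)
    if scene.vib_rms > 0 and t_slow.size > 1:
        fs = 1.0 / (t_slow[1] - t_slow[0])
        white = rng.standard_normal(t_slow.size)
        hi = min(scene.vib_band[1], 0.49 * fs)
        sos = signal.butter(4, [scene.vib_band[0], hi], btype="bandpass", fs=fs, output="sos")
        vib = signal.sosfiltfilt(sos, white)
        rms = np.sqrt(np.mean(vib**2))
        if rms > 0:
            r += vib * (scene.vib_rms / rms)
    return r, hr


def synthesize_baseband(
    displacement: np.ndarray,
    config: RadarConfig,
    noise_snr: float = np.inf,
    rng: np.random.Generator | None = None,
) -> RadarCube:
    """Raw baseband cube for a point target at the given per-frame range.

    Frame n is a real sampled tone at the beat frequency
    f_b = 2*B*R(t_n)/(c*T_c) with starting phase 4*pi*R(t_n)/lambda, plus
    white Gaussian noise at ``noise_snr`` dB relative to the tone power.
    """
    r = np.asarray(displacement, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ValueError("displacement must be a non-empty 1-D array")
    if np.any(r >= config.max_range) or np.any(r <= 0):
        raise ValueError(
            f"target range outside (0, {config.max_range:.3f}) m unambiguous interval"
        )

    slope = config.bandwidth / config.chirp_time
    f_beat = 2.0 * slope * r / C_LIGHT
    phase0 = 4.0 * np.pi * r / config.wavelength
    t_fast = np.arange(config.n_samples) / config.fs_fast
    frames = np.cos(2 * np.pi * f_beat[:, None] * t_fast[None, :] + phase0[:, None])

    if np.isfinite(noise_snr):
        if rng is None:
            raise ValueError("an rng is required when noise is enabled")
        p_sig = np.mean(frames**2)
        sigma = np.sqrt(p_sig / 10.0 ** (noise_snr / 10.0))
        frames = frames + sigma * rng.standard_normal(frames.shape)

    t_slow = np.arange(r.size) * config.frame_rep
    return RadarCube(frames.astype(np.float32), config, t_slow)


def simulate_recording(
    config: RadarConfig, scene: SceneConfig, truth_rate_hz: float = 1.0
) -> tuple[RadarCube, GroundTruthTrace]:
    """End-to-end scene synthesis: raw cube plus 1 Hz reference HR trace.

    The reference trace samples the true HR on an inclusive grid
    (0, 1/rate, ..., duration), emulating a chest-strap export.
    """
    rng = np.random.default_rng(scene.seed)
    t_slow = config.t_slow()
    r, _ = simulate_displacement(scene, t_slow, rng)
    cube = synthesize_baseband(r, config, scene.noise_snr, rng)
    t_truth = np.arange(0.0, config.duration + 1e-9, 1.0 / truth_rate_hz)
    truth = GroundTruthTrace(t_truth, scene.hr_at(t_truth))
    return cube, truth


# ---------------------------------------------------------------------------
# Recording container (HDF5): /frames, /t_slow, /truth_t, /truth_hr + attrs
# ---------------------------------------------------------------------------

_CONFIG_ATTRS = (
    "f_start", "f_end", "fs_fast", "n_samples", "frame_rep",
    "n_chirps_per_frame", "duration",
)


def write_recording(
    cube: RadarCube,
    truth: GroundTruthTrace | None,
    path: str | os.PathLike,
    overwrite: bool = False,
) -> None:
    """Persist a recording; round-trip reads are bit-identical."""
    if os.path.exists(path) and not overwrite:
        raise FileExistsError(f"{path} exists; pass overwrite=True to replace it")
    with h5py.File(path, "w") as f:
        f.create_dataset("frames", data=cube.data, dtype="float32")
        f.create_dataset("t_slow", data=cube.t_slow, dtype="float64")
        for name in _CONFIG_ATTRS:
            f.attrs[name] = getattr(cube.config, name)
        if truth is not None:
            f.create_dataset("truth_t", data=truth.t, dtype="float64")
            f.create_dataset("truth_hr", data=truth.hr, dtype="float64")


def read_recording(path: str | os.PathLike) -> tuple[RadarCube, GroundTruthTrace | None]:
    with h5py.File(path, "r") as f:
        kwargs = {name: f.attrs[name] for name in _CONFIG_ATTRS}
        kwargs["n_samples"] = int(kwargs["n_samples"])
        kwargs["n_chirps_per_frame"] = int(kwargs["n_chirps_per_frame"])
        config = RadarConfig(**kwargs)
        cube = RadarCube(f["frames"][...], config, f["t_slow"][...])
        truth = None
        if "truth_t" in f:
            truth = GroundTruthTrace(f["truth_t"][...], f["truth_hr"][...])
    return cube, truth
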