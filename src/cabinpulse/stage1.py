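"""Coarse per-chunk heart-rate estimation (f0).

Each 5 s phase-difference chunk is decomposed with a 3-level DWT; keeping
only the A3 (0-1.25 Hz) and D3 (1.25-2.5 Hz) subbands at 20 Hz isolates the
0-150 bpm band.  An AR model fitted with Burg's method gives a
high-resolution spectrum on the short window; local maxima form
characteristic 1-4 peak patterns, and a configurable decision rule selects a
single frequency (or the mean of two).  A plausibility gate against the
recent estimate history suppresses implausible jumps.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pywt
from scipy import signal as sig
from statsmodels.regression.linear_model import burg as _sm_burg

HR_BAND = (0.5, 2.5)  # Hz, plausible coarse-estimate band


# ---------------------------------------------------------------------------
# Discrete wavelet decomposition
# ---------------------------------------------------------------------------

@dataclass
class WaveletDecomposition:
    """Stepwise DWT pyramid: A_j / D_j coefficient vectors for j = 1..levels."""

    approx: list[np.ndarray]
    detail: list[np.ndarray]
    wavelet_name: str
    levels: int
    lengths: list[int]        # lengths[j] = len(A_j); lengths[0] = input length
    mode: str = "symmetric"

    @property
    def filters(self) -> tuple[np.ndarray, np.ndarray]:
        """Analysis filter pair (low-pass h, high-pass g)."""
        w = pywt.Wavelet(self.wavelet_name)
        return np.asarray(w.dec_lo), np.asarray(w.dec_hi)


def subband_edges(fs: float, level: int) -> dict[str, tuple[float, float]]:
    """Frequency bands (Hz) covered by A_level and D_level at rate ``fs``."""
    nyq = fs / 2.0
    return {
        f"A{level}": (0.0, nyq / 2**level),
        f"D{level}": (nyq / 2**level, nyq / 2 ** (level - 1)),
    }


def dwt_decompose(
    x: np.ndarray, levels: int = 3, wavelet_name: str = "db4", mode: str = "symmetric"
) -> WaveletDecomposition:
    """Iterated analysis: filter with (h, g) and downsample by two per level."""
    x = np.asarray(x, dtype=float)
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if x.size < 2**levels:
        raise ValueError(f"signal of length {x.size} too short for {levels} levels")
    wavelet = pywt.Wavelet(wavelet_name)
    approx: list[np.ndarray] = []
    detail: list[np.ndarray] = []
    lengths = [x.size]
    a = x
    for _ in range(levels):
        a, d = pywt.dwt(a, wavelet, mode=mode)
        approx.append(a)
        detail.append(d)
        lengths.append(a.size)
    return WaveletDecomposition(approx, detail, wavelet_name, levels, lengths, mode)


def reconstruct(
    decomp: WaveletDecomposition,
    keep_approx: bool = True,
    keep_details: Sequence[bool] | None = None,
) -> np.ndarray:
    """Inverse DWT keeping the selected subbands (others zeroed).

    ``keep_details[j-1]`` controls D_j; ``keep_approx`` controls the final
    A_levels.  Keeping everything reproduces the input exactly
    (perfect-reconstruction filter pair).
    """
    wavelet = pywt.Wavelet(decomp.wavelet_name)
    if keep_details is None:
        keep_details = [True] * decomp.levels
    if len(keep_details) != decomp.levels:
        raise ValueError("keep_details must have one flag per level")
    a = decomp.approx[-1] if keep_approx else np.zeros_like(decomp.approx[-1])
    for j in range(decomp.levels, 0, -1):
        d = decomp.detail[j - 1] if keep_details[j - 1] else np.zeros_like(decomp.detail[j - 1])
        a = pywt.idwt(a, d, wavelet, mode=decomp.mode)[: decomp.lengths[j - 1]]
    return a


def reconstruct_hr_band(decomp: WaveletDecomposition) -> np.ndarray:
    """Keep A3 and D3 only (0-2.5 Hz at a 20 Hz rate), zeroing D1 and D2."""
    if decomp.levels < 3:
        raise ValueError("need a decomposition of at least 3 levels")
    keep = [False] * decomp.levels
    keep[2] = True  # D3
    return reconstruct(decomp, keep_approx=True, keep_details=keep)


# ---------------------------------------------------------------------------
# Burg AR spectral estimation
# ---------------------------------------------------------------------------

@dataclass
class ARModel:
    """All-pole model x[n] = -sum_k alpha_k x[n-k] + e[n]."""

    order: int
    coeffs: np.ndarray        # alpha_1..alpha_p
    noise_var: float          # sigma_e^2
    fs: float

    def is_stable(self) -> bool:
        if self.order == 0:
            return True
        roots = np.roots(np.concatenate(([1.0], self.coeffs)))
        return bool(np.all(np.abs(roots) < 1.0))


def burg_ar(x: np.ndarray, order: int, fs: float) -> ARModel:
    """Fit an AR(p) model by Burg's forward+backward prediction-error method."""
    x = np.asarray(x, dtype=float)
    if order < 0 or (order > 0 and order >= x.size / 2):
        raise ValueError("order must satisfy 0 <= p < len(x)/2")
    if x.size <= 2 * order:
        raise ValueError("need len(x) > 2*order samples")
    xd = x - np.mean(x)
    if order == 0:
        return ARModel(0, np.empty(0), float(np.var(xd)) or 1e-30, fs)
    rho, sigma2 = _sm_burg(xd, order=order, demean=False)
    # statsmodels uses x[n] = sum rho_k x[n-k] + e; flip to the -sum convention
    return ARModel(order, -np.asarray(rho, dtype=float), float(sigma2), fs)


@dataclass
class Peak:
    freq: float
    amplitude: float
    prominence: float


@dataclass
class SpectrumEstimate:
    freqs: np.ndarray
    psd: np.ndarray
    peaks: list[Peak] = field(default_factory=list)


def ar_psd(model: ARModel, freqs: np.ndarray | None = None) -> SpectrumEstimate:
    """AR power spectrum P(f) = sigma_e^2 / |1 + sum_k alpha_k e^{-j2pi f k/fs}|^2.

    Default evaluation grid: 512 points over 0.5-2.5 Hz (the displayed heart
    band).
    """
    if freqs is None:
        freqs = np.linspace(HR_BAND[0], HR_BAND[1], 512)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        raise ValueError("empty frequency grid")
    if np.any(freqs < 0) or np.any(freqs > model.fs / 2):
        raise ValueError("grid must lie within [0, fs/2]")
    k = np.arange(1, model.order + 1)
    a_of_f = 1.0 + np.exp(-2j * np.pi * np.outer(freqs, k) / model.fs) @ model.coeffs \
        if model.order else np.ones_like(freqs, dtype=complex)
    psd = model.noise_var / np.abs(a_of_f) ** 2
    return SpectrumEstimate(freqs, psd)


def detect_peaks(spec: SpectrumEstimate, min_prominence_frac: float = 0.05) -> list[Peak]:
    """Local maxima with prominence >= frac * max(psd), sorted by frequency."""
    if spec.freqs.size < 3:
        raise ValueError("need at least 3 grid points")
    top = float(np.max(spec.psd))
    if top <= 0:
        return []
    idx, props = sig.find_peaks(spec.psd, prominence=min_prominence_frac * top)
    peaks = [
        Peak(float(spec.freqs[i]), float(spec.psd[i]), float(p))
        for i, p in zip(idx, props["prominences"])
    ]
    spec.peaks = peaks
    return peaks


# ---------------------------------------------------------------------------
# Peak decision and plausibility gating
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DecisionConfig:
    """Thresholds of the pattern-based peak decision rules."""

    harmonic_ratio: tuple[float, float] = (1.8, 2.2)  # f_high/f_low treated as octave
    amp_ratio_mean: float = 1.25    # near-equal amplitudes -> take the mean
    harmonic_tol: float = 0.10      # +-10% around 2x for pruning in 3-4 peak patterns
    jump_limit_hz: float = 0.25     # 15 bpm plausibility bound per 5 s chunk
    band: tuple[float, float] = HR_BAND


@dataclass
class CoarseEstimate:
    f0: float | None
    n_peaks_detected: int
    rule_applied: str
    valid: bool


def _two_peak_rule(lo: Peak, hi: Peak, cfg: DecisionConfig) -> tuple[float, str]:
    ratio = hi.freq / lo.freq
    if cfg.harmonic_ratio[0] <= ratio <= cfg.harmonic_ratio[1]:
        return lo.freq, "H1"  # harmonic pair: pick the fundamental
    amps = sorted((lo.amplitude, hi.amplitude))
    if amps[1] / amps[0] < cfg.amp_ratio_mean:
        return 0.5 * (lo.freq + hi.freq), "M1"  # near-equal: mean of the two
    return (lo if lo.amplitude > hi.amplitude else hi).freq, "A1"


def _prune_harmonics(peaks: list[Peak], tol: float) -> list[Peak]:
    """Drop peaks lying within +-tol of twice a retained lower peak."""
    retained: list[Peak] = []
    for p in peaks:  # peaks sorted by ascending frequency
        if any(abs(p.freq - 2 * q.freq) <= tol * 2 * q.freq for q in retained):
            continue
        retained.append(p)
    return retained


def peak_decision(
    peaks: list[Peak],
    history: Sequence[float] = (),
    config: DecisionConfig = DecisionConfig(),
) -> CoarseEstimate:
    """Select f0 from the peak pattern (pure function of peaks + history).

    Rules by peak count: a single peak is taken as-is; two peaks are resolved
    as a harmonic pair (H1), a near-equal pair averaged (M1), or by amplitude
    (A1); 3-4 peaks are first harmonic-pruned then reduced to the two largest
    survivors; more than 4 peaks fall back to the history median (or the
    largest peak without history).
    """
    n = len(peaks)
    if n == 0:
        return CoarseEstimate(None, 0, "none", False)
    if n == 1:
        return CoarseEstimate(peaks[0].freq, 1, "single", True)
    if n == 2:
        f0, rule = _two_peak_rule(peaks[0], peaks[1], config)
        return CoarseEstimate(f0, 2, rule, True)
    if n <= 4:
        survivors = _prune_harmonics(peaks, config.harmonic_tol)
        top_two = sorted(survivors, key=lambda p: p.amplitude, reverse=True)[:2]
        top_two.sort(key=lambda p: p.freq)
        if len(top_two) == 1:
            return CoarseEstimate(top_two[0].freq, n, "prune:single", True)
        f0, rule = _two_peak_rule(top_two[0], top_two[1], config)
        return CoarseEstimate(f0, n, f"prune:{rule}", True)
    if history:
        med = float(np.median(list(history)[-3:]))
        best = min(peaks, key=lambda p: abs(p.freq - med))
        return CoarseEstimate(best.freq, n, "history", True)
    best = max(peaks, key=lambda p: p.amplitude)
    return CoarseEstimate(best.freq, n, "max-amp", True)


def plausibility_check(
    estimate: CoarseEstimate,
    history: Sequence[float] = (),
    config: DecisionConfig = DecisionConfig(),
) -> CoarseEstimate:
    """Gate f0 against the accepted history; implausible jumps are suppressed.

    An estimate deviating from the median of the last three accepted values
    by more than ``jump_limit_hz`` (default 0.25 Hz = 15 bpm) is marked
    invalid, signalling the fine stage to continue independently.  The gate
    only engages once three values have been accepted: a median of fewer
    would let a single wrong cold-start estimate veto correct successors.
    """
    if estimate.f0 is None:
        return estimate
    lo, hi = config.band
    valid = lo <= estimate.f0 <= hi
    if valid and len(history) >= 3:
        med = float(np.median(list(history)[-3:]))
        valid = abs(estimate.f0 - med) <= config.jump_limit_hz
    return CoarseEstimate(estimate.f0, estimate.n_peaks_detected, estimate.rule_applied, valid)


def coarse_estimate_chunk(
    chunk: np.ndarray,
    fs: float,
    history: Sequence[float] = (),
    *,
    wavelet_name: str = "db4",
    levels: int = 3,
    ar_order: int = 12,
    n_psd: int = 512,
    min_prominence_frac: float = 0.05,
    decision: DecisionConfig = DecisionConfig(),
) -> CoarseEstimate:
    """Full coarse stage for one chunk: DWT band isolation -> Burg -> decision."""
    decomp = dwt_decompose(chunk, levels=levels, wavelet_name=wavelet_name)
    hr_sig = reconstruct_hr_band(decomp)
    model = burg_ar(hr_sig, ar_order, fs)
    spec = ar_psd(model, np.linspace(decision.band[0], decision.band[1], n_psd))
    peaks = detect_peaks(spec, min_prominence_frac)
    est = peak_decision(peaks, history, decision)
    return plausibility_check(est, history, decision)
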