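"""End-to-end estimation pipeline: raw cube -> per-chunk HR table.

Chains preprocess -> chunking -> coarse stage -> fine stage -> sequential
Kalman fusion.  The fine stage's search window is centred on the coarse
estimate when it passed the plausibility gate, otherwise on the previous
fused value; with neither available the full 0.5-2.5 Hz band is searched.

Chunk convention: the phase difference is initialised with a leading zero
(``diff(phi, prepend=phi[0])``) so that a recording of T seconds yields
exactly floor(T / chunk_len) chunks of chunk_len * fs samples each.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import fuse, preprocess, stage1, stage2
from .config import PipelineConfig
from .simulate import RadarCube, read_recording

logger = logging.getLogger("cabinpulse")


class DataError(ValueError):
    """Raised when a recording cannot be processed (bad data, not bad config)."""


@dataclass
class ChunkSet:
    """Non-overlapping, contiguous half-open index windows of equal length."""

    bounds: list[tuple[int, int]]
    chunk_len_s: float
    fs: float
    n_dropped_samples: int = 0

    def __len__(self) -> int:
        return len(self.bounds)

    def start_times(self) -> np.ndarray:
        return np.array([b[0] / self.fs for b in self.bounds])


def chunk(n_samples: int, fs: float, chunk_len_s: float = 5.0) -> ChunkSet:
    """Split ``n_samples`` at rate ``fs`` into 5 s windows; remainder dropped."""
    per = fs * chunk_len_s
    if abs(per - round(per)) > 1e-9:
        raise ValueError("fs * chunk_len_s must be an integer sample count")
    per = int(round(per))
    if n_samples < per:
        raise ValueError(f"signal shorter than one {chunk_len_s} s chunk")
    n_chunks = n_samples // per
    dropped = n_samples - n_chunks * per
    if dropped:
        logger.debug("dropping %d trailing samples shorter than one chunk", dropped)
    bounds = [(i * per, (i + 1) * per) for i in range(n_chunks)]
    return ChunkSet(bounds, chunk_len_s, fs, dropped)


@dataclass
class PipelineResult:
    table: pd.DataFrame
    chunks: ChunkSet
    intermediates: dict = field(default_factory=dict)


def preprocess_cube(cube: RadarCube, cfg: PipelineConfig, keep: dict | None = None) -> np.ndarray:
    """Run the preprocessing chain; returns the padded phase-difference series."""
    pp = cfg.preprocess
    rpm = preprocess.range_fft(cube, pp.window)
    if pp.use_clutter_filter:
        rpm = preprocess.clutter_filter(rpm, pp.clutter_cutoff_hz)
    try:
        bin_index = preprocess.select_range_bin(rpm, pp.search_range_m)
        phi = preprocess.extract_phase(rpm, bin_index)
    except ValueError as exc:
        raise DataError(f"preprocess: {exc}") from exc
    phi_bp = preprocess.bandpass_hr(phi, pp.hr_band_hz)
    if pp.use_hilbert_kalman:
        phi_bp = preprocess.hilbert_kalman(phi_bp, delta=pp.hk_delta)
    # leading-zero difference keeps chunk bookkeeping aligned with the frame grid
    dphi = np.diff(phi_bp.phi, prepend=phi_bp.phi[0])
    if keep is not None:
        keep.update(
            {"bin_index": bin_index, "phi": phi.phi, "phi_filtered": phi_bp.phi, "dphi": dphi}
        )
    return dphi


def run_pipeline(
    cube: RadarCube,
    cfg: PipelineConfig | None = None,
    dump_intermediates: str | os.PathLike | None = None,
) -> PipelineResult:
    """Full two-stage estimation on one recording."""
    cfg = cfg or PipelineConfig()
    fs = cube.config.fs_slow
    keep: dict = {}
    dphi = preprocess_cube(cube, cfg, keep)

    try:
        chunks = chunk(dphi.size, fs, cfg.chunk_len_s)
    except ValueError as exc:
        raise DataError(str(exc)) from exc

    s1 = cfg.stage1
    s2 = cfg.stage2
    decision = stage1.DecisionConfig(
        harmonic_ratio=s1.harmonic_ratio,
        amp_ratio_mean=s1.amp_ratio_mean,
        harmonic_tol=s1.harmonic_tol,
        jump_limit_hz=s1.jump_limit_bpm / 60.0,
        band=s1.band_hz,
    )
    n_chunk = chunks.bounds[0][1] - chunks.bounds[0][0]
    basis = stage2.build_basis(n_chunk, fs, s2.f_lo_hz, s2.f_hi_hz, s2.n_freqs)
    half_width_hz = s2.half_width_bpm / 60.0

    # ---- pass 1: coarse estimation with plausibility gating ----
    history: list[float] = []
    n_rejected = 0
    coarse_results: list[stage1.CoarseEstimate] = []
    for idx, (a, b) in enumerate(chunks.bounds):
        try:
            coarse = stage1.coarse_estimate_chunk(
                dphi[a:b], fs, history,
                wavelet_name=s1.wavelet, levels=s1.levels, ar_order=s1.ar_order,
                n_psd=s1.psd_points, min_prominence_frac=s1.prominence_frac,
                decision=decision,
            )
        except ValueError as exc:
            raise DataError(f"stage1 failed on chunk {idx}: {exc}") from exc
        coarse_results.append(coarse)
        if coarse.valid:
            history.append(coarse.f0)
            n_rejected = 0
        elif coarse.f0 is not None:
            # stale-history guard: after several consecutive rejections the
            # plausibility gate is likely locked onto a wrong level; restart
            n_rejected += 1
            if n_rejected >= s1.reacquire_after:
                logger.debug("chunk %d: clearing stale f0 history", idx)
                history.clear()
                n_rejected = 0

    # ---- pass 2: fine estimation + sequential Kalman fusion ----
    fcfg = cfg.fuse
    valid_f0 = [c.f0 * 60.0 for c in coarse_results if c.valid]
    state: fuse.KalmanState | None = None
    if valid_f0:
        # robust initialisation: median of the first five coarse estimates —
        # wide enough to straddle the stage-1 re-acquisition window, so a
        # harmonic-locked start cannot dominate the median
        state = fuse.KalmanState.scalar(
            float(np.median(valid_f0[:5])),
            P0=fcfg.P0, Q=fcfg.Q, R0=fcfg.R0, R1=fcfg.R1,
        )
    rows = []
    for idx, (a, b) in enumerate(chunks.bounds):
        y = dphi[a:b]
        coarse = coarse_results[idx]
        fit = stage2.rvm_fit(
            basis, y, max_iter=s2.max_iter, tol=s2.tol, prune_alpha=s2.prune_alpha
        )
        spec = stage2.energy_spectrum(fit, basis)
        if coarse.valid:
            center = coarse.f0
        elif state is not None:
            center = state.hr / 60.0
        else:
            center = None
        if center is not None:
            fine = stage2.windowed_peak_select(
                spec, center, half_width_hz, s2.prominence_frac, s2.pair_max_ratio
            )
        else:
            fine = stage2.full_band_select(spec, s2.prominence_frac)

        f0_bpm = coarse.f0 * 60.0 if coarse.valid else None
        f1_bpm = fine.f1 * 60.0
        if state is None:
            state = fuse.KalmanState.scalar(
                f0_bpm if f0_bpm is not None else f1_bpm,
                P0=fcfg.P0, Q=fcfg.Q, R0=fcfg.R0, R1=fcfg.R1,
            )
        state = fuse.predict(state)
        infl = fcfg.r1_fallback_inflation if fine.fallback_used else 1.0
        state = fuse.sequential_update(
            state, f0_bpm, f1_bpm, r1_inflation=infl, huber_delta=fcfg.huber_delta
        )

        logger.debug(
            "chunk %d: f0=%s f1=%.1f fused=%.1f rule=%s",
            idx, f"{f0_bpm:.1f}" if f0_bpm else "-", f1_bpm, state.hr, coarse.rule_applied,
        )
        rows.append(
            {
                "chunk_index": idx,
                "t_start_s": a / fs,
                "f0_bpm": np.nan if f0_bpm is None else f0_bpm,
                "f1_bpm": f1_bpm,
                "hr_skf_bpm": state.hr,
                "P": float(state.P[0, 0]),
                "n_peaks": coarse.n_peaks_detected,
                "rule": coarse.rule_applied,
                "valid": coarse.valid,
                "n_window_peaks": fine.n_window_peaks,
                "fallback_used": fine.fallback_used,
            }
        )

    table = pd.DataFrame(rows)
    result = PipelineResult(table, chunks, keep)
    if dump_intermediates is not None:
        _dump(result, dump_intermediates, fs)
    return result


def run_file(
    path: str | os.PathLike,
    cfg: PipelineConfig | None = None,
    dump_intermediates: str | os.PathLike | None = None,
) -> PipelineResult:
    try:
        cube, _ = read_recording(path)
    except (OSError, KeyError) as exc:
        raise DataError(f"cannot read recording {path}: {exc}") from exc
    return run_pipeline(cube, cfg, dump_intermediates)


def _dump(result: PipelineResult, out_dir: str | os.PathLike, fs: float) -> None:
    os.makedirs(out_dir, exist_ok=True)
    result.table.to_csv(os.path.join(out_dir, "chunks.csv"), index=False)
    for name in ("phi", "phi_filtered", "dphi"):
        arr = result.intermediates.get(name)
        if arr is not None:
            t = np.arange(arr.size) / fs
            pd.DataFrame({"time_s": t, name: arr}).to_csv(
                os.path.join(out_dir, f"{name}.csv"), index=False
            )
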