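"""Agreement metrics between the fused radar HR and a reference trace.

Covers the validation toolkit used for wearable-grade HR comparison: mean
absolute / mean relative error, error counting gated on the reference
standard deviation within each measurement period, Bland-Altman limits of
agreement (bias +- 1.96 * SD of the paired differences), and Pearson
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class AlignedPairs:
    """Time-aligned (estimate, reference) heart-rate pairs in bpm."""

    t: np.ndarray
    est: np.ndarray
    ref: np.ndarray
    recording: np.ndarray | None = None   # optional per-pair recording id
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.est = np.asarray(self.est, dtype=float)
        self.ref = np.asarray(self.ref, dtype=float)
        if not (self.t.size == self.est.size == self.ref.size):
            raise ValueError("t, est, ref must have equal length")
        if self.recording is not None:
            self.recording = np.asarray(self.recording)
            if self.recording.size != self.t.size:
                raise ValueError("recording ids must match pair count")


def align(
    est_t: np.ndarray,
    est: np.ndarray,
    ref_t: np.ndarray,
    ref: np.ndarray,
    chunk_len_s: float = 5.0,
) -> AlignedPairs:
    """Pair each chunk estimate with the reference mean over its interval.

    ``est_t`` holds chunk start times; the reference for a chunk is the mean
    of all reference samples inside [t, t + chunk_len_s).  Chunks without
    any reference sample are dropped and counted.
    """
    est_t = np.asarray(est_t, dtype=float)
    est = np.asarray(est, dtype=float)
    ref_t = np.asarray(ref_t, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if ref_t.size == 0 or est_t.size == 0:
        raise ValueError("empty trace")
    if ref_t.max() < est_t.min() or ref_t.min() >= est_t.max() + chunk_len_s:
        raise ValueError("estimate and reference traces do not overlap in time")

    t_out, e_out, r_out = [], [], []
    dropped = 0
    for t0, e in zip(est_t, est):
        inside = (ref_t >= t0) & (ref_t < t0 + chunk_len_s)
        if not np.any(inside):
            dropped += 1
            continue
        t_out.append(t0)
        e_out.append(e)
        r_out.append(float(np.mean(ref[inside])))
    return AlignedPairs(np.array(t_out), np.array(e_out), np.array(r_out), n_dropped=dropped)


def mae_mre(pairs: AlignedPairs) -> tuple[float, float]:
    """(mean absolute error in bpm, mean relative error in percent)."""
    if pairs.est.size == 0:
        raise ValueError("no pairs")
    if np.any(pairs.ref == 0):
        raise ValueError("reference contains zeros; MRE undefined")
    err = np.abs(pairs.est - pairs.ref)
    return float(np.mean(err)), float(np.mean(err / pairs.ref) * 100.0)


@dataclass
class SDGatedErrors:
    """Error bookkeeping gated on the reference SD of each measurement period."""

    ref_sd: float                       # mean per-recording reference SD
    n_pairs: int
    count_1sd: int
    count_2sd: int
    rate_1sd: float
    rate_2sd: float
    mae_1sd: float | None               # MAE/MRE restricted to error chunks
    mre_1sd: float | None
    mae_2sd: float | None
    mre_2sd: float | None
    degenerate_sd: bool = False


def out_of_sd_errors(pairs: AlignedPairs) -> SDGatedErrors:
    """Count chunks whose deviation exceeds 1 or 2 reference SDs.

    The SD is that of the reference HR within each measurement period (one
    recording; grouped by ``pairs.recording`` when ids are present).  A
    chunk is an error at level k iff |est - ref| > k * SD of its own
    recording.  A degenerate SD of zero falls back to an absolute 1 bpm
    tolerance and is flagged.
    """
    if pairs.est.size < 2:
        raise ValueError("need at least 2 pairs per measurement period")
    groups = (
        [np.arange(pairs.est.size)]
        if pairs.recording is None
        else [np.flatnonzero(pairs.recording == g) for g in np.unique(pairs.recording)]
    )
    err = np.abs(pairs.est - pairs.ref)
    mask1 = np.zeros(err.size, dtype=bool)
    mask2 = np.zeros(err.size, dtype=bool)
    sds, degenerate = [], False
    for idx in groups:
        sd = float(np.std(pairs.ref[idx], ddof=1)) if idx.size > 1 else 0.0
        if sd == 0.0:
            degenerate = True
            sd = 1.0  # absolute tolerance for a flat reference
        sds.append(sd)
        mask1[idx] = err[idx] > sd
        mask2[idx] = err[idx] > 2 * sd

    def _gated(mask: np.ndarray) -> tuple[float | None, float | None]:
        if not np.any(mask):
            return None, None
        sub = AlignedPairs(pairs.t[mask], pairs.est[mask], pairs.ref[mask])
        return mae_mre(sub)

    mae1, mre1 = _gated(mask1)
    mae2, mre2 = _gated(mask2)
    n = err.size
    return SDGatedErrors(
        ref_sd=float(np.mean(sds)),
        n_pairs=n,
        count_1sd=int(mask1.sum()),
        count_2sd=int(mask2.sum()),
        rate_1sd=float(mask1.mean()),
        rate_2sd=float(mask2.mean()),
        mae_1sd=mae1,
        mre_1sd=mre1,
        mae_2sd=mae2,
        mre_2sd=mre2,
        degenerate_sd=degenerate,
    )


def bland_altman(pairs: AlignedPairs) -> tuple[float, float, float, float]:
    """(bias, loa_low, loa_high, sd_diff): limits of agreement bias +- 1.96 SD."""
    if pairs.est.size < 2:
        raise ValueError("need at least 2 pairs")
    d = pairs.est - pairs.ref
    bias = float(np.mean(d))
    sd = float(np.std(d, ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd, sd


def pearson(pairs: AlignedPairs) -> tuple[float, float]:
    """Sample Pearson r and two-sided p-value (t distribution)."""
    if pairs.est.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(pairs.est) == 0 or np.std(pairs.ref) == 0:
        raise ValueError("constant input; correlation undefined")
    r, p = stats.pearsonr(pairs.est, pairs.ref)
    return float(r), float(p)


@dataclass
class AgreementReport:
    mae: float
    mre: float
    sd_gated: SDGatedErrors
    bias: float
    loa_low: float
    loa_high: float
    sd_diff: float
    pearson_r: float
    p_value: float
    n_pairs: int

    def to_dict(self) -> dict:
        d = {
            "mae_bpm": self.mae,
            "mre_pct": self.mre,
            "bias_bpm": self.bias,
            "loa_low_bpm": self.loa_low,
            "loa_high_bpm": self.loa_high,
            "sd_diff_bpm": self.sd_diff,
            "pearson_r": self.pearson_r,
            "p_value": self.p_value,
            "n_pairs": self.n_pairs,
            "ref_sd_bpm": self.sd_gated.ref_sd,
            "out_of_1sd_count": self.sd_gated.count_1sd,
            "out_of_1sd_rate": self.sd_gated.rate_1sd,
            "out_of_2sd_count": self.sd_gated.count_2sd,
            "out_of_2sd_rate": self.sd_gated.rate_2sd,
            "out_of_1sd_mae_bpm": self.sd_gated.mae_1sd,
            "out_of_1sd_mre_pct": self.sd_gated.mre_1sd,
            "out_of_2sd_mae_bpm": self.sd_gated.mae_2sd,
            "out_of_2sd_mre_pct": self.sd_gated.mre_2sd,
        }
        return d


def agreement_report(pairs: AlignedPairs) -> AgreementReport:
    """Full agreement summary for one set of aligned pairs.

    Pearson correlation is reported as NaN when undefined (constant trace).
    """
    mae, mre = mae_mre(pairs)
    gated = out_of_sd_errors(pairs)
    bias, lo, hi, sd = bland_altman(pairs)
    try:
        r, p = pearson(pairs)
    except ValueError:
        r, p = float("nan"), float("nan")
    return AgreementReport(mae, mre, gated, bias, lo, hi, sd, r, p, pairs.est.size)


def plot_bland_altman(pairs: AlignedPairs, path: str) -> None:
    """Bland-Altman scatter with bias and 95% limits of agreement."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bias, lo, hi, _ = bland_altman(pairs)
    mean = 0.5 * (pairs.est + pairs.ref)
    diff = pairs.est - pairs.ref
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.scatter(mean, diff, s=12, alpha=0.7)
    ax.axhline(bias, color="k", label=f"bias {bias:.2f} bpm")
    for y in (lo, hi):
        ax.axhline(y, color="k", linestyle=":")
    ax.set_xlabel("mean of methods (bpm)")
    ax.set_ylabel("estimate - reference (bpm)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
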