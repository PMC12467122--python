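"""Fine per-chunk heart-rate estimation (f1) by sparse line-spectrum fitting.

The 5 s phase-difference chunk y (N = 100 samples at 20 Hz) is modelled as a
sparse combination of sine/cosine atoms on a dense frequency grid,
y = Phi x + eps, and solved with sparse Bayesian regression (relevance
vector machine with automatic relevance determination): each weight carries
its own precision hyperparameter, updated by evidence maximisation, and
weights whose precision diverges are pruned.  The per-frequency energy
P(f_m) = mu_m(sin)^2 + mu_m(cos)^2 yields a line spectrum; within a narrow
window centred on the coarse estimate f0 (default +-12.5 bpm = 0.208 Hz)
the mean of the two strongest peaks is the refined estimate f1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sig


@dataclass
class FrequencyBasis:
    """Sin/cos dictionary: columns 1..M are sines, M+1..2M cosines."""

    t: np.ndarray             # s, length N
    f: np.ndarray             # Hz, length M
    Phi: np.ndarray           # N x 2M

    @property
    def n_freqs(self) -> int:
        return self.f.size


def build_basis(
    n_samples: int = 100,
    fs: float = 20.0,
    f_lo: float = 0.5,
    f_hi: float = 2.5,
    n_freqs: int = 200,
) -> FrequencyBasis:
    """Frequency dictionary over an inclusive linear grid (default 0.5-2.5 Hz,
    200 points, giving a 100 x 400 design matrix for 5 s chunks at 20 Hz)."""
    if n_samples < 2 or n_freqs < 2:
        raise ValueError("need at least 2 samples and 2 grid frequencies")
    if f_hi > fs / 2:
        raise ValueError("f_hi exceeds Nyquist")
    if not 0 < f_lo < f_hi:
        raise ValueError("need 0 < f_lo < f_hi")
    t = np.arange(n_samples) / fs
    f = np.linspace(f_lo, f_hi, n_freqs)
    arg = 2 * np.pi * np.outer(t, f)
    Phi = np.concatenate([np.sin(arg), np.cos(arg)], axis=1)
    return FrequencyBasis(t, f, Phi)


@dataclass
class RVMFit:
    """Posterior summary of the sparse Bayesian fit."""

    mu: np.ndarray            # length 2M; pruned weights exactly zero
    alpha: np.ndarray         # per-weight precision; inf where pruned
    noise_var: float
    n_relevant: int
    converged: bool
    n_iter: int


def rvm_fit(
    basis: FrequencyBasis,
    y: np.ndarray,
    *,
    max_iter: int = 500,
    tol: float = 1e-6,
    prune_alpha: float = 1e9,
    noise_floor_rel: float = 1e-6,
) -> RVMFit:
    """Sequential ARD evidence maximisation (deterministic; no random init).

    The marginal likelihood is maximised one basis atom at a time: for every
    atom the sparsity and quality factors (S_m, Q_m) are computed from the
    current active set, and the single add / delete / re-estimate action
    with the largest analytic evidence gain is applied per iteration.  An
    atom is relevant only while its evidence contribution is positive, which
    keeps near-collinear sine/cosine neighbours from entering with huge
    cancelling weights (the failure mode of jointly-initialised ARD on
    coherent dictionaries).  Precisions exceeding ``prune_alpha`` are
    treated as irrelevant.  The noise variance is re-estimated from the
    residual each iteration, floored at ``noise_floor_rel`` times the input
    variance.
    """
    Phi = basis.Phi
    y = np.asarray(y, dtype=float)
    if y.shape != (Phi.shape[0],):
        raise ValueError(f"y must have length {Phi.shape[0]}")
    if not np.all(np.isfinite(y)):
        raise ValueError("y contains non-finite values")

    n, d = Phi.shape
    var_y = float(np.var(y))
    empty = RVMFit(np.zeros(d), np.full(d, np.inf), max(var_y, 1e-12), 0, True, 0)
    if var_y == 0.0:
        return empty

    floor = max(noise_floor_rel * var_y, 1e-30)
    sigma2 = max(0.1 * var_y, floor)
    G = Phi.T @ Phi                     # gram matrix, d x d
    g_diag = np.diag(G).copy()
    b = Phi.T @ y

    # seed with the atom explaining the most energy
    first = int(np.argmax(b**2 / g_diag))
    denom = b[first] ** 2 / g_diag[first] - sigma2
    if denom <= 0:
        return empty
    alpha = np.full(d, np.inf)
    alpha[first] = g_diag[first] / denom
    active = [first]

    mu = np.zeros(0)
    sigma_mat = np.zeros((0, 0))
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        idx = np.asarray(active)
        beta = 1.0 / sigma2
        gram = beta * G[np.ix_(idx, idx)]
        gram[np.diag_indices_from(gram)] += alpha[idx]
        try:
            sigma_mat = np.linalg.inv(gram)
        except np.linalg.LinAlgError:
            sigma_mat = np.linalg.pinv(gram)
        mu = beta * (sigma_mat @ b[idx])

        # sparsity/quality factors for every atom given the active set
        g_am = G[idx, :]                          # |A| x d
        tmp = sigma_mat @ g_am                    # |A| x d
        S = beta * g_diag - beta**2 * np.einsum("ij,ij->j", g_am, tmp)
        Q = beta * b - beta**2 * (tmp.T @ b[idx])

        s = S.copy()
        q = Q.copy()
        a_act = alpha[idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            denom_act = a_act - S[idx]
            s[idx] = a_act * S[idx] / denom_act
            q[idx] = a_act * Q[idx] / denom_act
        theta = q**2 - s

        # evidence change for the best action on each atom
        dl = np.full(d, -np.inf)
        is_active = np.zeros(d, dtype=bool)
        is_active[idx] = True
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            # addition of an inactive atom with positive evidence
            add = (~is_active) & (theta > 0) & (S > 0) & (Q**2 > S)
            dl[add] = 0.5 * ((Q[add] ** 2 - S[add]) / S[add] + np.log(S[add] / Q[add] ** 2))
            # re-estimation of an active atom
            re = is_active & (theta > 0)
            a_new = np.where(theta > 0, s**2 / np.maximum(theta, 1e-300), np.inf)
            delta_inv = 1.0 / a_new[re] - 1.0 / alpha[re]
            frac = S[re] * delta_inv
            ok = frac > -1.0
            dl_re = np.full(frac.shape, -np.inf)
            dl_re[ok] = 0.5 * (
                Q[re][ok] ** 2 * delta_inv[ok] / (1.0 + frac[ok]) - np.log1p(frac[ok])
            )
            dl[re] = dl_re
            # deletion of an active atom that lost its evidence
            if len(active) > 1:
                rm = is_active & (theta <= 0)
                ratio = S[rm] / alpha[rm]
                okr = ratio < 1.0
                dl_rm = np.full(ratio.shape, np.inf)  # always delete a negative-evidence atom
                dl_rm[okr] = 0.5 * (
                    Q[rm][okr] ** 2 / (S[rm][okr] - alpha[rm][okr]) - np.log1p(-ratio[okr])
                )
                dl[rm] = np.where(np.isfinite(dl_rm), np.maximum(dl_rm, tol * 2), tol * 2)

        m = int(np.argmax(dl))
        if not np.isfinite(dl[m]) or dl[m] < tol:
            converged = True
            break
        if is_active[m] and theta[m] <= 0:
            active.remove(m)
            alpha[m] = np.inf
        else:
            new_a = s[m] ** 2 / theta[m]
            if new_a > prune_alpha:
                if is_active[m]:
                    active.remove(m)
                alpha[m] = np.inf
            else:
                alpha[m] = new_a
                if not is_active[m]:
                    active.append(m)

        # residual-based noise re-estimate
        idx = np.asarray(active)
        if idx.size:
            beta = 1.0 / sigma2
            gram = beta * G[np.ix_(idx, idx)]
            gram[np.diag_indices_from(gram)] += alpha[idx]
            try:
                sigma_mat = np.linalg.inv(gram)
            except np.linalg.LinAlgError:
                sigma_mat = np.linalg.pinv(gram)
            mu = beta * (sigma_mat @ b[idx])
            resid = y - Phi[:, idx] @ mu
            gamma = 1.0 - alpha[idx] * np.diag(sigma_mat)
            denom_n = max(n - float(np.sum(np.clip(gamma, 0.0, 1.0))), 1e-3)
            sigma2 = max(float(resid @ resid) / denom_n, floor)
        else:
            break

    mu_full = np.zeros(d)
    if active:
        mu_full[np.asarray(active)] = mu
    return RVMFit(
        mu=mu_full,
        alpha=alpha,
        noise_var=sigma2,
        n_relevant=len(active),
        converged=converged,
        n_iter=it,
    )


@dataclass
class EnergySpectrum:
    f: np.ndarray
    energy: np.ndarray


def energy_spectrum(fit: RVMFit, basis: FrequencyBasis) -> EnergySpectrum:
    """Per-frequency energy P(f_m) = mu_m(sin)^2 + mu_m(cos)^2."""
    m = basis.n_freqs
    if fit.mu.size != 2 * m:
        raise ValueError("weight vector length inconsistent with basis")
    energy = fit.mu[:m] ** 2 + fit.mu[m:] ** 2
    return EnergySpectrum(basis.f, energy)


@dataclass
class FineEstimate:
    f1: float
    n_window_peaks: int
    fallback_used: bool


def _local_peaks(energy: np.ndarray, prominence_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Local maxima including endpoints (the line spectrum is spiky)."""
    top = float(np.max(energy))
    if top <= 0:
        return np.array([], dtype=int), np.array([])
    padded = np.concatenate([[-1.0], energy, [-1.0]])
    idx, props = sig.find_peaks(padded, prominence=prominence_frac * top)
    return idx - 1, props["prominences"]


def windowed_peak_select(
    spec: EnergySpectrum,
    center: float,
    half_width_hz: float = 12.5 / 60.0,
    prominence_frac: float = 0.05,
    pair_max_ratio: float | None = None,
) -> FineEstimate:
    """f1 = mean of the two strongest peaks within [center +- half_width].

    One peak: that peak.  No peak (flat or empty window energy): fall back
    to f1 = center with ``fallback_used`` set, letting the fusion stage
    down-weight the chunk.  With ``pair_max_ratio`` set, the two peaks are
    averaged only when their energies are within that factor of each other
    (a split spectral line); a dominant single line is then taken as-is
    rather than being dragged toward a weak spurious neighbour.
    """
    mask = (spec.f >= center - half_width_hz) & (spec.f <= center + half_width_hz)
    if not np.any(mask):
        raise ValueError("search window does not intersect the frequency grid")
    f_win = spec.f[mask]
    e_win = spec.energy[mask]
    idx, _ = _local_peaks(e_win, prominence_frac)
    if idx.size == 0:
        return FineEstimate(center, 0, True)
    if idx.size == 1:
        return FineEstimate(float(f_win[idx[0]]), 1, False)
    top_two = idx[np.argsort(e_win[idx])[-2:]]
    if pair_max_ratio is not None:
        e_hi, e_lo = e_win[top_two[1]], e_win[top_two[0]]
        if max(e_hi, e_lo) > pair_max_ratio * min(e_hi, e_lo):
            return FineEstimate(float(f_win[top_two[1]]), int(idx.size), False)
    return FineEstimate(float(np.mean(f_win[top_two])), int(idx.size), False)


def full_band_select(spec: EnergySpectrum, prominence_frac: float = 0.05) -> FineEstimate:
    """Unwindowed selection over the whole grid (used when no coarse estimate
    or previous fused value is available): mean of the two strongest peaks."""
    idx, _ = _local_peaks(spec.energy, prominence_frac)
    if idx.size == 0:
        return FineEstimate(float(spec.f[np.argmax(spec.energy)]), 0, True)
    if idx.size == 1:
        return FineEstimate(float(spec.f[idx[0]]), 1, False)
    top_two = idx[np.argsort(spec.energy[idx])[-2:]]
    return FineEstimate(float(np.mean(spec.f[top_two])), int(idx.size), False)
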