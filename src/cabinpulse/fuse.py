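"""Sequential Kalman fusion of the coarse (f0) and fine (f1) estimates.

Both stages observe the same scalar heart-rate state, so each 5 s chunk
provides two noisy measurements.  Instead of stacking them into an augmented
observation, the standard Kalman update is applied twice in sequence --
first with f0 (noise R0), then with f1 (noise R1) -- which is algebraically
identical to the batch two-measurement update.  The default state model is
a scalar random walk in bpm (A = H = 1); the implementation is matrix-form
so richer dynamics remain possible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


def _as_matrix(v, n: int) -> np.ndarray:
    a = np.atleast_2d(np.asarray(v, dtype=float))
    if a.shape != (n, n):
        raise ValueError(f"expected {n}x{n} matrix, got {a.shape}")
    return a


@dataclass
class KalmanState:
    """Scalar-by-default Kalman state for heart-rate fusion (units: bpm)."""

    x: np.ndarray             # state estimate, shape (n,)
    P: np.ndarray             # covariance, (n, n)
    A: np.ndarray             # system matrix
    H: np.ndarray             # measurement row, (1, n)
    Q: np.ndarray             # process noise
    R0: float = 25.0          # coarse-measurement noise variance (bpm^2)
    R1: float = 9.0           # fine-measurement noise variance (bpm^2)
    k: int = 0                # chunk index

    @classmethod
    def scalar(
        cls,
        x0: float,
        P0: float = 100.0,
        Q: float = 0.5,
        R0: float = 25.0,
        R1: float = 9.0,
    ) -> "KalmanState":
        return cls(
            x=np.array([float(x0)]),
            P=np.array([[float(P0)]]),
            A=np.eye(1),
            H=np.ones((1, 1)),
            Q=np.array([[float(Q)]]),
            R0=R0,
            R1=R1,
        )

    def __post_init__(self) -> None:
        self.x = np.atleast_1d(np.asarray(self.x, dtype=float))
        n = self.x.size
        self.P = _as_matrix(self.P, n)
        self.A = _as_matrix(self.A, n)
        self.Q = _as_matrix(self.Q, n)
        self.H = np.atleast_2d(np.asarray(self.H, dtype=float)).reshape(1, n)
        if self.R0 <= 0 or self.R1 <= 0:
            raise ValueError("measurement noise variances must be positive")

    @property
    def hr(self) -> float:
        """Observed heart rate, H x."""
        return (self.H @ self.x).item()


def predict(state: KalmanState) -> KalmanState:
    """A-priori step: x = A x, P = A P A' + Q."""
    x = state.A @ state.x
    P = state.A @ state.P @ state.A.T + state.Q
    return replace(state, x=x, P=0.5 * (P + P.T))


def _scalar_update(
    x: np.ndarray, P: np.ndarray, H: np.ndarray, z: float, r: float,
    huber_delta: float | None = None,
):
    s = (H @ P @ H.T).item() + r
    K = (P @ H.T) / s                       # gain, (n, 1)
    nu = z - (H @ x).item()
    if huber_delta is not None and abs(nu) > huber_delta * np.sqrt(s):
        nu = nu * huber_delta * np.sqrt(s) / abs(nu)   # bounded influence
    x_new = x + (K * nu).ravel()
    P_new = (np.eye(x.size) - K @ H) @ P
    return x_new, 0.5 * (P_new + P_new.T)


def sequential_update(
    state: KalmanState,
    f0: float | None,
    f1: float | None,
    r1_inflation: float = 1.0,
    huber_delta: float | None = None,
) -> KalmanState:
    """Two scalar updates in order: f0 with R0, then f1 with R1*inflation.

    A missing (invalid) measurement skips its update; with both missing the
    chunk is prediction-only.  ``r1_inflation`` > 1 down-weights fallback
    fine estimates.  With ``huber_delta`` set, each innovation is clipped at
    delta standard deviations of its predicted spread, bounding the
    influence of outlier measurements without ever locking them out.
    """
    x, P = state.x, state.P
    if f0 is not None:
        x, P = _scalar_update(x, P, state.H, float(f0), state.R0, huber_delta)
    if f1 is not None:
        x, P = _scalar_update(x, P, state.H, float(f1), state.R1 * r1_inflation, huber_delta)
    return replace(state, x=x, P=P, k=state.k + 1)


def run_skf(
    pairs: Sequence[tuple[float | None, float | None, bool]],
    *,
    x0: float | None = None,
    P0: float = 100.0,
    Q: float = 0.5,
    R0: float = 25.0,
    R1: float = 9.0,
    r1_fallback_inflation: float = 4.0,
) -> pd.DataFrame:
    """Fuse per-chunk (f0, f1, fallback_flag) triples into one HR trace.

    Measurements are in bpm; ``None`` marks a missing/invalid estimate.  The
    state initialises at the first available f0 (else f1).  Returns one row
    per chunk with the a-posteriori estimate and covariance.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("need at least one chunk")
    if x0 is None:
        for f0, f1, _ in pairs:
            if f0 is not None:
                x0 = f0
                break
            if x0 is None and f1 is not None:
                x0 = f1
        if x0 is None:
            raise ValueError("no measurement available to initialise the state")

    state = KalmanState.scalar(x0, P0=P0, Q=Q, R0=R0, R1=R1)
    rows = []
    for k, (f0, f1, fallback) in enumerate(pairs):
        state = predict(state)
        infl = r1_fallback_inflation if fallback else 1.0
        state = sequential_update(state, f0, f1, r1_inflation=infl)
        rows.append(
            {
                "chunk_index": k,
                "f0_bpm": np.nan if f0 is None else f0,
                "f1_bpm": np.nan if f1 is None else f1,
                "hr_skf_bpm": state.hr,
                "P": float(state.P[0, 0]),
                "prediction_only": f0 is None and f1 is None,
            }
        )
    return pd.DataFrame(rows)
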