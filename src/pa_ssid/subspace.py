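"""Subspace (N4SID-style) state-space identification of a single output trace.

The algorithm builds a block Hankel matrix from the trace, projects the
future-output row space onto the past row space, selects the model order
from the singular-value spectrum of that projection, reconstructs the
extended observability matrix and state sequences, and solves a linear
least-squares problem for the system matrices (A, B, C).

The trace is treated as the response to a canonical unit impulse at its
onset, which is equivalent to the free response from the initial state B:
``y(k) = C A^k B``.  See :func:`impulse_response`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import scipy.linalg

from .signal import ONSET_THRESHOLD, PASignal

__all__ = [
    "HankelSplit",
    "SubspaceDecomposition",
    "StateSpaceModel",
    "IdentificationError",
    "build_hankel",
    "project_future_onto_past",
    "weighted_svd",
    "estimate_order",
    "observability_and_states",
    "solve_system_matrices",
    "identify",
    "impulse_response",
    "nrmse",
]

#: relative floor applied to singular values before taking log-gaps
SV_FLOOR = 1e-12


class IdentificationError(RuntimeError):
    """Raised when a stage of the subspace pipeline cannot proceed."""


@dataclass
class HankelSplit:
    """Past/future block Hankel split of a single-output trace.

    Entry (r, c) of the stacked ``[Yp; Yf]`` equals ``y[r + c]`` (0-based);
    each half has ``i`` rows and ``j = N - 2i + 1`` columns.
    """

    Yp: np.ndarray
    Yf: np.ndarray
    i: int
    j: int
    y: np.ndarray  # source trace, kept for the shifted split and Y_{i|i}


@dataclass
class SubspaceDecomposition:
    """Intermediate quantities of the subspace algorithm, kept for diagnostics."""

    Oi: np.ndarray
    U: np.ndarray
    singular_values: np.ndarray
    V: np.ndarray
    W1: Optional[np.ndarray] = None
    W2: Optional[np.ndarray] = None
    order_estimate: Optional[int] = None
    Gamma_i: Optional[np.ndarray] = None
    Xi: Optional[np.ndarray] = None
    Xi_plus: Optional[np.ndarray] = None


@dataclass
class StateSpaceModel:
    """State-space triplet (A, B, C) with sampling/domain bookkeeping.

    ``domain_tag`` is ``"discrete"`` (A advances one sample of ``ts``) or
    ``"continuous"`` (A is a rate matrix in 1/s).
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    ts: float
    domain_tag: str = "discrete"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.A = np.atleast_2d(np.asarray(self.A, dtype=float))
        self.B = np.asarray(self.B, dtype=float).reshape(-1, 1)
        self.C = np.asarray(self.C, dtype=float).reshape(1, -1)
        n = self.A.shape[0]
        if self.A.shape != (n, n):
            raise ValueError("A must be square")
        if self.B.shape != (n, 1) or self.C.shape != (1, n):
            raise ValueError("B, C dimensions inconsistent with A")
        if self.domain_tag not in ("discrete", "continuous"):
            raise ValueError(f"unknown domain_tag {self.domain_tag!r}")

    @property
    def order(self) -> int:
        return self.A.shape[0]

    def eigenvalues(self) -> np.ndarray:
        return np.linalg.eigvals(self.A)

    def is_stable(self) -> bool:
        lam = self.eigenvalues()
        if self.domain_tag == "discrete":
            return bool(np.all(np.abs(lam) < 1.0))
        return bool(np.all(lam.real < 0.0))


def build_hankel(y: Sequence[float], i: int) -> HankelSplit:
    """Split a trace into past/future block Hankel halves with ``i`` rows each."""
    y = np.asarray(y, dtype=float).ravel()
    if i < 1:
        raise ValueError("block half-size i must be >= 1")
    N = y.size
    if N < 2 * i + 1:
        raise ValueError(
            f"trace of length {N} too short for i={i}; need at least {2 * i + 1} samples"
        )
    j = N - 2 * i + 1
    H = scipy.linalg.hankel(y[: 2 * i], y[2 * i - 1 :])
    return HankelSplit(Yp=H[:i], Yf=H[i:], i=i, j=j, y=y)


def _row_projection(Yf: np.ndarray, Yp: np.ndarray) -> np.ndarray:
    # orthogonal projection of the rows of Yf onto rowspace(Yp) via least squares
    M, *_ = np.linalg.lstsq(Yp.T, Yf.T, rcond=None)
    return (Yp.T @ M).T


def project_future_onto_past(h: HankelSplit) -> np.ndarray:
    """Project the future outputs onto the past row space (output-only oblique
    projection); returns a matrix with the shape of ``Yf``."""
    return _row_projection(h.Yf, h.Yp)


def weighted_svd(
    Oi: np.ndarray,
    W1: Optional[np.ndarray] = None,
    W2: Optional[np.ndarray] = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """SVD of ``W1 @ Oi @ W2`` (identity weights when None), singular values
    sorted descending."""
    M = np.asarray(Oi, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("projection matrix contains non-finite entries")
    if W1 is not None:
        M = W1 @ M
    if W2 is not None:
        M = M @ W2
    U, s, Vt = np.linalg.svd(M, full_matrices=False)
    return U, s, Vt.T


def estimate_order(
    sigma: np.ndarray,
    max_order: int = 10,
    override: Optional[int] = None,
) -> int:
    """Model order from the largest log10 gap between consecutive singular values."""
    if override is not None:
        if override < 1:
            raise ValueError("order override must be >= 1")
        return int(override)
    s = np.asarray(sigma, dtype=float).ravel()
    if s.size < 2:
        raise ValueError("need at least 2 singular values to locate a gap")
    if s[0] <= 0:
        raise IdentificationError("signal indistinguishable from zero (all singular values ~ 0)")
    eps = SV_FLOOR * s[0]
    s = np.maximum(s, eps)
    kmax = min(max_order, s.size - 1)
    gaps = np.log10(s[:kmax] / s[1 : kmax + 1])
    return int(np.argmax(gaps)) + 1


def observability_and_states(
    dec: SubspaceDecomposition, h: HankelSplit, n_hat: int
) -> SubspaceDecomposition:
    """Build the extended observability matrix from the leading ``n_hat``
    singular triplets and estimate the aligned state sequences.

    ``Xi`` holds states at times ``i .. i+j-1``; ``Xi_plus`` the states one
    sample later, obtained from the shifted past/future split (first future
    row moved into the past block).
    """
    if n_hat < 1:
        raise ValueError("order must be >= 1")
    if n_hat > dec.singular_values.size:
        raise IdentificationError(
            f"requested order {n_hat} exceeds available rank {dec.singular_values.size}"
        )
    U1 = dec.U[:, :n_hat]
    sqrt_s = np.sqrt(dec.singular_values[:n_hat])
    Gamma_i = U1 * sqrt_s  # W1 = identity
    if dec.W1 is not None:
        Gamma_i = np.linalg.solve(dec.W1, Gamma_i)

    Xi = np.linalg.pinv(Gamma_i) @ dec.Oi

    # shifted split: Yp+ gains the first future row, Yf- loses it
    i = h.i
    H = np.vstack([h.Yp, h.Yf])
    Yp_plus = H[: i + 1]
    Yf_minus = H[i + 1 :]
    O_im1 = _row_projection(Yf_minus, Yp_plus)
    Gamma_im1 = Gamma_i[:-1]
    Xi_plus = np.linalg.pinv(Gamma_im1) @ O_im1

    dec.order_estimate = n_hat
    dec.Gamma_i = Gamma_i
    dec.Xi = Xi
    dec.Xi_plus = Xi_plus
    return dec


def _fit_initial_state(A: np.ndarray, C: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Least-squares initial state for the free response y(k) = C A^k x0."""
    n = A.shape[0]
    N = y.size
    G = np.empty((N, n))
    row = C.reshape(1, n).copy()
    for k in range(N):
        G[k] = row
        row = row @ A
    x0, *_ = np.linalg.lstsq(G, y, rcond=None)
    return x0.reshape(n, 1)


def solve_system_matrices(
    dec: SubspaceDecomposition,
    h: HankelSplit,
    ts: float,
) -> StateSpaceModel:
    """Solve the stacked least-squares problem for (A, C) from the aligned state
    sequences and the one-row output Hankel block, then recover B as the
    least-squares initial-state fit to the measured response.

    The canonical excitation is a unit impulse at the onset sample; its input
    Hankel row over the state-sequence columns is identically zero, so the
    input column of the regression drops out and B is identified separately.
    """
    if dec.Xi is None or dec.Xi_plus is None:
        raise IdentificationError("state sequences not available; run observability_and_states")
    Xi, Xi_plus = dec.Xi, dec.Xi_plus
    j = min(Xi.shape[1], Xi_plus.shape[1])
    Xi, Xi_plus = Xi[:, :j], Xi_plus[:, :j]
    n = Xi.shape[0]
    y = h.y
    Yii = y[h.i : h.i + j].reshape(1, j)

    if np.allclose(y, 0):
        raise IdentificationError("degenerate zero signal")

    lhs = np.vstack([Xi_plus, Yii])  # (n+1) x j
    rank = np.linalg.matrix_rank(Xi)
    if rank < n:
        raise IdentificationError(
            f"state-sequence regressor is rank deficient ({rank} < {n}); "
            "try a larger Hankel half-size i or stronger decimation"
        )
    sol, *_ = np.linalg.lstsq(Xi.T, lhs.T, rcond=None)
    AC = sol.T
    A = AC[:n, :]
    C = AC[n:, :]
    B = _fit_initial_state(A, C, y)
    model = StateSpaceModel(A=A, B=B, C=C, ts=ts, domain_tag="discrete")
    model.meta["stable"] = model.is_stable()
    return model


def identify(
    signal: PASignal,
    i: int = 20,
    max_order: int = 10,
    order_override: Optional[int] = None,
    decimate_to: Optional[float] = 1e8,
    onset_threshold: float = ONSET_THRESHOLD,
) -> tuple[StateSpaceModel, SubspaceDecomposition]:
    """Full identification pipeline for one trace.

    Stages: onset alignment, optional stride decimation to ``decimate_to``
    samples/s, Hankel split, projection, SVD (identity weighting), order
    selection, state reconstruction, and the system-matrix solve.
    Diagnostics (singular values, order, NRMSE of the refit) are stored in
    ``model.meta``.

    Decimation keeps every ``factor``-th sample starting at the onset: for a
    heavily oversampled exponential-modal trace this maps the dynamics
    exactly (``A -> A^factor``, B and C unchanged), whereas a low-pass
    decimator would smear the onset into spurious extra modes.  White
    measurement noise stays white under striding, so no anti-alias filter is
    applied.
    """
    work = signal.aligned(onset_threshold)
    if decimate_to is not None and 1.0 / work.ts > decimate_to * 1.5:
        factor = int(round(1.0 / (work.ts * decimate_to)))
        work = PASignal(
            samples=work.samples[::factor].copy(),
            ts=work.ts * factor,
            t0=work.t0,
            label=work.label,
        )

    try:
        h = build_hankel(work.samples, i)
        Oi = project_future_onto_past(h)
        U, s, V = weighted_svd(Oi)
        dec = SubspaceDecomposition(Oi=Oi, U=U, singular_values=s, V=V)
        n_hat = estimate_order(s, max_order=max_order, override=order_override)
        dec = observability_and_states(dec, h, n_hat)
        model = solve_system_matrices(dec, h, work.ts)
    except (ValueError, IdentificationError) as exc:
        raise IdentificationError(f"identification failed: {exc}") from exc

    model.meta["onset_t"] = work.t0
    model.meta["singular_values"] = s
    model.meta["nrmse"] = nrmse(work.samples, impulse_response(model, len(work)))
    return model, dec


def impulse_response(model: StateSpaceModel, n_points: int) -> np.ndarray:
    """Response ``y(k) = C A^k B`` for k = 0..n_points-1, by state recursion."""
    if model.domain_tag != "discrete":
        raise ValueError("impulse_response requires a discrete-time model")
    x = model.B.copy()
    y = np.empty(n_points)
    A, C = model.A, model.C
    for k in range(n_points):
        y[k] = float((C @ x)[0, 0])
        x = A @ x
    return y


def nrmse(y_meas: Sequence[float], y_model: Sequence[float]) -> float:
    """Normalized RMS fit score in percent: 100 means exact, 0 means no better
    than the signal mean."""
    y = np.asarray(y_meas, dtype=float).ravel()
    yh = np.asarray(y_model, dtype=float).ravel()
    if y.size != yh.size:
        raise ValueError("sequences must have equal length")
    if y.size < 2:
        raise ValueError("need at least 2 samples")
    denom = np.linalg.norm(y - y.mean())
    if denom == 0:
        raise ValueError("constant reference signal: NRMSE undefined")
    return float((1.0 - np.linalg.norm(y - yh) / denom) * 100.0)
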