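"""Continuous-time conversion and modal-parameter extraction.

A fitted second-order discrete model is converted to continuous time via the
matrix logarithm (the ZOH relation ``A = exp(A' ts)``) and rotated into the
real modal form

    A_bar = [[-1/alpha,  omega_n],
             [-omega_n, -1/alpha]],      C_bar = [c1, c2],

whose free response from the canonical initial state ``B_bar = [1, 0]^T`` is
the damped sinusoid ``exp(-t/alpha) * (c1 cos(omega_n t) - c2 sin(omega_n t))``.

Canonicalization
----------------
The modal form leaves a rotation/scaling freedom (any transform commuting
with A_bar).  It is fixed by requiring the transformed initial-state vector
to be exactly ``[1, 0]^T``, absorbing the scale into C_bar.  After this the
transfer behaviour is unchanged and (c1, c2) are unique, so they can be used
as reproducible features.  Note alpha is a time constant in seconds (the
modal diagonal is -1/alpha).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Optional

import numpy as np
import scipy.linalg

from .signal import PASignal
from .subspace import IdentificationError, StateSpaceModel, identify

__all__ = [
    "ModalParameters",
    "ModalExtractionError",
    "FeatureVector",
    "to_continuous",
    "to_modal",
    "extract_ss_features",
]


class ModalExtractionError(RuntimeError):
    """Raised when a model admits no underdamped modal form."""


@dataclass
class ModalParameters:
    """The four-parameter feature set {alpha, omega_n, c1, c2}.

    alpha : decay time constant in seconds (> 0); the response envelope
        falls by 1/e over alpha.
    omega_n : natural angular frequency in rad/s (> 0).
    c1, c2 : modal mixing amplitudes (c1 = response value at t = 0+).
    """

    alpha: float
    omega_n: float
    c1: float
    c2: float

    def __post_init__(self) -> None:
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not (self.omega_n > 0):
            raise ValueError(f"omega_n must be positive, got {self.omega_n}")

    def continuous_matrix(self) -> np.ndarray:
        """The implied 2x2 modal rate matrix (eigenvalues -1/alpha +/- i omega_n)."""
        return np.array(
            [[-1.0 / self.alpha, self.omega_n], [-self.omega_n, -1.0 / self.alpha]]
        )

    def as_dict(self) -> dict[str, float]:
        return {
            "alpha": self.alpha,
            "omega_n": self.omega_n,
            "c1": self.c1,
            "c2": self.c2,
        }


@dataclass
class FeatureVector:
    """Named features for one sample, tagged with their family (TD/FD/ARMA/SS)."""

    sample_id: str
    label: str
    family: str
    values: dict[str, float]
    meta: dict[str, Any] = field(default_factory=dict)


def to_continuous(model: StateSpaceModel) -> StateSpaceModel:
    """Discrete-to-continuous conversion via the principal matrix logarithm.

    ``A' = logm(A)/ts`` so that ``exp(A' ts) = A``.  B and C are carried over
    unchanged: B is the canonical initial state (free-response convention),
    which maps between domains as a state vector, and C reads the state in
    both domains.
    """
    if model.domain_tag != "discrete":
        raise ValueError("model is already continuous")
    lam = model.eigenvalues()
    if np.any(np.abs(lam) == 0) or np.any((lam.imag == 0) & (lam.real <= 0)):
        raise ModalExtractionError(
            "eigenvalue on the closed negative real axis (or zero): "
            "no principal matrix logarithm, ZOH conversion undefined"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # logm warns about imaginary residue noise
        Ac = scipy.linalg.logm(model.A) / model.ts
    Ac = np.real_if_close(Ac, tol=1e6)
    if np.iscomplexobj(Ac):
        Ac = Ac.real
    return StateSpaceModel(
        A=Ac,
        B=model.B.copy(),
        C=model.C.copy(),
        ts=model.ts,
        domain_tag="continuous",
        meta=dict(model.meta),
    )


def to_modal(model: StateSpaceModel) -> tuple[ModalParameters, StateSpaceModel]:
    """Rotate a continuous second-order model into canonical modal form.

    Requires a complex-conjugate eigenvalue pair ``sigma +/- i omega`` with
    ``sigma < 0`` and ``omega != 0`` (underdamped, decaying).  Returns the
    modal parameters and the canonical modal model.
    """
    if model.domain_tag != "continuous":
        raise ValueError("to_modal expects a continuous-time model")
    if model.order != 2:
        raise ModalExtractionError(f"modal form requires order 2, got {model.order}")
    lam, vecs = np.linalg.eig(model.A)
    if np.all(np.abs(lam.imag) <= 1e-12 * np.max(np.abs(lam))):
        raise ModalExtractionError(
            "real eigenvalues (overdamped fit): no underdamped modal form"
        )
    k = int(np.argmax(lam.imag))  # eigenvalue with omega > 0
    sigma, omega = lam[k].real, lam[k].imag
    if sigma >= 0:
        raise ModalExtractionError(f"non-decaying mode (Re lambda = {sigma:g} >= 0)")
    alpha = -1.0 / sigma
    omega_n = abs(omega)

    v = vecs[:, k]
    M = np.column_stack([v.real, v.imag])  # A M = M A_bar
    if abs(np.linalg.det(M)) < 1e-300:
        raise ModalExtractionError("degenerate eigenvector basis")
    Minv = np.linalg.inv(M)
    B_tilde = (Minv @ model.B).ravel()
    C_tilde = (model.C @ M).ravel()

    # fix the remaining rotation/scaling freedom: S B_tilde = [1, 0]^T with
    # S = aI + bJ in the commutant of A_bar
    b1, b2 = B_tilde
    r2 = b1 * b1 + b2 * b2
    if r2 < 1e-300:
        raise ModalExtractionError("zero initial-state component: canonical form undefined")
    S = np.array([[b1, b2], [-b2, b1]]) / r2
    C_bar = C_tilde @ np.linalg.inv(S)

    params = ModalParameters(
        alpha=alpha, omega_n=omega_n, c1=float(C_bar[0]), c2=float(C_bar[1])
    )
    modal_model = StateSpaceModel(
        A=params.continuous_matrix(),
        B=np.array([[1.0], [0.0]]),
        C=C_bar.reshape(1, 2),
        ts=model.ts,
        domain_tag="continuous",
        meta=dict(model.meta),
    )
    return params, modal_model


def extract_ss_features(
    signal: PASignal,
    sample_id: str = "",
    i: int = 20,
    max_order: int = 10,
    order_override: Optional[int] = None,
    decimate_to: Optional[float] = 1e8,
) -> FeatureVector:
    """Identify, convert, and canonicalize one trace into the SS feature family.

    Raises :class:`ModalExtractionError` for overdamped fits (the caller
    excludes the sample with a warning) and :class:`IdentificationError`
    when identification itself fails.
    """
    model, dec = identify(
        signal,
        i=i,
        max_order=max_order,
        order_override=order_override,
        decimate_to=decimate_to,
    )
    params, _ = to_modal(to_continuous(model))
    return FeatureVector(
        sample_id=sample_id,
        label=signal.label,
        family="SS",
        values=params.as_dict(),
        meta={
            "nrmse": model.meta.get("nrmse"),
            "order": model.order,
            "stable": model.meta.get("stable"),
        },
    )
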