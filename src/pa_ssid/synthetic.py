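"""Synthetic five-class photoacoustic trace generator.

Real blood measurements are not deposited anywhere, so every downstream
stage is exercised on simulated traces that have the statistical structure
the identification step assumes: an underdamped second-order impulse
response (exponentially damped sinusoid) arriving at a class-dependent
time, plus additive white Gaussian noise.

The per-class parameter means are invented plumbing: the source experiment
reports only the natural-frequency band (2.5-3.5e7 rad/s), the class sizes
(10, 10, 4, 4, 7), the healthy arrival times (6.56 / 6.59 us), the ordering
of the second modal amplitude across conditions, and that the leukemia
class is the most variable.  The defaults below respect those constraints
and are fully overridable via :class:`SimulationConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .modal import ModalParameters
from .signal import PASignal

__all__ = [
    "ClassParameterSpec",
    "SimulationConfig",
    "CLASS_LABELS",
    "default_class_table",
    "modal_impulse_response",
    "simulate_signal",
    "simulate_dataset",
]

CLASS_LABELS = ("HF", "HM", "A1", "A2", "L")


@dataclass
class ClassParameterSpec:
    """Gaussian parameter distribution for one blood class."""

    label: str
    alpha_mean: float  # s
    alpha_sd: float
    omega_mean: float  # rad/s
    omega_sd: float
    c1_mean: float
    c1_sd: float
    c2_mean: float
    c2_sd: float
    arrival_mean: float  # s (absolute time)
    arrival_sd: float
    n_samples: int

    def __post_init__(self) -> None:
        if self.label not in CLASS_LABELS:
            raise ValueError(f"unknown class label {self.label!r}")
        if not (self.alpha_mean > 0 and self.omega_mean > 0):
            raise ValueError("alpha_mean and omega_mean must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        for name in ("alpha_sd", "omega_sd", "c1_sd", "c2_sd", "arrival_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SimulationConfig:
    """Window geometry, noise level, and class table for one simulated dataset."""

    classes: list[ClassParameterSpec] = field(default_factory=lambda: default_class_table())
    ts: float = 10e-9  # decimated working rate; the hardware rate is 0.2 ns
    duration: float = 1.2e-6
    t0: float = 6.5e-6  # window start (the experiment segments 6.5-7.7 us)
    snr_db: Union[float, str] = "none"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 4:
            raise ValueError("duration/ts must give at least 4 samples")

    @property
    def n_points(self) -> int:
        # round half up, so "~1.2 us" windows are stable across float noise
        return int(np.floor(self.duration / self.ts + 0.5))

    @property
    def noise_free(self) -> bool:
        return isinstance(self.snr_db, str) and self.snr_db == "none"


def default_class_table() -> list[ClassParameterSpec]:
    """Shipped five-class table (HF, HM, A1, A2, L).

    Class sizes 10/10/4/4/7; healthy arrivals 6.56 and 6.59 us; all
    omega_n means inside 2.5-3.5e7 rad/s; c2 ordered healthy > anemia >
    leukemia; leukemia has the largest spreads.  Numeric means are
    otherwise invented defaults (see module docstring).
    """
    us = 1e-6
    return [
        ClassParameterSpec("HF", 5.1e-7, 0.30e-7, 3.05e7, 0.040e7, 1.00, 0.05,
                           0.95, 0.050, 6.56 * us, 0.010 * us, 10),
        ClassParameterSpec("HM", 4.7e-7, 0.30e-7, 3.25e7, 0.040e7, 0.99, 0.05,
                           0.92, 0.050, 6.59 * us, 0.010 * us, 10),
        ClassParameterSpec("A1", 3.9e-7, 0.30e-7, 2.65e7, 0.045e7, 0.60, 0.08,
                           0.57, 0.070, 6.64 * us, 0.018 * us, 4),
        ClassParameterSpec("A2", 3.7e-7, 0.30e-7, 2.85e7, 0.045e7, 0.56, 0.08,
                           0.50, 0.070, 6.65 * us, 0.018 * us, 4),
        ClassParameterSpec("L", 3.1e-7, 0.45e-7, 3.40e7, 0.090e7, 0.44, 0.10,
                           0.30, 0.090, 6.67 * us, 0.025 * us, 7),
    ]


def modal_impulse_response(
    params: ModalParameters, ts: float, n_points: int
) -> np.ndarray:
    """Sampled free response of the canonical modal pair:

    ``y(k) = exp(-k ts / alpha) * (c1 cos(omega_n k ts) - c2 sin(omega_n k ts))``

    i.e. ``C_bar exp(A_bar k ts) B_bar`` with the canonical ``B_bar = [1, 0]^T``
    and the modal matrix carrying ``+omega_n`` in the (1, 2) slot.  This is
    exactly the convention :func:`pa_ssid.modal.to_modal` canonicalizes to, so
    the round trip generator -> identify -> modal parameters is consistent.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if not (ts > 0):
        raise ValueError("ts must be positive")
    t = ts * np.arange(n_points)
    env = np.exp(-t / params.alpha)
    return env * (params.c1 * np.cos(params.omega_n * t)
                  - params.c2 * np.sin(params.omega_n * t))


def simulate_signal(
    params: ModalParameters,
    arrival: float,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
    label: str = "unlabeled",
) -> PASignal:
    """One trace: zeros before the arrival index, the modal response after it,
    plus white Gaussian noise scaled to ``snr_db`` over the post-arrival
    segment (no noise when ``snr_db == "none"``)."""
    offset = arrival - config.t0
    if not (0 <= offset < config.duration):
        raise ValueError(
            f"arrival {arrival:g} s outside the window "
            f"[{config.t0:g}, {config.t0 + config.duration:g}) s"
        )
    n = config.n_points
    k_arr = int(np.floor(offset / config.ts + 0.5))
    k_arr = min(k_arr, n - 1)
    clean = np.zeros(n)
    clean[k_arr:] = modal_impulse_response(params, config.ts, n - k_arr)

    samples = clean
    if not config.noise_free:
        if rng is None:
            rng = np.random.default_rng(config.seed)
        p_sig = float(np.mean(clean[k_arr:] ** 2))
        sigma = np.sqrt(p_sig * 10.0 ** (-float(config.snr_db) / 10.0))
        samples = clean + rng.normal(0.0, sigma, size=n)

    return PASignal(
        samples=samples,
        ts=config.ts,
        t0=config.t0,
        label=label,
        meta={"arrival": arrival, "true_params": params.as_dict()},
    )


def _draw_positive(rng: np.random.Generator, mean: float, sd: float) -> float:
    # truncated Gaussian by rejection: physical parameters must stay positive
    if sd == 0:
        return mean
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x > 0:
            return x
    raise RuntimeError("truncated-Gaussian draw failed (mean/sd badly scaled)")


def draw_class_parameters(
    spec: ClassParameterSpec, config: SimulationConfig, rng: np.random.Generator
) -> tuple[ModalParameters, float]:
    """One (parameters, arrival) draw from a class distribution."""
    alpha = _draw_positive(rng, spec.alpha_mean, spec.alpha_sd)
    omega = _draw_positive(rng, spec.omega_mean, spec.omega_sd)
    c1 = rng.normal(spec.c1_mean, spec.c1_sd)
    c2 = rng.normal(spec.c2_mean, spec.c2_sd)
    lo, hi = config.t0, config.t0 + config.duration
    arrival = spec.arrival_mean
    if spec.arrival_sd > 0:
        for _ in range(1000):
            arrival = rng.normal(spec.arrival_mean, spec.arrival_sd)
            if lo <= arrival < hi:
                break
        else:
            raise RuntimeError("arrival draw never landed inside the window")
    return ModalParameters(alpha, omega, c1, c2), arrival


def simulate_dataset(
    config: SimulationConfig,
    n_samples_override: Optional[Sequence[int]] = None,
) -> list[PASignal]:
    """Labeled dataset: ``n_samples`` draws per class spec, simulated in class
    order.  Reproducible from ``config.seed``."""
    if not config.classes:
        raise ValueError("class list is empty")
    rng = np.random.default_rng(config.seed)
    specs = list(config.classes)
    if n_samples_override is not None:
        if len(n_samples_override) != len(specs):
            raise ValueError("n_samples_override length mismatch")
        specs = [replace(s, n_samples=int(n)) for s, n in zip(specs, n_samples_override)]
    signals: list[PASignal] = []
    for spec in specs:
        for _ in range(spec.n_samples):
            params, arrival = draw_class_parameters(spec, config, rng)
            signals.append(
                simulate_signal(params, arrival, config, rng=rng, label=spec.label)
            )
    return signals
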