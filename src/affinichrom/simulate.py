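"""Synthetic chromatogram generator with known binding ground truth.

Emulates the data structure of an injection-amount-dependent binding
study on an immobilized-receptor column: a saturable (Langmuir-type)
pool of n_a binding sites with association constant K_A, so the
capacity factor falls as the injected amount n_b rises; tailing
(exponentially modified Gaussian) detector peaks; multiplicative
Gaussian noise on retention times and additive white noise on the
detector signal. Every generated dataset carries its ground truth for
recovery scoring.

The apparent capacity factor is the exact algebraic inversion of the
linearized overload model: substituting x = k'V_m and y = k'n_b/(1+k')
into y = n_a - x/K_A gives the quadratic

    V_m k'^2 + (V_m + n_b K_A - n_a K_A) k' - n_a K_A = 0

whose unique positive root is the simulated k'. At n_b -> 0 it reduces
to the linear-chromatography limit k' = K_A n_a / V_m, and it decreases
strictly and continuously as n_b grows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy import optimize, stats

from .chromatogram import Chromatogram
from .column import ColumnSystem
from .errors import ValidationError
from . import published

__all__ = [
    "SimulationTruth",
    "apparent_k",
    "render_peak",
    "generate_series",
    "generate_void_marker",
    "default_truth",
]

DEFAULT_DT_MIN = 0.002


@dataclass(frozen=True)
class SimulationTruth:
    """Ground truth and nuisance parameters of one synthetic study.

    ``K_A`` in L/mol, ``n_a`` in mol; peak shape is an exponentially
    modified Gaussian with Gaussian width ``sigma`` and exponential
    tail constant ``tau`` (minutes; tau > 0 gives asymmetry > 1).
    ``height_scale`` converts moles injected to apex height (signal
    units per mol). ``rel_sd_tr`` is the relative SD of multiplicative
    retention-time noise; ``detector_sd`` the SD of additive white
    detector noise.
    """

    K_A: float
    n_a: float
    column: ColumnSystem
    sigma: float = 0.05
    tau: float = 0.15
    baseline: float = 0.0
    height_scale: float = 1.0e10
    rel_sd_tr: float = 0.0
    detector_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.K_A <= 0 or self.n_a <= 0:
            raise ValidationError("K_A and n_a must be positive")
        if self.sigma <= 0 or self.tau < 0:
            raise ValidationError("sigma must be > 0 and tau >= 0")
        if self.rel_sd_tr < 0 or self.detector_sd < 0:
            raise ValidationError("noise SDs must be non-negative")


def default_truth(seed: int = 0, **overrides) -> SimulationTruth:
    """Study-condition defaults: rosmarinic-acid-like binding parameters
    on a column with t0 = 0.298 min at 0.6 mL/min."""
    params = dict(
        K_A=published.REPORTED_K_A["rosmarinic_acid"],
        n_a=published.REPORTED_N_A["rosmarinic_acid"],
        column=ColumnSystem(
            t0=published.VOID_TIME_MIN, flow_rate=published.BINDING_FLOW_ML_MIN
        ),
        seed=seed,
    )
    params.update(overrides)
    return SimulationTruth(**params)


def apparent_k(truth: SimulationTruth, n_b):
    """Capacity factor at injected amount ``n_b`` (mol), scalar or array.

    Unique positive root of the overload quadratic; strictly decreasing
    in n_b, with the n_b = 0 limit K_A * n_a / V_m.
    """
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_b < 0):
        raise ValidationError("n_b must be non-negative")
    v_m = truth.column.void_volume
    a = v_m
    b = v_m + (n_b - truth.n_a) * truth.K_A
    c = -truth.n_a * truth.K_A
    # c < 0 guarantees one positive and one negative real root; pick the
    # positive one with the cancellation-free branch of the formula
    disc = np.sqrt(b * b - 4.0 * a * c)
    k = np.where(b <= 0, (-b + disc) / (2.0 * a), 2.0 * c / (-b - disc))
    return float(k) if k.ndim == 0 else k


@lru_cache(maxsize=64)
def _emg_mode_offset(sigma: float, tau: float) -> float:
    """Mode of the EMG with Gaussian mean 0, width sigma, tail tau."""
    if tau == 0:
        return 0.0
    K = tau / sigma
    res = optimize.minimize_scalar(
        lambda t: -stats.exponnorm.pdf(t, K, loc=0.0, scale=sigma),
        bounds=(0.0, tau + 3.0 * sigma),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(res.x)


def render_peak(
    k: float,
    truth: SimulationTruth,
    n_b: float = 1.0e-8,
    duration: float | None = None,
    dt: float = DEFAULT_DT_MIN,
    rng: np.random.Generator | None = None,
    meta: dict | None = None,
) -> Chromatogram:
    """Render one injection as a chromatogram.

    An exponentially modified Gaussian is positioned so its *mode* falls
    at t_R = t0 * (1 + k'); apex height is n_b * height_scale on top of
    the configured baseline. With tau = 0 the shape degenerates to a
    symmetric Gaussian. Detector noise is added when ``rng`` is given
    and truth.detector_sd > 0.
    """
    if dt <= 0:
        raise ValidationError("dt must be positive")
    t_r = truth.column.t0 * (1.0 + k)
    span = 5.0 * (truth.sigma + truth.tau)
    if duration is None:
        duration = t_r + 2.0 * span
    elif duration < t_r + span:
        raise ValidationError(
            f"duration {duration} min too short: needs t_R + 5*(sigma+tau) "
            f"= {t_r + span:.3f} min"
        )
    time = np.arange(0.0, duration + 0.5 * dt, dt)
    amplitude = n_b * truth.height_scale
    if truth.tau == 0:
        shape = np.exp(-0.5 * ((time - t_r) / truth.sigma) ** 2)
    else:
        K = truth.tau / truth.sigma
        mu = t_r - _emg_mode_offset(truth.sigma, truth.tau)
        pdf = stats.exponnorm.pdf(time, K, loc=mu, scale=truth.sigma)
        shape = pdf / stats.exponnorm.pdf(t_r, K, loc=mu, scale=truth.sigma)
    signal = truth.baseline + amplitude * shape
    if rng is not None and truth.detector_sd > 0:
        signal = signal + rng.normal(0.0, truth.detector_sd, size=signal.size)
    return Chromatogram(time=time, signal=signal, meta=dict(meta or {}))


def generate_void_marker(
    truth: SimulationTruth, duration: float = 1.0, dt: float = DEFAULT_DT_MIN
) -> Chromatogram:
    """Narrow symmetric peak at the void time (non-retained marker)."""
    t0 = truth.column.t0
    time = np.arange(0.0, duration + 0.5 * dt, dt)
    signal = truth.baseline + 100.0 * np.exp(-0.5 * ((time - t0) / 0.01) ** 2)
    return Chromatogram(time=time, signal=signal, meta={"analyte": "void_marker"})


def generate_series(
    truth: SimulationTruth,
    concentrations,
    injection_volume: float = published.INJECTION_VOLUME_L,
    *,
    with_traces: bool = False,
    n_replicates: int = 1,
    dt: float = DEFAULT_DT_MIN,
    analyte: str = "synthetic",
):
    """Generate a full concentration series with known truth.

    For each concentration c: n_b = c * V_inj, the true capacity factor
    comes from :func:`apparent_k`, and each of ``n_replicates``
    replicate injections observes t_R = t0 * (1 + k') * (1 + eps) with
    eps ~ Normal(0, rel_sd_tr). Replicates are averaged at the k' level,
    giving one point per concentration. Identical seeds produce
    bit-identical output.

    Returns (series, traces, truth); ``traces`` is empty unless
    ``with_traces``.
    """
    from .binding import Injection, InjectionSeries  # avoid import cycle

    concs = [float(c) for c in concentrations]
    if not concs or any(c <= 0 for c in concs):
        raise ValidationError("concentrations must be non-empty and positive")
    if len(set(concs)) != len(concs):
        raise ValidationError("concentrations must be pairwise distinct")
    rng = np.random.default_rng(truth.seed)
    t0 = truth.column.t0
    injections = []
    traces = []
    for c in concs:
        n_b = c * injection_volume
        k_true = apparent_k(truth, n_b)
        k_reps = []
        for _ in range(n_replicates):
            eps = rng.normal(0.0, truth.rel_sd_tr) if truth.rel_sd_tr > 0 else 0.0
            t_r_rep = t0 * (1.0 + k_true) * (1.0 + eps)
            k_reps.append((t_r_rep - t0) / t0)
        k_obs = float(np.mean(k_reps))
        t_r_obs = t0 * (1.0 + k_obs)
        injections.append(
            Injection(concentration=c, volume=injection_volume, t_r=t_r_obs, k=k_obs)
        )
        if with_traces:
            traces.append(
                render_peak(
                    k_obs,
                    truth,
                    n_b=n_b,
                    dt=dt,
                    rng=rng,
                    meta={
                        "analyte": analyte,
                        "concentration": c,
                        "injection_volume": injection_volume,
                        "flow_rate": truth.column.flow_rate,
                    },
                )
            )
    series = InjectionSeries(analyte=analyte, column=truth.column, injections=injections)
    return series, traces, truth
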