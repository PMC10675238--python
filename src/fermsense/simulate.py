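"""Kinetic batch-fermentation simulator.

Generates multi-batch datasets with the statistical structure a local
soft-sensor ensemble assumes: multi-stage nonlinear kinetics,
batch-to-batch parameter variation, and environmental channels that
co-vary with the biochemical state.

State model (per batch, fixed-step RK4):

    dX/dt = mu_max * X * (1 - X/X_max) * S/(K_s + S)       biomass
    dS/dt = -(1/Y_xs) * dX/dt - m_s * X, floored at 0      substrate
    dP/dt = alpha * dX/dt + beta * X                       product
                                                           (Luedeking-Piret)

Logistic growth with Monod substrate limitation gives a lag/exponential
phase, a transition, and a stationary phase once the substrate runs
out; the product keeps accumulating through the non-growth-associated
term, so the three targets have genuinely different local dynamics in
the two regimes -- the structure that makes local models worthwhile.

Observed environmental channels (temperature, pH, dissolved oxygen,
agitation) are smooth monotone functions of the state plus AR(1)
autocorrelated sensor noise; all observed columns additionally carry
white measurement noise scaled to each channel's dynamic range.

The target columns (X, S, P) model *offline assays*: each observation
reads the true trajectory at a jittered sampling time t + eps,
eps ~ N(0, sample_time_jitter_sd).  Because the error this induces is
proportional to the local rate of change, target noise is strongly
phase-dependent -- large during exponential growth, nearly zero in the
stationary phase -- which is the realistic heteroscedastic structure
that makes one global regression with a single noise variance a poor
description of the whole batch.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .datamodel import BatchDataset, ColumnSchema

__all__ = [
    "KineticParams",
    "simulate_batch",
    "generate_frame",
    "generate_dataset",
    "AUX_CHANNELS",
    "TARGETS",
]

AUX_CHANNELS = ("temperature", "pH", "dissolved_oxygen", "agitation")
TARGETS = ("X", "S", "P")


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and noise parameters of one nominal fermentation.

    Units: rates in 1/h, concentrations in g/L, P in relative activity
    units.  ``noise_sd`` is the white measurement noise as a fraction of
    each observed channel's dynamic range; ``batch_cv`` the lognormal
    coefficient of variation applied to the kinetic parameters per batch.
    """

    mu_max: float = 0.6       # specific growth rate (1/h)
    X_max: float = 10.0       # carrying capacity (g/L)
    Y_xs: float = 0.5         # biomass yield on substrate (g/g)
    m_s: float = 0.02         # maintenance coefficient (1/h)
    alpha: float = 2.0        # growth-associated product coefficient
    beta: float = 0.05        # non-growth-associated product rate (1/h)
    X0: float = 0.2           # inoculum biomass (g/L)
    S0: float = 18.0          # initial substrate (g/L)
    K_s: float = 0.05         # Monod half-saturation (g/L)
    noise_sd: float = 0.02    # env-channel sensor noise (fraction of range)
    assay_cv: tuple[float, float, float] = (0.05, 0.03, 0.08)  # CV of X, S, P assays
    batch_cv: float = 0.08    # inter-batch parameter jitter (CV)
    sample_time_jitter_sd: float = 0.25   # offline-assay timing error (h)

    def __post_init__(self) -> None:
        for name in ("mu_max", "X_max", "Y_xs", "alpha", "X0", "S0", "K_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("m_s", "beta", "noise_sd", "sample_time_jitter_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if len(self.assay_cv) != 3 or any(c < 0 for c in self.assay_cv):
            raise ValueError("assay_cv must be three non-negative CVs (X, S, P)")
        if not 0.0 <= self.batch_cv <= 0.5:
            raise ValueError("batch_cv must lie in [0, 0.5]")


def _derivs(state: np.ndarray, p: KineticParams) -> np.ndarray:
    X, S, P = state
    S = max(S, 0.0)
    dX = p.mu_max * X * (1.0 - X / p.X_max) * S / (p.K_s + S)
    dS = -dX / p.Y_xs - p.m_s * X
    dP = p.alpha * dX + p.beta * X
    return np.array([dX, dS, dP])


def _integrate(
    p: KineticParams, n_points: int, dt: float, substeps: int = 4
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fixed-step RK4.

    Returns (sampled states (n_points, 3), fine time grid, fine states)
    -- the fine grid is kept so jittered sampling times can be
    interpolated accurately.
    """
    n_fine = (n_points - 1) * substeps + 1
    fine = np.empty((n_fine, 3))
    state = np.array([p.X0, p.S0, 0.0])
    fine[0] = state
    h = dt / substeps
    for i in range(1, n_fine):
        k1 = _derivs(state, p)
        k2 = _derivs(state + 0.5 * h * k1, p)
        k3 = _derivs(state + 0.5 * h * k2, p)
        k4 = _derivs(state + h * k3, p)
        state = state + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        state[1] = max(state[1], 0.0)   # substrate floor
        fine[i] = state
    t_fine = np.arange(n_fine) * h
    return fine[::substeps].copy(), t_fine, fine


def _env_channels(traj: np.ndarray, p: KineticParams) -> np.ndarray:
    """Noise-free environmental channels as functions of the state."""
    X, S = traj[:, 0], traj[:, 1]
    fx = X / p.X_max
    fs = S / (p.K_s + S)
    temperature = 30.0 + 2.0 * fx                       # metabolic heat load
    ph = 7.2 - 0.9 * (p.S0 - S) / p.S0                  # acidification
    do = 95.0 - 70.0 * fx * fs - 15.0 * fx              # O2 drawdown during growth
    agitation = 200.0 + 250.0 * fx                      # controller ramps with demand
    return np.column_stack([temperature, ph, do, agitation])


def _ar1(rng: np.random.Generator, n: int, sd: float, phi: float = 0.8) -> np.ndarray:
    if sd <= 0:
        return np.zeros(n)
    innov = rng.normal(0.0, sd * np.sqrt(1.0 - phi * phi), size=n)
    x = np.empty(n)
    x[0] = rng.normal(0.0, sd)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + innov[i]
    return x


def simulate_batch(
    p: KineticParams,
    n_points: int = 60,
    dt: float = 0.25,
    seed: int = 0,
    batch_id: int = 1,
    include_truth: bool = False,
) -> pd.DataFrame:
    """Simulate one batch; returns a tidy frame with env channels and targets.

    With ``include_truth`` the noise-free state and channel values are
    appended under ``truth_``-prefixed columns.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = np.random.default_rng(seed)
    traj, t_fine, fine = _integrate(p, n_points, dt)
    env = _env_channels(traj, p)
    t_grid = np.arange(n_points) * dt

    obs_env = env.copy()
    obs_targets = traj.copy()
    if p.sample_time_jitter_sd > 0:
        # offline assays read the state at a jittered sampling time
        t_jit = np.clip(
            t_grid + rng.normal(0.0, p.sample_time_jitter_sd, size=n_points),
            t_fine[0], t_fine[-1],
        )
        for j in range(3):
            obs_targets[:, j] = np.interp(t_jit, t_fine, fine[:, j])
    if p.noise_sd > 0:
        for j in range(env.shape[1]):
            rng_range = np.ptp(env[:, j])
            scale = p.noise_sd * (rng_range if rng_range > 0 else 1.0)
            obs_env[:, j] = env[:, j] + _ar1(rng, n_points, scale) + rng.normal(
                0.0, 0.5 * scale, size=n_points
            )
    # offline assays: constant-CV error plus a small range-proportional floor
    for j in range(traj.shape[1]):
        cv = p.assay_cv[j]
        if cv <= 0 and p.noise_sd <= 0:
            continue
        floor = 0.5 * p.noise_sd * np.ptp(traj[:, j])
        scale = cv * np.abs(obs_targets[:, j]) + floor
        obs_targets[:, j] = obs_targets[:, j] + rng.normal(0.0, 1.0, size=n_points) * scale

    df = pd.DataFrame({"batch_id": batch_id, "time_index": np.arange(n_points)})
    for j, name in enumerate(AUX_CHANNELS):
        df[name] = obs_env[:, j]
    for j, name in enumerate(TARGETS):
        df[name] = obs_targets[:, j]
    if include_truth:
        for j, name in enumerate(AUX_CHANNELS):
            df[f"truth_{name}"] = env[:, j]
        for j, name in enumerate(TARGETS):
            df[f"truth_{name}"] = traj[:, j]
    return df


def _jitter(p: KineticParams, rng: np.random.Generator) -> KineticParams:
    """Lognormal multiplicative jitter with CV ``batch_cv`` on the kinetics."""
    if p.batch_cv <= 0:
        return p
    sigma = float(np.sqrt(np.log1p(p.batch_cv**2)))
    fields = ("mu_max", "X_max", "Y_xs", "m_s", "alpha", "beta", "X0", "S0")
    factors = np.exp(rng.normal(-0.5 * sigma * sigma, sigma, size=len(fields)))
    return replace(p, **{f: getattr(p, f) * float(k) for f, k in zip(fields, factors)})


def generate_frame(
    n_batches: int = 15,
    n_points: int = 60,
    base: KineticParams | None = None,
    seed: int = 0,
    dt: float = 0.25,
    include_truth: bool = False,
) -> pd.DataFrame:
    """Tidy multi-batch frame with per-batch kinetic jitter; optionally
    carries the noise-free ground truth under ``truth_`` columns."""
    if n_batches < 2:
        raise ValueError("n_batches must be >= 2")
    base = base or KineticParams()
    root = np.random.default_rng(seed)
    frames = []
    for b in range(1, n_batches + 1):
        pb = _jitter(base, root)
        batch_seed = int(root.integers(0, 2**31 - 1))
        frames.append(
            simulate_batch(pb, n_points=n_points, dt=dt, seed=batch_seed,
                           batch_id=b, include_truth=include_truth)
        )
    return pd.concat(frames, ignore_index=True)


def generate_dataset(
    n_batches: int = 15,
    n_points: int = 60,
    base: KineticParams | None = None,
    seed: int = 0,
    dt: float = 0.25,
) -> BatchDataset:
    """Simulate ``n_batches`` batches with per-batch kinetic jitter.

    Defaults give 15 batches x 60 points = 900 rows, so a 12-batch
    training split yields 720 train / 180 test rows.
    """
    df = generate_frame(n_batches, n_points, base, seed, dt, include_truth=False)
    schema = ColumnSchema(aux=AUX_CHANNELS, targets=TARGETS)
    return BatchDataset.from_frame(df, schema)
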