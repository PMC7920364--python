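"""Fractional-step time integration of the coupled transwell system.

Each macro step is a Strang split: an implicit half-step of the
pointwise kinetics (damped Newton on the 11x11 per-cell systems), a full
explicit transport step (subcycled to respect the diffusion/taxis CFL
bound and the membrane exchange), and a second implicit kinetics
half-step.  The ECM field is clamped at zero after every kinetics solve
(its degradation law has no self-dependence, so exact integration can
cross zero).

Step size is adaptive: it grows by 1.5x after five consecutive cheap
Newton solves and halves whenever Newton fails to converge; falling
below ``dt_min`` is a hard failure that surfaces the diagnostic state.
The model has no randomness anywhere, so a fixed configuration
reproduces its trajectory bit for bit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import ConfigurationError, Grid
from .kinetics import IDX, State, TreatmentFlags, reaction_jacobian, reaction_rates
from .parameters import ParameterSet
from .transport import TransportOperator

__all__ = ["SolverConfig", "Trajectory", "SolverError", "StepRejected", "step", "run"]

logger = logging.getLogger(__name__)


class SolverError(RuntimeError):
    """Unrecoverable integration failure; carries the last state reached."""

    def __init__(self, message: str, state: State | None = None):
        super().__init__(message)
        self.state = state


class StepRejected(RuntimeError):
    """Newton non-convergence (or a non-physical iterate); retry smaller."""


@dataclass(frozen=True)
class SolverConfig:
    dt_init: float = 1e-4
    dt_min: float = 1e-9
    dt_max: float = 1e-2
    newton_tol: float = 1e-8
    newton_maxiter: int = 12
    #: Newton solves with at most this many iterations count as "cheap".
    cheap_iterations: int = 3
    #: consecutive cheap solves before dt grows by 1.5x
    growth_patience: int = 5
    cfl: float = 0.3
    #: log a warning when any field magnitude exceeds this
    blowup_threshold: float = 1e6

    def __post_init__(self) -> None:
        if not (0 < self.dt_min <= self.dt_init <= self.dt_max):
            raise ConfigurationError("require 0 < dt_min <= dt_init <= dt_max")
        if self.newton_tol <= 0:
            raise ConfigurationError("newton_tol must be positive")


@dataclass
class Trajectory:
    """Time-stamped snapshots plus run metadata."""

    times: list[float] = field(default_factory=list)
    states: list[State] = field(default_factory=list)
    stats: dict = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def append(self, state: State) -> None:
        self.times.append(state.t)
        self.states.append(state.copy())

    def final(self) -> State:
        return self.states[-1]


class _Stepper:
    """Caches the transport operator and region masks for one run."""

    def __init__(
        self,
        p: ParameterSet,
        grid: Grid,
        cfg: SolverConfig,
        flags: TreatmentFlags = TreatmentFlags(),
        g_source: float | np.ndarray = 0.0,
    ):
        self.p, self.grid, self.cfg, self.flags = p, grid, cfg, flags
        self.g_source = g_source
        self.transport = TransportOperator(p, grid)
        self.S_mask = grid.ecm_mask()
        self.inj_mask = grid.injection_mask()
        self.eye = np.eye(len(IDX))
        self.newton_iterations_last = 0
        self.stats = {"steps": 0, "rejections": 0, "newton_iterations": 0,
                      "transport_substeps": 0}

    # -- kinetics ----------------------------------------------------------
    def _rates(self, u: np.ndarray) -> np.ndarray:
        return reaction_rates(u, self.p, self.S_mask, self.inj_mask,
                              self.flags, self.g_source)

    def kinetics_half_step(self, u: np.ndarray, dt_half: float) -> np.ndarray:
        """Trapezoidal (Crank-Nicolson) half-step by damped Newton.

        Second order, so the full kinetics-transport-kinetics split keeps
        its formal order; the Newton systems are solved per cell,
        vectorized across the grid.
        """
        cfg = self.cfg
        u0 = u
        w = 0.5 * dt_half
        f0 = self._rates(u0)
        base = u0 + w * f0

        def residual(v):
            return v - base - w * self._rates(v)

        v = u0 + dt_half * f0  # explicit predictor
        res = residual(v)
        norm = np.max(np.abs(res))
        for it in range(1, cfg.newton_maxiter + 1):
            if norm <= cfg.newton_tol:
                self.newton_iterations_last = it - 1
                break
            J = reaction_jacobian(v, self.p, self.S_mask)
            A = self.eye[None, :, :] - w * J
            delta = np.linalg.solve(A, -res.T[:, :, None])[:, :, 0].T
            lam = 1.0
            for _ in range(6):  # damping line search
                v_new = v + lam * delta
                res_new = residual(v_new)
                norm_new = np.max(np.abs(res_new))
                if norm_new < norm or norm_new <= cfg.newton_tol:
                    break
                lam *= 0.5
            v, res, norm = v_new, res_new, norm_new
        else:
            raise StepRejected(f"Newton stalled at |res|={norm:.3e}")
        self.stats["newton_iterations"] += self.newton_iterations_last
        # rho's degradation law has no self-dependence, so it crosses zero
        # in finite time by design: clamp it, never reject on it.
        rho_row = IDX["rho"]
        v[rho_row] = np.maximum(v[rho_row], 0.0)
        if np.min(v) < -1e-8:
            raise StepRejected("kinetics produced a significantly negative field")
        return np.maximum(v, 0.0)  # clear roundoff-level negatives

    # -- transport ---------------------------------------------------------
    def transport_step(self, u: np.ndarray, dt: float) -> np.ndarray:
        n_sub = max(1, math.ceil(dt / self.transport.stable_dt(self.cfg.cfl)))
        sub = dt / n_sub
        for _ in range(n_sub):
            u = self.transport.step(u, sub)
        self.stats["transport_substeps"] += n_sub
        return np.maximum(u, 0.0)

    # -- full step ---------------------------------------------------------
    def step(self, state: State, dt: float) -> State:
        u = self.kinetics_half_step(state.fields, 0.5 * dt)
        iters = self.newton_iterations_last
        u = self.transport_step(u, dt)
        u = self.kinetics_half_step(u, 0.5 * dt)
        self.newton_iterations_last = max(iters, self.newton_iterations_last)
        peak = np.max(np.abs(u))
        if peak > self.cfg.blowup_threshold:
            logger.warning("field magnitude %.3e exceeds threshold %.1e at t=%.4f",
                           peak, self.cfg.blowup_threshold, state.t + dt)
        self.stats["steps"] += 1
        return State(u, state.t + dt)


def step(
    state: State,
    dt: float,
    p: ParameterSet,
    grid: Grid,
    cfg: SolverConfig | None = None,
    flags: TreatmentFlags = TreatmentFlags(),
    g_source: float | np.ndarray = 0.0,
) -> State:
    """Advance one Strang-split macro step (one-shot convenience form)."""
    if dt <= 0:
        raise ConfigurationError("dt must be positive")
    return _Stepper(p, grid, cfg or SolverConfig(), flags, g_source).step(state, dt)


def run(
    initial: State,
    p: ParameterSet,
    grid: Grid,
    t_end: float,
    cfg: SolverConfig | None = None,
    output_times: np.ndarray | None = None,
    flags: TreatmentFlags = TreatmentFlags(),
    g_source: float | np.ndarray = 0.0,
    metadata: dict | None = None,
) -> Trajectory:
    """Integrate to ``t_end``, sampling snapshots at ``output_times``.

    Steps land exactly on every requested output time (dt is clipped,
    never interpolated), and on ``t_end``.
    """
    cfg = cfg or SolverConfig()
    if output_times is None:
        output_times = np.array([t_end], float)
    output_times = np.asarray(sorted(set(float(t) for t in output_times)))
    if output_times.size and output_times[-1] > t_end + 1e-12:
        raise ConfigurationError("output times beyond t_end")

    stepper = _Stepper(p, grid, cfg, flags, g_source)
    traj = Trajectory(metadata=metadata or {})
    state = State(initial.fields.copy(), initial.t)
    traj.append(state)

    targets = [t for t in output_times if t > state.t + 1e-14]
    if t_end > state.t + 1e-14 and (not targets or targets[-1] < t_end - 1e-14):
        targets.append(t_end)

    dt = cfg.dt_init
    cheap_streak = 0
    for t_target in targets:
        while state.t < t_target - 1e-13:
            dt_try = min(dt, t_target - state.t)
            try:
                state = stepper.step(state, dt_try)
            except StepRejected:
                stepper.stats["rejections"] += 1
                cheap_streak = 0
                dt = 0.5 * dt_try
                if dt < cfg.dt_min:
                    raise SolverError(
                        f"dt underflow ({dt:.2e} < dt_min) at t={state.t:.6f}; "
                        "diagnostic state attached", state
                    ) from None
                continue
            if stepper.newton_iterations_last <= cfg.cheap_iterations:
                cheap_streak += 1
                if cheap_streak >= cfg.growth_patience:
                    dt = min(dt * 1.5, cfg.dt_max)
                    cheap_streak = 0
            else:
                cheap_streak = 0
        state.t = t_target  # absorb roundoff in the time accumulator
        traj.append(state)

    traj.stats = dict(stepper.stats)
    return traj
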