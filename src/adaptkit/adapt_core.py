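"""Step-wise estimation of time-varying parameter trajectories (ADAPT).

The estimator advances a kinetic model over a long-time grid t0, t0+dt, ...
On each step the system is simulated from the current state with candidate
parameters held constant, and the free parameters are re-estimated by
regularized weighted least squares against a continuous data interpolant:

    theta_hat(t+dt) = argmin  X_d(theta) + lambda_r * X_r(theta)

    X_d = (1/N) sum_n ((y_n - d_n(t+dt)) / sigma_n(t+dt))^2
    X_r = (1/M) sum_m ((theta_m(t+dt) - theta_m(t)) / (theta_ref_m * dt))^2

with N residuals and M free parameters. The squared-derivative penalty on
the normalized parameters suppresses unphysiological fluctuations; its
weight lambda_r trades data fit against trajectory smoothness (Pareto
sweep below). Repeating the whole procedure on bootstrap interpolants with
log-uniform random initial parameter draws (Monte Carlo multiple
minimization) yields an ensemble of trajectories whose spread reflects
both measurement uncertainty and undermodelling; replicates whose
cumulative SSE exceeds an acceptance threshold are flagged as rejected.

Two time scales are bridged: the data live on a slow axis (days) while the
model kinetics relax in seconds. Within each slow step the model is
integrated for a fixed fast-time horizon long enough for the metabolic
states to relax fully, so the trajectory tracks the quasi-steady state
implied by the current parameters.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .interpolants import (
    Interpolant,
    PhenotypeDataset,
    SigmaEnvelope,
    bootstrap_sample,
    default_smoothing,
    sigma_envelope,
)
from .kinetic_model import (
    KineticModel,
    SimulationError,
    SteadyStateError,
    fluxes,
    simulate,
    steady_state,
)

__all__ = [
    "AdaptConfig",
    "ObjectiveBreakdown",
    "ParameterTrajectory",
    "TrajectoryEnsemble",
    "objective_data",
    "objective_reg",
    "estimate_step",
    "init_trajectory",
    "run_trajectory",
    "run_ensemble",
    "flux_trajectories",
    "lambda_sweep",
]

_PENALTY = 1e6  # finite objective for failed simulations inside the optimizer


@dataclass(frozen=True)
class AdaptConfig:
    """Algorithm settings.

    Defaults follow the standard configuration: lambda_r = 0.1, dt = 0.1
    (long-time units), initial-draw bounds [lr, ur] = [0.1, 10] (multipliers
    on the reference parameters), nr = 1000 ensemble repeats, acceptance
    threshold sse_thres = 1000 on the cumulative un-averaged SSE, and
    optimizer/integrator tolerances of 1e-6.
    """

    lambda_r: float = 0.1
    dt: float = 0.1
    lr: float = 0.1
    ur: float = 10.0
    nr: int = 1000
    sse_thres: float = 1000.0
    free_parameters: tuple[str, ...] = ("k1",)
    seed: int = 0
    smoothing: float | None = None  # None -> per-dataset spacing heuristic
    tol: float = 1e-6  # optimizer termination (ftol/xtol)
    ode_rtol: float = 1e-6
    ode_atol: float = 1e-6
    relax_horizon: float = 1e4  # fast-time units integrated per slow step
    sigma_floor_rel: float = 0.01
    init_retries: int = 5
    sse_statistic: str = "interpolant"  # or "data": SSE vs raw stage data

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if not 0 < self.lr < self.ur:
            raise ValueError("need 0 < lr < ur")
        if self.nr < 1:
            raise ValueError("nr must be >= 1")
        if self.lambda_r < 0:
            raise ValueError("lambda_r must be >= 0")
        if self.sse_thres <= 0:
            raise ValueError("sse_thres must be positive")
        object.__setattr__(self, "free_parameters", tuple(self.free_parameters))

    def replace(self, **kwargs) -> "AdaptConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["free_parameters"] = list(self.free_parameters)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AdaptConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class ObjectiveBreakdown:
    """Per-step decomposition of the objective."""

    X_d: float
    X_r: float
    N_meas: int
    M: int

    @property
    def sse(self) -> float:
        """Un-averaged sum of squared weighted data errors, X_d * N."""
        return self.X_d * self.N_meas


def objective_data(
    y: np.ndarray, d_t: np.ndarray, sigma_t: np.ndarray
) -> ObjectiveBreakdown:
    """Weighted data misfit X_d = (1/N) sum ((y - d)/sigma)^2."""
    y = np.asarray(y, dtype=float)
    d_t = np.asarray(d_t, dtype=float)
    sigma_t = np.asarray(sigma_t, dtype=float)
    if y.shape != d_t.shape or y.shape != sigma_t.shape:
        raise ValueError("y, d_t and sigma_t must have identical shapes")
    if np.any(sigma_t <= 0):
        raise ValueError("sigma_t must be strictly positive")
    n = y.size
    x_d = float(np.sum(((y - d_t) / sigma_t) ** 2) / n)
    return ObjectiveBreakdown(X_d=x_d, X_r=0.0, N_meas=n, M=0)


def objective_reg(
    theta_prev: np.ndarray,
    theta_new: np.ndarray,
    dt: float,
    theta_ref: np.ndarray,
) -> ObjectiveBreakdown:
    """Roughness penalty X_r = (1/M) sum ((dtheta_m)/(theta_ref_m * dt))^2.

    The derivative is a forward finite difference over the step; the
    normalizer theta_ref makes the penalty scale-invariant.
    """
    theta_prev = np.asarray(theta_prev, dtype=float)
    theta_new = np.asarray(theta_new, dtype=float)
    theta_ref = np.asarray(theta_ref, dtype=float)
    if dt <= 0:
        raise ValueError("dt must be positive")
    if np.any(theta_ref <= 0):
        raise ValueError("theta_ref must be strictly positive")
    m = theta_prev.size
    x_r = float(np.sum(((theta_new - theta_prev) / (theta_ref * dt)) ** 2) / m)
    return ObjectiveBreakdown(X_d=0.0, X_r=x_r, N_meas=0, M=m)


def _relaxed_outputs(
    model: KineticModel,
    theta: np.ndarray,
    state_t: np.ndarray,
    config: AdaptConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Fast-time integration over the relaxation horizon; returns (y, x_end)."""
    res = simulate(
        model,
        theta,
        np.maximum(state_t, 0.0),
        model.u0,
        (0.0, config.relax_horizon),
        rtol=config.ode_rtol,
        atol=config.ode_atol,
    )
    x_end = res.final_state()
    return model.outputs(x_end), x_end


def estimate_step(
    model: KineticModel,
    state_t: np.ndarray,
    theta_t: np.ndarray,
    interpolant: Interpolant,
    sigma_env: SigmaEnvelope,
    t: float,
    config: AdaptConfig,
) -> tuple[np.ndarray, np.ndarray, ObjectiveBreakdown]:
    """One estimation step from t to t + dt.

    Simulates the model from ``state_t`` with candidate parameters held
    constant over the step and minimizes X_d(y(t+dt)) + lambda_r * X_r over
    the free parameters, warm-started at theta_t. Optimization is in
    log-parameter space so positivity is structural; the roughness
    normalizer is the step-start value theta_t. Returns the full parameter
    vector at t+dt, the relaxed state, and the objective breakdown.
    """
    free_idx = [model.parameter_index(n) for n in config.free_parameters]
    theta_t = np.asarray(theta_t, dtype=float)
    if np.any(theta_t[free_idx] <= 0):
        raise ValueError("free parameters must be strictly positive")
    t_next = t + config.dt
    d_next = interpolant(t_next)
    sigma_next = sigma_env(t_next)
    n_meas, m = d_next.size, len(free_idx)
    theta_ref = theta_t[free_idx]
    sqrt_reg = np.sqrt(config.lambda_r / m) / (theta_ref * config.dt)

    failures: list[np.ndarray] = []

    def residuals(z: np.ndarray) -> np.ndarray:
        th = theta_t.copy()
        th[free_idx] = np.exp(z)
        try:
            y, _ = _relaxed_outputs(model, th, state_t, config)
            r_d = (y - d_next) / sigma_next / np.sqrt(n_meas)
        except SimulationError:
            failures.append(th[free_idx].copy())
            r_d = np.full(n_meas, _PENALTY)
        r_r = sqrt_reg * (th[free_idx] - theta_ref)
        return np.concatenate([r_d, r_r])

    z0 = np.log(theta_ref)
    fit = least_squares(
        residuals, z0, method="lm", xtol=config.tol, ftol=config.tol
    )
    theta_new = theta_t.copy()
    theta_new[free_idx] = np.exp(fit.x)
    y_new, x_new = _relaxed_outputs(model, theta_new, state_t, config)
    bd = objective_data(y_new, d_next, sigma_next)
    br = objective_reg(theta_ref, theta_new[free_idx], config.dt, theta_ref)
    breakdown = ObjectiveBreakdown(
        X_d=bd.X_d, X_r=br.X_r, N_meas=n_meas, M=m
    )
    breakdown.optimizer_converged = bool(fit.status > 0)
    breakdown.simulation_failures = failures
    return theta_new, x_new, breakdown


def init_trajectory(
    model: KineticModel,
    interpolant: Interpolant,
    sigma_env: SigmaEnvelope,
    t0: float,
    config: AdaptConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Random initialization and stage-1 fit at the trajectory start.

    Free parameters are drawn log-uniformly on [lr, ur] times their
    reference values, then fitted to the interpolant at t0 by minimizing
    X_d alone (no roughness penalty at the start), with the model at steady
    state for the candidate parameters. Steady-state failures trigger a
    bounded number of re-draws.
    """
    free_idx = [model.parameter_index(n) for n in config.free_parameters]
    theta_ref = model.theta0[free_idx]
    d0 = interpolant(t0)
    sigma0 = sigma_env(t0)
    n_meas = d0.size

    last_err: Exception | None = None
    for _ in range(config.init_retries):
        draw = np.exp(
            rng.uniform(np.log(config.lr * theta_ref), np.log(config.ur * theta_ref))
        )
        theta = model.theta0.copy()
        theta[free_idx] = draw

        def residuals(z: np.ndarray) -> np.ndarray:
            th = theta.copy()
            th[free_idx] = np.exp(z)
            try:
                x_ss = steady_state(model, th, model.u0, model.x0, tol=1e-10)
            except SteadyStateError:
                return np.full(n_meas, _PENALTY)
            return (model.outputs(x_ss) - d0) / sigma0 / np.sqrt(n_meas)

        fit = least_squares(
            residuals, np.log(draw), method="lm",
            xtol=config.tol, ftol=config.tol,
        )
        theta[free_idx] = np.exp(fit.x)
        try:
            x0 = steady_state(model, theta, model.u0, model.x0, tol=1e-10)
            return theta, x0
        except SteadyStateError as exc:
            last_err = exc
    raise SteadyStateError(
        f"initialization failed after {config.init_retries} draws: {last_err}"
    )


@dataclass
class ParameterTrajectory:
    """One step-wise estimate theta_hat(t) with its state/flux/objective traces."""

    times: np.ndarray
    free_parameter_names: tuple[str, ...]
    theta_hat: np.ndarray  # (n_times, n_free)
    states: np.ndarray  # (n_times, n_states)
    fluxes: np.ndarray  # (n_times, n_reactions)
    breakdowns: list[ObjectiveBreakdown]
    total_sse: float
    accepted: bool
    replicate: int = 0
    diagnostic: str = ""

    @property
    def total_X_d(self) -> float:
        return float(sum(b.X_d for b in self.breakdowns))

    @property
    def total_X_r(self) -> float:
        return float(sum(b.X_r for b in self.breakdowns))

    def parameter(self, name: str) -> np.ndarray:
        return self.theta_hat[:, self.free_parameter_names.index(name)]


def run_trajectory(
    model: KineticModel,
    interpolant: Interpolant,
    sigma_env: SigmaEnvelope,
    config: AdaptConfig,
    rng: np.random.Generator,
    t0: float | None = None,
    t_end: float | None = None,
    dataset: PhenotypeDataset | None = None,
    replicate: int = 0,
) -> ParameterTrajectory:
    """One complete trajectory: random start, then step-wise estimation.

    The cumulative SSE sums the un-averaged weighted data error over all
    steps (against the replicate's own interpolant by default, or against
    the raw stage data if ``config.sse_statistic == 'data'``); the
    trajectory is accepted iff it stays below ``config.sse_thres``.
    """
    t0 = interpolant.t_min if t0 is None else t0
    t_end = interpolant.t_max if t_end is None else t_end
    n_steps = int(round((t_end - t0) / config.dt))
    free_idx = [model.parameter_index(n) for n in config.free_parameters]

    times = t0 + config.dt * np.arange(n_steps + 1)
    theta_hat = np.empty((n_steps + 1, len(free_idx)))
    states = np.empty((n_steps + 1, model.n_states))
    flux_tr = np.empty((n_steps + 1, model.n_reactions))
    breakdowns: list[ObjectiveBreakdown] = []

    try:
        theta, x = init_trajectory(model, interpolant, sigma_env, t0, config, rng)
    except SteadyStateError as exc:
        return ParameterTrajectory(
            times=times,
            free_parameter_names=tuple(config.free_parameters),
            theta_hat=np.full_like(theta_hat, np.nan),
            states=np.full_like(states, np.nan),
            fluxes=np.full_like(flux_tr, np.nan),
            breakdowns=[],
            total_sse=float("inf"),
            accepted=False,
            replicate=replicate,
            diagnostic=f"initialization failed: {exc}",
        )

    theta_hat[0] = theta[free_idx]
    states[0] = x
    flux_tr[0] = fluxes(model, x, theta, model.u0)

    diagnostic = ""
    for k in range(n_steps):
        t = times[k]
        try:
            theta, x, breakdown = estimate_step(
                model, x, theta, interpolant, sigma_env, t, config
            )
        except (SimulationError, SteadyStateError, ValueError) as exc:
            diagnostic = f"step {k} at t={t:.3f} failed: {exc}"
            theta_hat[k + 1 :] = np.nan
            states[k + 1 :] = np.nan
            flux_tr[k + 1 :] = np.nan
            return ParameterTrajectory(
                times=times,
                free_parameter_names=tuple(config.free_parameters),
                theta_hat=theta_hat,
                states=states,
                fluxes=flux_tr,
                breakdowns=breakdowns,
                total_sse=float("inf"),
                accepted=False,
                replicate=replicate,
                diagnostic=diagnostic,
            )
        theta_hat[k + 1] = theta[free_idx]
        states[k + 1] = x
        flux_tr[k + 1] = fluxes(model, x, theta, model.u0)
        breakdowns.append(breakdown)

    if config.sse_statistic == "data" and dataset is not None:
        env = sigma_env
        total_sse = 0.0
        for i, ts in enumerate(dataset.stage_times):
            k = int(round((ts - t0) / config.dt))
            if 0 <= k <= n_steps:
                y = model.outputs(states[k])
                bd = objective_data(y, dataset.means[i], env(ts))
                total_sse += bd.sse
    else:
        total_sse = float(sum(b.sse for b in breakdowns))

    return ParameterTrajectory(
        times=times,
        free_parameter_names=tuple(config.free_parameters),
        theta_hat=theta_hat,
        states=states,
        fluxes=flux_tr,
        breakdowns=breakdowns,
        total_sse=total_sse,
        accepted=bool(total_sse < config.sse_thres),
        replicate=replicate,
        diagnostic=diagnostic,
    )


@dataclass
class TrajectoryEnsemble:
    """nr repeated trajectories, each fitted to its own bootstrap interpolant."""

    trajectories: list[ParameterTrajectory]
    interpolants: list[Interpolant]
    config: AdaptConfig

    def __len__(self) -> int:
        return len(self.trajectories)

    @property
    def accepted(self) -> list[ParameterTrajectory]:
        return [tr for tr in self.trajectories if tr.accepted]

    @property
    def acceptance_rate(self) -> float:
        return len(self.accepted) / max(len(self.trajectories), 1)

    def parameter_matrix(self, name: str, accepted_only: bool = True) -> np.ndarray:
        """(n_kept, n_times) matrix of one free parameter across replicates."""
        trs = self.accepted if accepted_only else self.trajectories
        return np.vstack([tr.parameter(name) for tr in trs])

    def flux_matrix(self, reaction: int, accepted_only: bool = True) -> np.ndarray:
        trs = self.accepted if accepted_only else self.trajectories
        return np.vstack([tr.fluxes[:, reaction] for tr in trs])

    @property
    def times(self) -> np.ndarray:
        return self.trajectories[0].times


def run_ensemble(
    model: KineticModel,
    dataset: PhenotypeDataset,
    config: AdaptConfig,
) -> TrajectoryEnsemble:
    """Monte-Carlo ensemble of nr trajectories.

    Each replicate draws its own bootstrap sample of the data, fits a fresh
    spline interpolant to it, and runs the step-wise estimator from an
    independent log-uniform initial draw. Replicates are independently
    seeded (spawned from config.seed), so results are reproducible and
    independent of execution order.
    """
    p = (
        default_smoothing(dataset.stage_times)
        if config.smoothing is None
        else config.smoothing
    )
    env = sigma_envelope(dataset, floor_rel=config.sigma_floor_rel)
    children = np.random.SeedSequence(config.seed).spawn(config.nr)
    trajectories, interpolants = [], []
    for r in range(config.nr):
        rng = np.random.default_rng(children[r])
        rep = bootstrap_sample(dataset, rng)
        itp = Interpolant.fit(rep, p)
        tr = run_trajectory(
            model, itp, env, config, rng, dataset=dataset, replicate=r
        )
        trajectories.append(tr)
        interpolants.append(itp)
    return TrajectoryEnsemble(
        trajectories=trajectories, interpolants=interpolants, config=config
    )


def flux_trajectories(
    ensemble: TrajectoryEnsemble, model: KineticModel
) -> list[np.ndarray]:
    """Recompute per-replicate flux time-series from stored states/parameters.

    Serves as a consistency check: the result is identical to the fluxes
    stored during the run.
    """
    if not ensemble.trajectories:
        raise ValueError("ensemble is empty")
    out = []
    for tr in ensemble.trajectories:
        rows = []
        for k in range(len(tr.times)):
            if not np.all(np.isfinite(tr.states[k])):
                rows.append(np.full(model.n_reactions, np.nan))
                continue
            theta = model.theta0.copy()
            for j, name in enumerate(tr.free_parameter_names):
                theta[model.parameter_index(name)] = tr.theta_hat[k, j]
            rows.append(fluxes(model, tr.states[k], theta, model.u0))
        out.append(np.vstack(rows))
    return out


def lambda_sweep(
    model: KineticModel,
    dataset: PhenotypeDataset,
    config: AdaptConfig,
    lambdas,
) -> list[tuple[float, float, float]]:
    """Pareto sweep over the regularization weight.

    Runs one (typically reduced-nr) ensemble per lambda_r with identical
    seeds and returns (lambda_r, mean total X_d, mean total X_r) sorted by
    lambda_r, means taken over all replicates with finite objectives.
    """
    lambdas = sorted(float(lam) for lam in lambdas)
    if len(lambdas) < 2:
        raise ValueError("need at least 2 lambda values")
    results = []
    for lam in lambdas:
        ens = run_ensemble(model, dataset, config.replace(lambda_r=lam))
        xd = [tr.total_X_d for tr in ens.trajectories if tr.breakdowns]
        xr = [tr.total_X_r for tr in ens.trajectories if tr.breakdowns]
        results.append(
            (lam, float(np.mean(xd)) if xd else float("nan"),
             float(np.mean(xr)) if xr else float("nan"))
        )
    return results
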