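"""Kinetic ODE models of metabolic networks.

Models have the form

    dx/dt = N f(x, theta, u) + B u,      y = C x

with stoichiometric matrix ``N``, rate laws ``f`` (mass-action or saturable
kinetics), input fluxes ``u`` entering the balances through ``B``, and a
0/1 observation matrix ``C`` selecting the measurable species.

The module provides stiff-capable simulation, steady-state solving (damped
Newton with a long-horizon integration fallback), flux evaluation and an
asymptotic parameter-variance approximation from the Fisher information of
a weighted least-squares fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "KineticModel",
    "SimulationError",
    "SteadyStateError",
    "SimulationResult",
    "simulate",
    "steady_state",
    "fluxes",
    "fim_variance",
    "conservation_laws",
]


class SimulationError(RuntimeError):
    """ODE integration failed; carries the time at which it failed."""

    def __init__(self, message: str, t_fail: float | None = None):
        super().__init__(message)
        self.t_fail = t_fail


class SteadyStateError(RuntimeError):
    """Steady-state search did not converge; carries the residual norm."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


@dataclass
class KineticModel:
    """A kinetic network model dx/dt = N f(x, theta, u) + B u, y = C x.

    Parameters
    ----------
    state_names
        Species identifiers, one per row of ``stoichiometry``.
    stoichiometry
        Integer matrix, species x reactions.
    rate_laws
        Callable ``f(x, theta, u) -> rates`` returning one non-negative rate
        per reaction (all reactions irreversible).
    input_matrix
        Species x inputs matrix routing the input fluxes ``u`` into the
        balances.
    observation
        0/1 matrix mapping states to outputs, at most one 1 per row.
    parameter_names
        Identifiers for theta, in the order ``rate_laws`` expects.
    x0
        Default initial state (concentrations, a.u.).
    theta0
        Default parameter values (fixture reference set).
    u0
        Default input fluxes (a.u./time).
    """

    state_names: list[str]
    stoichiometry: np.ndarray
    rate_laws: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray]
    input_matrix: np.ndarray
    observation: np.ndarray
    parameter_names: list[str]
    x0: np.ndarray
    theta0: np.ndarray
    u0: np.ndarray
    reaction_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.stoichiometry = np.asarray(self.stoichiometry, dtype=float)
        self.input_matrix = np.asarray(self.input_matrix, dtype=float)
        self.observation = np.asarray(self.observation, dtype=float)
        self.x0 = np.asarray(self.x0, dtype=float)
        self.theta0 = np.asarray(self.theta0, dtype=float)
        self.u0 = np.asarray(self.u0, dtype=float)
        n_s, n_r = self.stoichiometry.shape
        if len(self.state_names) != n_s:
            raise ValueError("stoichiometry rows must match state_names")
        if self.input_matrix.shape[0] != n_s:
            raise ValueError("input_matrix rows must match states")
        if self.observation.shape[1] != n_s:
            raise ValueError("observation columns must match states")
        obs = self.observation
        if not np.all(np.isin(obs, (0.0, 1.0))) or np.any(obs.sum(axis=1) > 1):
            raise ValueError("observation must be 0/1 with at most one 1 per row")
        if not self.reaction_names:
            self.reaction_names = [f"v{i + 1}" for i in range(n_r)]
        test_rates = np.asarray(
            self.rate_laws(self.x0, self.theta0, self.u0), dtype=float
        )
        if test_rates.shape != (n_r,):
            raise ValueError(
                f"rate_laws returned {test_rates.shape}, expected ({n_r},)"
            )

    @property
    def n_states(self) -> int:
        return self.stoichiometry.shape[0]

    @property
    def n_reactions(self) -> int:
        return self.stoichiometry.shape[1]

    @property
    def output_names(self) -> list[str]:
        names = []
        for row in self.observation:
            idx = int(np.argmax(row))
            names.append(self.state_names[idx])
        return names

    def parameter_index(self, name: str) -> int:
        return self.parameter_names.index(name)

    def with_theta(self, **overrides: float) -> np.ndarray:
        """Default parameter vector with named entries replaced."""
        theta = self.theta0.copy()
        for name, value in overrides.items():
            theta[self.parameter_index(name)] = float(value)
        return theta

    def rhs(self, t: float, x: np.ndarray, theta: np.ndarray, u) -> np.ndarray:
        u_t = np.asarray(u(t), dtype=float) if callable(u) else np.asarray(u)
        rates = np.asarray(self.rate_laws(x, theta, u_t), dtype=float)
        return self.stoichiometry @ rates + self.input_matrix @ u_t

    def outputs(self, x: np.ndarray) -> np.ndarray:
        return self.observation @ np.asarray(x, dtype=float)

    def summary(self) -> dict:
        """JSON-serializable structural summary for provenance logs."""
        return {
            "state_names": list(self.state_names),
            "parameter_names": list(self.parameter_names),
            "reaction_names": list(self.reaction_names),
            "stoichiometry": self.stoichiometry.astype(int).tolist(),
            "observed": self.output_names,
        }


@dataclass
class SimulationResult:
    """Time-indexed state trajectory from :func:`simulate`."""

    times: np.ndarray
    states: np.ndarray  # (n_times, n_states)

    def final_state(self) -> np.ndarray:
        return self.states[-1]


def simulate(
    model: KineticModel,
    theta: np.ndarray,
    x0: np.ndarray,
    u,
    t_span: tuple[float, float],
    t_eval: np.ndarray | None = None,
    rtol: float = 1e-6,
    atol: float = 1e-6,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the model ODEs over ``t_span``.

    ``u`` may be a constant input vector or a callable ``u(t)``. Default
    tolerances are abs = rel = 1e-6.
    """
    t0, t1 = float(t_span[0]), float(t_span[1])
    if not t1 > t0:
        raise ValueError("t_span must be increasing")
    if rtol <= 0 or atol <= 0:
        raise ValueError("tolerances must be positive")
    theta = np.asarray(theta, dtype=float)
    x0 = np.asarray(x0, dtype=float)
    if np.any(theta < 0) or np.any(x0 < 0):
        raise ValueError("theta and x0 must be non-negative")
    sol = solve_ivp(
        model.rhs,
        (t0, t1),
        x0,
        args=(theta, u),
        method=method,
        rtol=rtol,
        atol=atol,
        t_eval=t_eval,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed at t={sol.t[-1]:.6g}: {sol.message}",
            t_fail=float(sol.t[-1]),
        )
    if not np.all(np.isfinite(sol.y)):
        raise SimulationError("non-finite state encountered", t_fail=t1)
    return SimulationResult(times=sol.t, states=sol.y.T)


def conservation_laws(model: KineticModel, tol: float = 1e-10) -> np.ndarray:
    """Left null space of [N | B]: rows w with w N = 0 and w B = 0.

    Each row is a conserved moiety (a weighted species sum invariant under
    all reactions and inputs). Returns an (n_laws, n_states) array.
    """
    aug = np.hstack([model.stoichiometry, model.input_matrix])
    u_mat, s, _ = np.linalg.svd(aug)
    rank = int(np.sum(s > tol * (s[0] if s.size else 1.0)))
    null = u_mat[:, rank:].T
    return null


def steady_state(
    model: KineticModel,
    theta: np.ndarray,
    u: np.ndarray,
    x_guess: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> np.ndarray:
    """Solve N f(x) + B u = 0 by damped Newton, preserving conserved moieties.

    Conserved totals are pinned to the values implied by ``x_guess`` (the
    balance equations alone are rank-deficient in their presence). Falls
    back to long-horizon integration if Newton stalls. Raises
    :class:`SteadyStateError` on non-convergence or a negative solution.
    """
    theta = np.asarray(theta, dtype=float)
    u = np.asarray(u, dtype=float)
    x = np.asarray(x_guess, dtype=float).copy()
    if np.any(x < 0):
        raise ValueError("x_guess must be non-negative")
    laws = conservation_laws(model)
    totals = laws @ x if laws.size else np.empty(0)

    def residual(xv: np.ndarray) -> np.ndarray:
        r = model.rhs(0.0, xv, theta, u)
        if laws.size:
            return np.concatenate([r, laws @ xv - totals])
        return r

    scale = np.maximum(np.abs(x), 1.0)

    def norm(r):
        return float(np.max(np.abs(r)))

    converged = False
    for _ in range(max_iter):
        r = residual(x)
        if norm(r[: model.n_states]) < tol:
            converged = True
            break
        # finite-difference Jacobian of the augmented (consistent) system
        n = x.size
        jac = np.empty((r.size, n))
        for j in range(n):
            h = 1e-7 * scale[j]
            xp = x.copy()
            xp[j] += h
            jac[:, j] = (residual(xp) - r) / h
        step, *_ = np.linalg.lstsq(jac, -r, rcond=None)
        # backtracking line search with positivity clip
        lam, r0 = 1.0, norm(r)
        for _ in range(30):
            x_new = np.maximum(x + lam * step, 0.0)
            if norm(residual(x_new)) < r0:
                break
            lam *= 0.5
        else:
            break  # stalled -> integration fallback
        x = x_new

    if not converged:
        # long-horizon integration fallback, then one polish pass
        try:
            res = simulate(model, theta, np.maximum(x, 0.0), u, (0.0, 1e6))
            x = np.maximum(res.final_state(), 0.0)
        except SimulationError:
            pass
        r = residual(x)
        if norm(r[: model.n_states]) >= tol:
            raise SteadyStateError(
                f"steady-state residual {norm(r[: model.n_states]):.3e} "
                f"exceeds tol {tol:.1e}",
                residual=norm(r[: model.n_states]),
            )
    if np.any(x < -1e-9):
        raise SteadyStateError("negative steady-state solution rejected")
    return np.maximum(x, 0.0)


def fluxes(
    model: KineticModel,
    x: np.ndarray,
    theta: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Evaluate the reaction rates f(x, theta, u), in reaction order."""
    x = np.asarray(x, dtype=float)
    if x.shape != (model.n_states,):
        raise ValueError(
            f"state has shape {x.shape}, model expects ({model.n_states},)"
        )
    if np.any(x < 0):
        raise ValueError("state must be non-negative")
    u = np.asarray(u, dtype=float)
    return np.asarray(model.rate_laws(x, np.asarray(theta, float), u), dtype=float)


def fim_variance(
    model: KineticModel,
    theta: np.ndarray,
    dataset,
    free_indices: Sequence[int],
    u: np.ndarray | None = None,
    rel_step: float = 1e-6,
    ss_tol: float = 1e-10,
) -> np.ndarray:
    """Asymptotic variances diag((J' W J)^-1) of a weighted steady-state fit.

    J is the sensitivity of the steady-state outputs to the free parameters
    (central finite differences, relative step ``rel_step``) stacked over
    the dataset's stages; W = diag(1/sigma^2). Raises
    :class:`SteadyStateError` if the information matrix is singular
    (structural non-identifiability).
    """
    free_indices = list(free_indices)
    if not free_indices:
        raise ValueError("free_indices must be non-empty")
    sds = np.asarray(dataset.sds, dtype=float)
    if np.any(sds <= 0):
        raise ValueError("dataset sds must be strictly positive for the FIM")
    theta = np.asarray(theta, dtype=float)
    u = model.u0 if u is None else np.asarray(u, dtype=float)
    n_stages = len(dataset.stage_times)

    def outputs_all_stages(th: np.ndarray) -> np.ndarray:
        ys = []
        x_guess = model.x0
        for _ in range(n_stages):
            x_ss = steady_state(model, th, u, x_guess, tol=ss_tol)
            ys.append(model.outputs(x_ss))
            x_guess = x_ss
        return np.concatenate(ys)

    jac_cols = []
    for idx in free_indices:
        h = rel_step * max(abs(theta[idx]), 1e-12)
        tp, tm = theta.copy(), theta.copy()
        tp[idx] += h
        tm[idx] -= h
        jac_cols.append((outputs_all_stages(tp) - outputs_all_stages(tm)) / (2 * h))
    jac = np.column_stack(jac_cols)
    w = 1.0 / sds.reshape(-1) ** 2
    fim = jac.T @ (w[:, None] * jac)
    cond = np.linalg.cond(fim)
    if not np.isfinite(cond) or cond > 1e14:
        raise SteadyStateError(
            "singular Fisher information matrix: parameters "
            f"{[model.parameter_names[i] for i in free_indices]} are "
            "structurally non-identifiable from this dataset"
        )
    variances = np.diag(np.linalg.inv(fim)).copy()
    # numerically tiny negatives from inversion are clipped
    return np.maximum(variances, 0.0)
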