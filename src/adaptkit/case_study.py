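"""The staged toy system: a small metabolic network under transcriptional
negative feedback, its undermodelled reduction, and the three inference
case drivers.

The true system has four metabolites S1..S4 (observable) and one regulator
mRNA R1 (unobservable). The network contains a conserved carrier cycle
(S2 + S3 invariant), a branch, two constant input fluxes, and an
S4-activated transcript whose product inhibits the first reaction:

    v1 = Vmax * S1 * S3 / (1 + R1/Ki)     (inhibited carrier reaction)
    v2 = k2 * S2                           (carrier return, feeds S4)
    v3 = k3 * S1                           (branch drain of S1)
    v4 = k4 * S4                           (drain of S4)
    v5 = k5 * S2                           (branch return to S3)
    v6 = k6 * S4                           (transcription + translation)
    v7 = kd * R1                           (mRNA degradation)

    dS1 = u1 - v1 - v3          dS2 = v1 - v2 - v5
    dS3 = v2 + v5 - v1          dS4 = v2 + u2 - v4
    dR1 = v6 - v7

A slow gene circuit (k6, kd several orders below the metabolic rate
constants) separates the fast metabolic time scale (seconds) from the slow
adaptation driven by staged changes in k6. The reduced model drops R1 and
lumps reaction 1 into pure mass action v1' = k1*S1*S3; k1 absorbs both the
enzyme capacity and its transcriptional regulation.

Default parameter values are fixture constants chosen so that (i) the
metabolic subsystem relaxes within ~10 s after a small input pulse,
(ii) the gene circuit is >= 10^3-fold slower than metabolism, and
(iii) every stage of the intervention admits a positive steady state.
Tests that compare against "truth" always compare against this generator,
never against external tables. The topology lives only in the two
constructors below, so it can be swapped without touching other modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .adapt_core import AdaptConfig, TrajectoryEnsemble, run_ensemble
from .interpolants import PhenotypeDataset, sigma_envelope
from .kinetic_model import (
    KineticModel,
    SteadyStateError,
    fim_variance,
    simulate,
    steady_state,
)

__all__ = [
    "TRUE_DEFAULTS",
    "InterventionSchedule",
    "build_true_system",
    "build_reduced_model",
    "intervention_schedule",
    "lumped_k1",
    "run_case1",
    "run_case2",
    "run_case3",
    "reestimate_reference_k6",
    "fraction_within_quantiles",
    "pulse_response",
    "Case1Result",
    "PulseSpec",
    "PulseResult",
]

# Fixture reference parameterization (fast-time units: seconds).
TRUE_DEFAULTS = {
    "Vmax": 1.0,
    "Ki": 0.1,
    "k2": 1.0,
    "k3": 0.1,
    "k4": 0.5,
    "k5": 0.2,
    "k6": 0.01,  # reference transcription-translation rate constant
    "kd": 2e-4,
}
INPUTS = np.array([1.0, 0.2])  # u1 -> S1, u2 -> S4

K6_REFERENCE = 0.01
STAGE_DECLINE_FACTOR = 0.5  # geometric per-stage decline of k6
N_STAGES = 5


def _true_rate_laws(x, theta, u):
    s1, s2, s3, s4, r1 = x
    vmax, ki, k2, k3, k4, k5, k6, kd = theta
    return np.array(
        [
            vmax * s1 * s3 / (1.0 + r1 / ki),
            k2 * s2,
            k3 * s1,
            k4 * s4,
            k5 * s2,
            k6 * s4,
            kd * r1,
        ]
    )


def _reduced_rate_laws(x, theta, u):
    s1, s2, s3, s4 = x
    k1, k2, k3, k4, k5 = theta
    return np.array(
        [k1 * s1 * s3, k2 * s2, k3 * s1, k4 * s4, k5 * s2]
    )


@lru_cache(maxsize=None)
def _reference_steady_state() -> tuple[float, ...]:
    """Stage-1 steady state of the true system (moiety total S2+S3 = 2)."""
    model = _build_true_raw(x0=np.array([1.0, 1.0, 1.0, 1.0, 1.0]))
    x_ss = steady_state(model, model.theta0, model.u0, model.x0, tol=1e-12)
    return tuple(x_ss)


def _build_true_raw(x0: np.ndarray, overrides: dict | None = None) -> KineticModel:
    params = dict(TRUE_DEFAULTS)
    if overrides:
        for k, v in overrides.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r}")
            if not v > 0:
                raise ValueError(f"parameter {k!r} must be positive")
            params[k] = float(v)
    #        v1  v2  v3  v4  v5  v6  v7
    stoich = np.array(
        [
            [-1,  0, -1,  0,  0,  0,  0],  # S1
            [ 1, -1,  0,  0, -1,  0,  0],  # S2
            [-1,  1,  0,  0,  1,  0,  0],  # S3
            [ 0,  1,  0, -1,  0,  0,  0],  # S4
            [ 0,  0,  0,  0,  0,  1, -1],  # R1
        ]
    )
    input_matrix = np.array(
        [[1, 0], [0, 0], [0, 0], [0, 1], [0, 0]], dtype=float
    )
    observation = np.eye(5)[:4]  # S1..S4 observed, R1 hidden
    return KineticModel(
        state_names=["S1", "S2", "S3", "S4", "R1"],
        stoichiometry=stoich,
        rate_laws=_true_rate_laws,
        input_matrix=input_matrix,
        observation=observation,
        parameter_names=list(TRUE_DEFAULTS),
        x0=x0,
        theta0=np.array([params[k] for k in TRUE_DEFAULTS]),
        u0=INPUTS.copy(),
    )


def build_true_system(overrides: dict | None = None) -> KineticModel:
    """The five-state true system; x0 is the reference (stage-1) steady state."""
    x0 = np.array(_reference_steady_state())
    return _build_true_raw(x0=x0, overrides=overrides)


def build_reduced_model(overrides: dict | None = None) -> KineticModel:
    """The four-state undermodelled reduction with lumped mass-action k1.

    All metabolites are observed (identity observation). Defaults: k2..k5
    from the true system; k1 at its stage-1 lumped value so the default
    reduced model reproduces the reference metabolite steady state.
    """
    x_ref = np.array(_reference_steady_state())
    r1_ss = x_ref[4]
    params = {
        "k1": TRUE_DEFAULTS["Vmax"] / (1.0 + r1_ss / TRUE_DEFAULTS["Ki"]),
        "k2": TRUE_DEFAULTS["k2"],
        "k3": TRUE_DEFAULTS["k3"],
        "k4": TRUE_DEFAULTS["k4"],
        "k5": TRUE_DEFAULTS["k5"],
    }
    if overrides:
        for k, v in overrides.items():
            if k not in params:
                raise KeyError(f"unknown parameter {k!r}")
            if not v > 0:
                raise ValueError(f"parameter {k!r} must be positive")
            params[k] = float(v)
    stoich = np.array(
        [
            [-1,  0, -1,  0,  0],
            [ 1, -1,  0,  0, -1],
            [-1,  1,  0,  0,  1],
            [ 0,  1,  0, -1,  0],
        ]
    )
    input_matrix = np.array([[1, 0], [0, 0], [0, 0], [0, 1]], dtype=float)
    return KineticModel(
        state_names=["S1", "S2", "S3", "S4"],
        stoichiometry=stoich,
        rate_laws=_reduced_rate_laws,
        input_matrix=input_matrix,
        observation=np.eye(4),
        parameter_names=list(params),
        x0=x_ref[:4].copy(),
        theta0=np.array(list(params.values())),
        u0=INPUTS.copy(),
    )


@dataclass
class InterventionSchedule:
    """Per-stage values of the staged parameter (default: k6).

    Five stages at long-times 0..4 (days); stage 1 holds the reference
    value, later stages decline geometrically.
    """

    stage_times: np.ndarray
    values: np.ndarray
    parameter: str = "k6"

    def __post_init__(self):
        self.stage_times = np.asarray(self.stage_times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.stage_times.shape != self.values.shape:
            raise ValueError("stage_times and values must have equal length")
        d = np.diff(self.values)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("schedule must be strictly monotone")

    def __len__(self) -> int:
        return len(self.values)


def intervention_schedule(
    factor: float = STAGE_DECLINE_FACTOR, n_stages: int = N_STAGES
) -> InterventionSchedule:
    values = K6_REFERENCE * factor ** np.arange(n_stages)
    return InterventionSchedule(
        stage_times=np.arange(n_stages, dtype=float), values=values
    )


def lumped_k1(k6: float, true_model: KineticModel | None = None) -> float:
    """True lumped reaction-1 constant k1 = Vmax / (1 + R1_ss/Ki) at a given k6.

    This is the value for which the reduced model's metabolite steady state
    coincides with the true system's.
    """
    model = true_model if true_model is not None else build_true_system()
    theta = model.with_theta(k6=k6)
    x_ss = steady_state(model, theta, model.u0, model.x0, tol=1e-12)
    i_vmax = model.parameter_index("Vmax")
    i_ki = model.parameter_index("Ki")
    return float(theta[i_vmax] / (1.0 + x_ss[4] / theta[i_ki]))


# ---------------------------------------------------------------------------
# Case drivers
# ---------------------------------------------------------------------------

def _wls_fit_steady_state(
    model: KineticModel,
    free_names: list[str],
    theta_start: np.ndarray,
    d: np.ndarray,
    sigma: np.ndarray,
    tol: float = 1e-6,
) -> np.ndarray:
    """Weighted least-squares fit of steady-state outputs to one snapshot.

    Optimizes the named parameters in log space (positivity is structural),
    warm-started at ``theta_start``. Returns the full fitted theta.
    """
    from scipy.optimize import least_squares

    free_idx = [model.parameter_index(n) for n in free_names]
    theta = np.asarray(theta_start, dtype=float).copy()
    n_meas = d.size

    def residuals(z: np.ndarray) -> np.ndarray:
        th = theta.copy()
        th[free_idx] = np.exp(z)
        try:
            x_ss = steady_state(model, th, model.u0, model.x0, tol=1e-10)
        except SteadyStateError:
            return np.full(n_meas, 1e6)
        return (model.outputs(x_ss) - d) / sigma / np.sqrt(n_meas)

    z0 = np.log(theta[free_idx])
    fit = least_squares(residuals, z0, method="lm", xtol=tol, ftol=tol)
    theta[free_idx] = np.exp(fit.x)
    return theta


@dataclass
class Case1Result:
    """Per-stage re-estimates of k6 (stages 2..n) with FIM variances."""

    stage_times: np.ndarray
    k6_reference: float
    estimates: np.ndarray  # stages 2..n
    variances: np.ndarray  # same length as estimates
    fitted_outputs: np.ndarray = field(default=None)  # (n_stages-1, n_obs)


def run_case1(dataset: PhenotypeDataset, config: AdaptConfig | None = None) -> Case1Result:
    """Classical estimation: re-fit k6 per stage from steady-state data.

    k6 is known at stage 1 (the reference phenotype) and used as the warm
    start; stages 2..n are estimated independently by weighted least
    squares (no regularization), each warm-started at the previous stage's
    estimate. Variances come from the inverse Fisher information of each
    stage's fit.
    """
    config = config or AdaptConfig(free_parameters=["k6"])
    model = build_true_system()
    env = sigma_envelope(dataset, floor_rel=config.sigma_floor_rel)
    k6_idx = model.parameter_index("k6")

    estimates, variances, fitted = [], [], []
    theta = model.theta0.copy()  # stage-1 reference values, k6 known
    for i in range(1, len(dataset.stage_times)):
        t_i = dataset.stage_times[i]
        d_i = dataset.means[i]
        sigma_i = env(t_i)
        theta = _wls_fit_steady_state(
            model, ["k6"], theta, d_i, sigma_i, tol=config.tol
        )
        estimates.append(theta[k6_idx])
        stage_ds = dataset.stage(i).with_sds(sigma_i[None, :])
        variances.append(
            float(fim_variance(model, theta, stage_ds, [k6_idx])[0])
        )
        x_ss = steady_state(model, theta, model.u0, model.x0, tol=1e-10)
        fitted.append(model.outputs(x_ss))
    return Case1Result(
        stage_times=dataset.stage_times.copy(),
        k6_reference=float(model.theta0[k6_idx]),
        estimates=np.array(estimates),
        variances=np.array(variances),
        fitted_outputs=np.array(fitted),
    )


def run_case2(
    dataset: PhenotypeDataset, config: AdaptConfig | None = None
) -> list[np.ndarray]:
    """Independent per-stage Monte-Carlo estimation of the lumped k1.

    For each stage the snapshot is bootstrapped (parametric Gaussian error
    model) and the reduced model's k1 is re-fitted to each replicate at
    steady state, giving one empirical distribution per stage. Replicates
    whose fit fails are dropped (counted via the returned array lengths).
    """
    from .interpolants import bootstrap_sample

    config = config or AdaptConfig(free_parameters=["k1"])
    model = build_reduced_model()
    env = sigma_envelope(dataset, floor_rel=config.sigma_floor_rel)
    rng = np.random.default_rng(np.random.SeedSequence(config.seed).spawn(1)[0])

    distributions = []
    for i in range(len(dataset.stage_times)):
        stage_ds = dataset.stage(i)
        sigma_i = env(dataset.stage_times[i])
        draws = []
        theta = model.theta0.copy()
        for _ in range(config.nr):
            rep = bootstrap_sample(stage_ds, rng)
            try:
                theta_fit = _wls_fit_steady_state(
                    model, ["k1"], theta, rep.means[0], sigma_i, tol=config.tol
                )
            except (SteadyStateError, FloatingPointError):
                continue
            draws.append(theta_fit[model.parameter_index("k1")])
        distributions.append(np.array(draws))
    return distributions


def run_case3(
    dataset: PhenotypeDataset, config: AdaptConfig | None = None
) -> TrajectoryEnsemble:
    """Full trajectory inference: time-varying k1 in the reduced model.

    Delegates to the ensemble estimator with free parameter {k1}; k2..k5
    stay fixed at their reference values.
    """
    config = config or AdaptConfig()
    config = config.replace(free_parameters=["k1"])
    model = build_reduced_model()
    return run_ensemble(model, dataset, config)


def reestimate_reference_k6(
    dataset: PhenotypeDataset,
    config: AdaptConfig | None = None,
    start_factor: float = 5.0,
) -> float:
    """Re-estimate the reference (stage-1) k6 from the stage-1 snapshot.

    Treats k6 as unknown and fits it by weighted least squares on the
    stage-1 steady-state outputs, warm-started ``start_factor`` away from
    the reference value so the optimizer does real work.
    """
    config = config or AdaptConfig(free_parameters=["k6"])
    model = build_true_system()
    env = sigma_envelope(dataset, floor_rel=config.sigma_floor_rel)
    theta = model.with_theta(k6=start_factor * K6_REFERENCE)
    theta = _wls_fit_steady_state(
        model, ["k6"], theta, dataset.means[0], env(dataset.stage_times[0]),
        tol=config.tol,
    )
    return float(theta[model.parameter_index("k6")])


def fraction_within_quantiles(
    values: np.ndarray,
    reference: np.ndarray,
    lo: float = 0.05,
    hi: float = 0.95,
) -> float:
    """Fraction of ``values`` inside the [lo, hi] quantile band of ``reference``.

    The overlap statistic used to compare trajectory-ensemble parameter
    values at a stage time against the per-stage Monte-Carlo distributions.
    """
    values = np.asarray(values, dtype=float)
    q_lo, q_hi = np.quantile(np.asarray(reference, dtype=float), [lo, hi])
    return float(np.mean((values >= q_lo) & (values <= q_hi)))


# ---------------------------------------------------------------------------
# Short-term dynamics: pulse experiment
# ---------------------------------------------------------------------------

@dataclass
class PulseSpec:
    """Square pulse added to one input flux."""

    start: float = 5.0
    duration: float = 0.5
    amplitude: float = 0.2  # absolute addition to the input, a.u./time
    input_index: int = 0


@dataclass
class PulseResult:
    times: np.ndarray
    states: np.ndarray
    recovery_time: float  # duration from pulse onset to sustained recovery
    max_rel_deviation: np.ndarray  # per state, over the whole experiment


def pulse_response(
    model: KineticModel,
    theta: np.ndarray,
    x_ss: np.ndarray,
    pulse: PulseSpec,
    t_end: float = 60.0,
    recovery_frac: float = 0.01,
    n_grid: int = 6001,
) -> PulseResult:
    """Simulate the response to a square input pulse from a steady state.

    The recovery time is the duration from pulse onset until all observed
    metabolite deviations stay below ``recovery_frac`` of their steady-state
    values for the remainder of the horizon (sustained recovery). A pulse
    of zero amplitude recovers instantly (recovery time 0).
    """
    x_ss = np.asarray(x_ss, dtype=float)
    u_base = model.u0.copy()
    u_pulse = u_base.copy()
    u_pulse[pulse.input_index] += pulse.amplitude
    t_on, t_off = pulse.start, pulse.start + pulse.duration

    segs = []
    grid = np.linspace(0.0, t_end, n_grid)
    for (a, b), u in (
        ((0.0, t_on), u_base),
        ((t_on, t_off), u_pulse),
        ((t_off, t_end), u_base),
    ):
        t_eval = grid[(grid >= a) & (grid <= b)]
        if t_eval.size == 0 or t_eval[0] > a:
            t_eval = np.insert(t_eval, 0, a)
        if t_eval[-1] < b:
            t_eval = np.append(t_eval, b)
        x_start = segs[-1][1][-1] if segs else x_ss
        res = simulate(model, theta, np.maximum(x_start, 0.0), u, (a, b), t_eval=t_eval)
        segs.append((res.times, res.states))

    times = np.concatenate([s[0] for s in segs])
    states = np.vstack([s[1] for s in segs])
    order = np.argsort(times, kind="stable")
    times, states = times[order], states[order]

    obs_idx = [int(np.argmax(row)) for row in model.observation]
    rel_dev = np.abs(states - x_ss) / np.maximum(np.abs(x_ss), 1e-12)
    if pulse.amplitude == 0.0:
        recovery = 0.0
    else:
        post = times >= t_off
        dev_post = rel_dev[post][:, obs_idx]
        t_post = times[post]
        below = np.all(dev_post < recovery_frac, axis=1)
        # first index after which recovery is sustained to the horizon
        sustained = np.flip(np.logical_and.accumulate(np.flip(below)))
        hit = np.argmax(sustained)
        if not sustained.any():
            recovery = float("inf")
        else:
            recovery = float(t_post[hit] - t_on)
    return PulseResult(
        times=times,
        states=states,
        recovery_time=recovery,
        max_rel_deviation=rel_dev.max(axis=0),
    )
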