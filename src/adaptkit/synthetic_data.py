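"""Mock phenotype-snapshot generation from a staged kinetic system.

Each stage sets the staged parameter (the intervention), brings the system
to steady state, and reads out the observables. Measurement noise is
zero-mean Gaussian; its standard deviation is drawn uniformly between 0
and ``max_rel_sd`` (default 20%) of the reference-phenotype output, per
observable. By default an independent SD is drawn for every stage
(matching stage-indexed measurement error); a flag switches to a single
draw shared across stages. Negative noisy means are kept — the error
model is unconditionally Gaussian.

A ground-truth record (true steady states, fluxes and staged parameter
values) accompanies every dataset for recovery tests; estimators never
read it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .interpolants import PhenotypeDataset
from .kinetic_model import KineticModel, SteadyStateError, fluxes, steady_state

__all__ = ["NoiseConfig", "GroundTruth", "generate_snapshots", "ground_truth_fluxes"]


@dataclass(frozen=True)
class NoiseConfig:
    """Gaussian measurement-noise settings.

    max_rel_sd: upper bound of the uniform SD draw, as a fraction of the
    reference (stage-1) output. per_stage_draw: draw a fresh SD for every
    stage (default) or once per observable for the whole dataset.
    sd_overrides: optional fixed per-observable SDs (bypass the draw).
    """

    max_rel_sd: float = 0.2
    per_stage_draw: bool = True
    sd_overrides: dict | None = None

    def __post_init__(self):
        if self.max_rel_sd < 0:
            raise ValueError("max_rel_sd must be >= 0")


@dataclass
class GroundTruth:
    """Generator truth: stage-wise steady states, fluxes and staged parameters."""

    stage_times: np.ndarray
    staged_parameter: str
    staged_values: np.ndarray
    state_names: list[str]
    reaction_names: list[str]
    steady_states: np.ndarray  # (n_stages, n_states)
    fluxes: np.ndarray  # (n_stages, n_reactions)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "stage_times": self.stage_times.tolist(),
            "staged_parameter": self.staged_parameter,
            "staged_values": self.staged_values.tolist(),
            "state_names": list(self.state_names),
            "reaction_names": list(self.reaction_names),
            "steady_states": self.steady_states.tolist(),
            "fluxes": self.fluxes.tolist(),
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            stage_times=np.array(d["stage_times"]),
            staged_parameter=d["staged_parameter"],
            staged_values=np.array(d["staged_values"]),
            state_names=d["state_names"],
            reaction_names=d["reaction_names"],
            steady_states=np.array(d["steady_states"]),
            fluxes=np.array(d["fluxes"]),
        )


def generate_snapshots(
    system: KineticModel,
    schedule,
    noise: NoiseConfig,
    rng: np.random.Generator | int | None = None,
) -> tuple[PhenotypeDataset, GroundTruth]:
    """Steady-state snapshots of a staged system plus Gaussian noise.

    For each stage i the staged parameter takes its scheduled value, the
    steady state is solved (warm-started from the previous stage), and the
    noisy snapshot is d_i = y_ss_i + xi_i with xi_i ~ Normal(0, sigma_i).
    Aborts with the failing stage index if any stage has no steady state.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n_stages = len(schedule)
    if n_stages < 1:
        raise ValueError("schedule must have at least one stage")

    y_list, x_list, f_list = [], [], []
    x_guess = system.x0
    for i in range(n_stages):
        theta = system.with_theta(**{schedule.parameter: schedule.values[i]})
        try:
            x_ss = steady_state(system, theta, system.u0, x_guess, tol=1e-10)
        except SteadyStateError as exc:
            raise SteadyStateError(
                f"no steady state at stage {i + 1}: {exc}"
            ) from exc
        x_list.append(x_ss)
        y_list.append(system.outputs(x_ss))
        f_list.append(fluxes(system, x_ss, theta, system.u0))
        x_guess = x_ss

    y_true = np.vstack(y_list)
    y_ref = y_true[0]
    obs_names = system.output_names
    n_obs = len(obs_names)

    if noise.sd_overrides is not None:
        sds_row = np.array([noise.sd_overrides[name] for name in obs_names])
        sds = np.tile(sds_row, (n_stages, 1))
    elif noise.per_stage_draw:
        sds = rng.uniform(0.0, noise.max_rel_sd * np.abs(y_ref), (n_stages, n_obs))
    else:
        sds_row = rng.uniform(0.0, noise.max_rel_sd * np.abs(y_ref), n_obs)
        sds = np.tile(sds_row, (n_stages, 1))

    means = y_true + rng.standard_normal((n_stages, n_obs)) * sds
    dataset = PhenotypeDataset(
        stage_times=np.asarray(schedule.stage_times, dtype=float),
        observable_names=obs_names,
        means=means,
        sds=sds,
    )
    truth = GroundTruth(
        stage_times=np.asarray(schedule.stage_times, dtype=float),
        staged_parameter=schedule.parameter,
        staged_values=np.asarray(schedule.values, dtype=float),
        state_names=list(system.state_names),
        reaction_names=list(system.reaction_names),
        steady_states=np.vstack(x_list),
        fluxes=np.vstack(f_list),
    )
    return dataset, truth


def ground_truth_fluxes(record: GroundTruth) -> np.ndarray:
    """Stage-wise true fluxes from a generation record, (n_stages, n_reactions)."""
    return record.fluxes.copy()
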