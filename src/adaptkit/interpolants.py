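"""Continuous descriptions of phenotype snapshot data.

Snapshot datasets hold per-stage means and standard deviations of the
observed outputs. To drive trajectory estimation they are turned into
continuous functions of time: cubic smoothing splines fitted to parametric
bootstrap replicates of the means, yielding an ensemble of data
interpolants whose spread reflects the measurement uncertainty.

Smoothing convention: the weight ``p`` in (0, 1] trades fidelity against
curvature in the classic cubic-smoothing-spline criterion

    p * sum_i (y_i - s(t_i))^2  +  (1 - p) * integral s''(t)^2 dt,

so p = 1 interpolates the points exactly and p -> 0 approaches the
least-squares straight line. The minimizer is the natural cubic spline
through the shrunk values g = (I + lam K)^-1 y with lam = (1 - p)/p and
K the usual curvature matrix (Green & Silverman's formulation); it is
computed directly, which keeps the fit exact down to two data points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "PhenotypeDataset",
    "Interpolant",
    "InterpolantEnsemble",
    "SigmaEnvelope",
    "bootstrap_sample",
    "fit_spline",
    "default_smoothing",
    "build_interpolant_ensemble",
    "sigma_envelope",
    "density_histogram",
]


@dataclass
class PhenotypeDataset:
    """Snapshot means d and standard deviations sigma per stage and observable.

    ``means`` and ``sds`` are (n_stages, n_observables) arrays; stage times
    are strictly increasing (long-time units, e.g. days).
    """

    stage_times: np.ndarray
    observable_names: list[str]
    means: np.ndarray
    sds: np.ndarray

    def __post_init__(self):
        self.stage_times = np.asarray(self.stage_times, dtype=float)
        self.means = np.atleast_2d(np.asarray(self.means, dtype=float))
        self.sds = np.atleast_2d(np.asarray(self.sds, dtype=float))
        if np.any(np.diff(self.stage_times) <= 0):
            raise ValueError("stage_times must be strictly increasing")
        shape = (len(self.stage_times), len(self.observable_names))
        if self.means.shape != shape or self.sds.shape != shape:
            raise ValueError(
                f"means/sds must have shape {shape}, got "
                f"{self.means.shape}/{self.sds.shape}"
            )
        if not np.all(np.isfinite(self.means)):
            raise ValueError("means must be finite")
        if np.any(self.sds < 0):
            raise ValueError("sds must be non-negative")

    @property
    def n_stages(self) -> int:
        return len(self.stage_times)

    @property
    def n_observables(self) -> int:
        return len(self.observable_names)

    def stage(self, i: int) -> "PhenotypeDataset":
        """Single-stage slice (keeps the stage's time stamp)."""
        return PhenotypeDataset(
            stage_times=self.stage_times[i : i + 1],
            observable_names=list(self.observable_names),
            means=self.means[i : i + 1].copy(),
            sds=self.sds[i : i + 1].copy(),
        )

    def with_sds(self, sds: np.ndarray) -> "PhenotypeDataset":
        return PhenotypeDataset(
            stage_times=self.stage_times.copy(),
            observable_names=list(self.observable_names),
            means=self.means.copy(),
            sds=np.asarray(sds, dtype=float).copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.stage_times):
            for j, name in enumerate(self.observable_names):
                rows.append(
                    {"time": t, "observable": name,
                     "mean": self.means[i, j], "sd": self.sds[i, j]}
                )
        return pd.DataFrame(rows, columns=["time", "observable", "mean", "sd"])

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PhenotypeDataset":
        times = np.sort(df["time"].unique())
        names = list(dict.fromkeys(df["observable"]))
        means = np.full((len(times), len(names)), np.nan)
        sds = np.zeros((len(times), len(names)))
        t_index = {t: i for i, t in enumerate(times)}
        o_index = {n: j for j, n in enumerate(names)}
        for _, row in df.iterrows():
            i, j = t_index[row["time"]], o_index[row["observable"]]
            means[i, j] = row["mean"]
            sds[i, j] = row["sd"]
        return cls(stage_times=times, observable_names=names, means=means, sds=sds)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PhenotypeDataset":
        return cls.from_frame(pd.read_csv(path))


def bootstrap_sample(
    dataset: PhenotypeDataset, rng: np.random.Generator
) -> PhenotypeDataset:
    """One parametric bootstrap replicate: means ~ Normal(d, sigma) elementwise.

    The replicate keeps the original standard deviations. With sigma = 0 the
    replicate equals the dataset. Negative draws are kept — the error model
    is unconditionally Gaussian.
    """
    noise = rng.standard_normal(dataset.means.shape) * dataset.sds
    return PhenotypeDataset(
        stage_times=dataset.stage_times.copy(),
        observable_names=list(dataset.observable_names),
        means=dataset.means + noise,
        sds=dataset.sds.copy(),
    )


def _curvature_matrix(times: np.ndarray) -> np.ndarray:
    """K = D' W^-1 D with D the second-difference map and W the curvature
    inner-product matrix, so that g' K g = integral of the squared second
    derivative of the natural cubic spline through g."""
    h = np.diff(times)
    n = times.size
    d = np.zeros((n - 2, n))
    w = np.zeros((n - 2, n - 2))
    for i in range(n - 2):
        d[i, i] = 1.0 / h[i]
        d[i, i + 1] = -1.0 / h[i] - 1.0 / h[i + 1]
        d[i, i + 2] = 1.0 / h[i + 1]
        w[i, i] = (h[i] + h[i + 1]) / 3.0
        if i + 1 < n - 2:
            w[i, i + 1] = w[i + 1, i] = h[i + 1] / 6.0
    return d.T @ np.linalg.solve(w, d)


def fit_spline(times: np.ndarray, values: np.ndarray, smoothing: float):
    """Cubic smoothing spline through (times, values) with weight p=smoothing.

    Minimizes p * RSS + (1-p) * curvature; smoothing = 1 interpolates
    exactly, smoothing -> 0 approaches the least-squares straight line.
    Returns a callable natural cubic spline defined on the data interval
    (continuous with continuous first derivative). Works from 2 points up
    (2 points: the connecting line).
    """
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if times.size < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing (no duplicates)")
    if not 0.0 < smoothing <= 1.0:
        raise ValueError("smoothing must lie in (0, 1]")
    lam = (1.0 - smoothing) / smoothing
    if times.size == 2 or lam == 0.0:
        g = values
    else:
        k = _curvature_matrix(times)
        g = np.linalg.solve(np.eye(times.size) + lam * k, values)
    return CubicSpline(times, g, bc_type="natural")


def default_smoothing(stage_times: np.ndarray) -> float:
    """Heuristic default weight p = 1 / (1 + h^3/6), h = mean stage spacing."""
    h = float(np.mean(np.diff(np.asarray(stage_times, dtype=float))))
    return 1.0 / (1.0 + h**3 / 6.0)


@dataclass
class Interpolant:
    """Per-observable continuous data description over the stage interval."""

    observable_names: list[str]
    splines: list
    t_min: float
    t_max: float
    smoothing: float

    @classmethod
    def fit(cls, dataset: PhenotypeDataset, smoothing: float | None = None):
        p = default_smoothing(dataset.stage_times) if smoothing is None else smoothing
        splines = [
            fit_spline(dataset.stage_times, dataset.means[:, j], p)
            for j in range(dataset.n_observables)
        ]
        return cls(
            observable_names=list(dataset.observable_names),
            splines=splines,
            t_min=float(dataset.stage_times[0]),
            t_max=float(dataset.stage_times[-1]),
            smoothing=p,
        )

    def __call__(self, t: float) -> np.ndarray:
        """Vector of all observables at time t (within the stage interval)."""
        return np.array([float(s(t)) for s in self.splines])

    def component(self, name: str):
        return self.splines[self.observable_names.index(name)]


@dataclass
class InterpolantEnsemble:
    """Bootstrap-sampled distribution of data interpolants."""

    interpolants: list[Interpolant]
    replicates: list[PhenotypeDataset]
    seed: int | None
    smoothing: float

    def __len__(self) -> int:
        return len(self.interpolants)

    def curves(self, observable: str):
        return [itp.component(observable) for itp in self.interpolants]

    def to_json_dict(self, t_grid: np.ndarray) -> dict:
        t_grid = np.asarray(t_grid, dtype=float)
        return {
            "seed": self.seed,
            "smoothing": self.smoothing,
            "observables": list(self.interpolants[0].observable_names),
            "t_grid": t_grid.tolist(),
            "curves": [
                [[float(t), *map(float, itp(t))] for t in t_grid]
                for itp in self.interpolants
            ],
        }


def build_interpolant_ensemble(
    dataset: PhenotypeDataset,
    n: int = 1000,
    smoothing: float | None = None,
    rng: np.random.Generator | int | None = None,
) -> InterpolantEnsemble:
    """Fit one smoothing spline per bootstrap replicate, n replicates.

    The smoothing weight is fixed once for the whole ensemble (default: the
    spacing heuristic on the dataset's stage times). Reproducible from the
    seed/generator.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    p = default_smoothing(dataset.stage_times) if smoothing is None else smoothing
    replicates, interpolants = [], []
    for k in range(n):
        rep = bootstrap_sample(dataset, gen)
        try:
            interpolants.append(Interpolant.fit(rep, p))
        except Exception as exc:  # pragma: no cover - propagated with context
            raise RuntimeError(f"spline fit failed for replicate {k}") from exc
        replicates.append(rep)
    return InterpolantEnsemble(
        interpolants=interpolants, replicates=replicates, seed=seed, smoothing=p
    )


@dataclass
class SigmaEnvelope:
    """Continuous per-observable SD function sigma(t).

    Piecewise-linear interpolation of the per-stage standard deviations,
    floored at eps_j = max(floor_rel * max_t |d_tj|, floor_rel) per
    observable so that weighted residuals stay finite and measurement
    weights never exceed a plausible assay precision.
    """

    stage_times: np.ndarray
    sds: np.ndarray
    floors: np.ndarray

    def __call__(self, t: float) -> np.ndarray:
        vals = np.array(
            [
                np.interp(t, self.stage_times, self.sds[:, j])
                for j in range(self.sds.shape[1])
            ]
        )
        return np.maximum(vals, self.floors)


def sigma_envelope(dataset: PhenotypeDataset, floor_rel: float = 0.01) -> SigmaEnvelope:
    """Build the continuous SD envelope for a dataset (see SigmaEnvelope)."""
    floors = floor_rel * np.maximum(np.max(np.abs(dataset.means), axis=0), 1.0)
    return SigmaEnvelope(
        stage_times=dataset.stage_times.copy(),
        sds=dataset.sds.copy(),
        floors=floors,
    )


def density_histogram(
    curves: list, t_grid: np.ndarray, v_bins: np.ndarray
) -> np.ndarray:
    """2-D density of an ensemble of time-functions.

    counts[b, t] = number of curves whose value at t_grid[t] falls in value
    bin b. Bins are left-closed/right-open, the last bin closed (numpy
    convention); each column sums to the number of curves inside the
    binned range at that time.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    v_bins = np.asarray(v_bins, dtype=float)
    if t_grid.size == 0:
        raise ValueError("t_grid must be non-empty")
    if not curves:
        raise ValueError("need at least one curve")
    if np.any(np.diff(v_bins) <= 0):
        raise ValueError("v_bins must be strictly increasing")
    counts = np.zeros((v_bins.size - 1, t_grid.size), dtype=int)
    for k, t in enumerate(t_grid):
        vals = np.array([float(c(t)) for c in curves])
        counts[:, k], _ = np.histogram(vals, bins=v_bins)
    return counts
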