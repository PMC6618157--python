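"""Simulation experiments: edge-case sweeps, response curves, hypercube.

Three *edge-case* scenarios vary one coevolutionary parameter while the
other two are pinned to extreme values:

* ``speciation_only``: vary Lambda; M = 0, P = 0;
* ``migration_only``:  vary M; Lambda = 1, P = 1;
* ``cospeciation_only``: vary P; Lambda = 1e-6, M = 0.

For each grid value a batch of replicate pathogen trees is simulated and
each distance measure is averaged over the batch; the per-measure mean
curves are rescaled to [0, 1] over the grid and summarized by the
parameter value where they cross 0.5 (Lambda50 / M50 / P50), a compact
sensitivity landmark.  The ``hypercube`` design jointly varies all three
parameters with Latin hypercube sampling: Lambda and M partitioned into
log-spaced intervals over [1e-6, 1] (a log partition of [0, 1] is not
defined at 0, so the smallest simulated rate serves as the lower bound),
P into linear intervals over [0, 1], each interval used exactly once.

Replicate r at design point i draws its simulator seed from
``SeedSequence(master_seed, spawn_key=(i, r))`` so results are
reproducible and replicates independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CophyloError, CurveError
from .distances import MEASURES, compute_all
from .simulator import SimParams, simulate
from .treecore import TimeTree

__all__ = [
    "SweepDesign",
    "ResponseCurve",
    "X50",
    "lhs_design",
    "run_sweep",
    "run_hypercube",
    "scale_curve",
    "estimate_x50",
    "replicate_seed",
    "SCENARIOS",
]

# fixed values and default grids per edge-case scenario
SCENARIOS = {
    "speciation_only": {
        "varies": "Lambda",
        "fixed": {"M": 0.0, "P": 0.0},
        "grid": np.geomspace(1e-6, 1.0, 20),
        "log_axis": True,
    },
    "migration_only": {
        "varies": "M",
        "fixed": {"Lambda": 1.0, "P": 1.0},
        "grid": np.geomspace(1e-6, 1.0, 20),
        "log_axis": True,
    },
    "cospeciation_only": {
        "varies": "P",
        "fixed": {"Lambda": 1e-6, "M": 0.0},
        "grid": np.linspace(0.0, 1.0, 21),
        "log_axis": False,
    },
}


@dataclass
class SweepDesign:
    """An edge-case sweep or hypercube design."""

    scenario: str
    grid: np.ndarray | None = None  # edge-case scenarios
    points: pd.DataFrame | None = None  # hypercube: columns Lambda, M, P
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.scenario not in (*SCENARIOS, "hypercube"):
            raise CophyloError(f"unknown scenario {self.scenario!r}")
        if self.n_replicates < 1:
            raise CophyloError("n_replicates must be >= 1")
        if self.scenario == "hypercube":
            if self.points is None:
                raise CophyloError("hypercube design needs a points table")
        elif self.grid is None:
            self.grid = SCENARIOS[self.scenario]["grid"]

    def parameter_points(self) -> pd.DataFrame:
        """One row per design point with columns Lambda, M, P."""
        if self.scenario == "hypercube":
            return self.points[["Lambda", "M", "P"]].reset_index(drop=True)
        info = SCENARIOS[self.scenario]
        rows = []
        for value in np.asarray(self.grid, dtype=float):
            row = dict(info["fixed"])
            row[info["varies"]] = float(value)
            rows.append(row)
        return pd.DataFrame(rows)[["Lambda", "M", "P"]]


def replicate_seed(master_seed: int, point: int, rep: int) -> int:
    """Deterministic per-replicate simulator seed (< 2**31)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(point), int(rep)))
    return int(ss.generate_state(1)[0] % (2**31))


def lhs_design(
    n_points: int,
    ranges: dict[str, tuple[float, float, str]] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Latin hypercube sample over (Lambda, M, P).

    Each axis is partitioned into ``n_points`` intervals -- log-spaced for
    axes marked ``"log"``, equal-width otherwise -- a random permutation
    assigns one interval per axis to each point, and a point is drawn
    uniformly inside each interval.  Every interval index is used exactly
    once per axis (the Latin property).
    """
    if n_points < 1:
        raise CophyloError("n_points must be >= 1")
    ranges = ranges or {
        "Lambda": (1e-6, 1.0, "log"),
        "M": (1e-6, 1.0, "log"),
        "P": (0.0, 1.0, "linear"),
    }
    rng = np.random.default_rng(seed)
    columns = {}
    for name, (lo, hi, scale) in ranges.items():
        if scale == "log":
            if lo <= 0:
                raise CophyloError(f"log axis {name!r} needs a positive lower bound")
            edges = np.geomspace(lo, hi, n_points + 1)
        elif scale == "linear":
            edges = np.linspace(lo, hi, n_points + 1)
        else:
            raise CophyloError(f"unknown axis scale {scale!r}")
        perm = rng.permutation(n_points)
        u = rng.random(n_points)
        lows, highs = edges[perm], edges[perm + 1]
        columns[name] = lows + u * (highs - lows)
        columns[f"{name}_interval"] = perm
    df = pd.DataFrame(columns)
    return df


def _measure_table(host, points, n_replicates, measures, seed) -> pd.DataFrame:
    """Simulate and measure: long table (point, Lambda, M, P, measure, mean, sd, cv)."""
    measures = list(measures)
    records = []
    for i, row in points.iterrows():
        values = {m: [] for m in measures}
        for r in range(n_replicates):
            params = SimParams(
                Lambda=row["Lambda"], M=row["M"], P=row["P"],
                seed=replicate_seed(seed, i, r),
            )
            try:
                result = simulate(host, params)
                d = compute_all(result.collapsed_tree, host, measures,
                                options={"seed": params.seed})
            except CophyloError as exc:
                raise type(exc)(
                    f"design point {i} (Lambda={row['Lambda']:.3g}, M={row['M']:.3g}, "
                    f"P={row['P']:.3g}), replicate {r}: {exc}"
                ) from exc
            for m in measures:
                values[m].append(d[m])
        for m in measures:
            arr = np.asarray(values[m])
            mean = float(arr.mean())
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            records.append({
                "point": i,
                "Lambda": row["Lambda"], "M": row["M"], "P": row["P"],
                "measure": m, "mean": mean, "sd": sd,
                "cv": sd / mean if mean > 0 else np.nan,
            })
    return pd.DataFrame.from_records(records)


def run_sweep(
    host: TimeTree,
    design: SweepDesign,
    measures: list[str] | None = None,
) -> pd.DataFrame:
    """Run an edge-case sweep (or hypercube) and tabulate per-point stats.

    Returns a long-format table with one row per (design point, measure)
    carrying the replicate mean, standard deviation and CV = sd/mean.
    Deterministic for a fixed (host, design, seed).
    """
    measures = measures or list(MEASURES)
    points = design.parameter_points()
    return _measure_table(host, points, design.n_replicates, measures, design.seed)


def run_hypercube(
    host: TimeTree,
    n_points: int = 500,
    n_replicates: int = 100,
    measures: list[str] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """LHS design + sweep; wide table of mean distances (points x measures).

    Rows carry the sampled (Lambda, M, P); columns the replicate-mean of
    each measure against the host tree.
    """
    design_df = lhs_design(n_points, seed=seed)
    design = SweepDesign("hypercube", points=design_df,
                         n_replicates=n_replicates, seed=seed)
    long = run_sweep(host, design, measures)
    wide = long.pivot_table(index=["point", "Lambda", "M", "P"],
                            columns="measure", values="mean").reset_index()
    wide.columns.name = None
    return wide


def scale_curve(means: np.ndarray) -> np.ndarray:
    """Rescale a mean-distance curve to span [0, 1] over its grid."""
    means = np.asarray(means, dtype=float)
    lo, hi = means.min(), means.max()
    if hi <= lo:
        raise CurveError("constant curve cannot be rescaled (non-informative measure)")
    return (means - lo) / (hi - lo)


@dataclass
class X50:
    """A 0.5 crossing of a scaled response curve."""

    value: float
    n_crossings: int = 1


def estimate_x50(scaled: np.ndarray, grid: np.ndarray, log_axis: bool = False) -> X50:
    """Parameter value where a scaled curve first crosses 0.5.

    Linear interpolation between the bracketing grid points, on the log
    scale for log axes; multiple crossings are flagged via
    ``n_crossings``.
    """
    scaled = np.asarray(scaled, dtype=float)
    grid = np.asarray(grid, dtype=float)
    above = scaled >= 0.5
    crossings = []
    for k in range(len(grid) - 1):
        if above[k] != above[k + 1]:
            x0, x1 = grid[k], grid[k + 1]
            y0, y1 = scaled[k], scaled[k + 1]
            if log_axis:
                x0, x1 = np.log(x0), np.log(x1)
            frac = (0.5 - y0) / (y1 - y0)
            x = x0 + frac * (x1 - x0)
            crossings.append(np.exp(x) if log_axis else x)
    if np.any(scaled == 0.5):
        for k in np.nonzero(scaled == 0.5)[0]:
            crossings.append(float(grid[k]))
    if not crossings:
        raise CurveError("scaled curve never crosses 0.5")
    crossings = sorted(set(float(c) for c in crossings))
    return X50(value=crossings[0], n_crossings=len(crossings))


@dataclass
class ResponseCurve:
    """Per-measure response of mean distance to one swept parameter."""

    parameter: str
    grid: np.ndarray
    table: pd.DataFrame  # long table restricted to one scenario
    log_axis: bool = False

    @classmethod
    def from_sweep(cls, sweep_table: pd.DataFrame, scenario: str) -> "ResponseCurve":
        info = SCENARIOS[scenario]
        param = info["varies"]
        grid = np.sort(sweep_table[param].unique())
        return cls(parameter=param, grid=grid, table=sweep_table,
                   log_axis=info["log_axis"])

    def means(self, measure: str) -> np.ndarray:
        sub = self.table[self.table["measure"] == measure]
        sub = sub.sort_values(self.parameter)
        return sub["mean"].to_numpy()

    def cv(self, measure: str) -> np.ndarray:
        sub = self.table[self.table["measure"] == measure]
        return sub.sort_values(self.parameter)["cv"].to_numpy()

    def scaled(self, measure: str) -> np.ndarray:
        return scale_curve(self.means(measure))

    def x50(self, measure: str) -> X50:
        return estimate_x50(self.scaled(measure), self.grid, log_axis=self.log_axis)
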