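"""Sparsity sweep: threshold a connectivity matrix over a grid of network
sparsities, compute every global and nodal metric at each point, and
summarize each metric curve by its trapezoidal area under the curve (AUC).

The AUC removes the arbitrariness of any single threshold: a metric that is
constant at c over a grid spanning [s_min, s_max] has AUC c * (s_max - s_min).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .graph import binarize_by_sparsity, global_metrics, nodal_metrics, path_census
from .nulls import NullConfig, normalize_small_world

__all__ = [
    "SparsityGrid",
    "MetricCurve",
    "AUCRecord",
    "SubjectSweep",
    "GLOBAL_METRIC_NAMES",
    "NODAL_METRIC_NAMES",
    "run_sweep",
    "auc",
]

GLOBAL_METRIC_NAMES = ("c_p", "l_p", "gamma", "lambda", "sigma", "e_glob", "e_loc")
NODAL_METRIC_NAMES = ("degree", "efficiency", "betweenness")


@dataclass(frozen=True)
class SparsityGrid:
    """Evenly spaced sparsity thresholds s_min, s_min + step, ..., s_max."""

    s_min: float = 0.10
    s_max: float = 0.42
    s_step: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 < self.s_min <= self.s_max < 1.0:
            raise ValueError("need 0 < s_min <= s_max < 1")
        if self.s_step <= 0:
            raise ValueError("s_step must be positive")

    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        grid = self.s_min + self.s_step * np.arange(n)
        return np.round(grid, 10)

    @property
    def n_points(self) -> int:
        return self.values().size


@dataclass
class MetricCurve:
    """One network metric as a function of sparsity for one subject."""

    metric_name: str
    values: np.ndarray
    subject_id: Optional[str] = None
    region: Optional[int] = None  # 1-based ROI index for nodal curves


@dataclass
class AUCRecord:
    metric_name: str
    auc: float
    subject_id: Optional[str] = None
    region: Optional[int] = None
    flagged_nonfinite: bool = False


@dataclass
class SubjectSweep:
    """All metric curves for one subject over a sparsity grid.

    ``global_curves`` maps metric name -> vector over grid points;
    ``nodal_curves`` maps metric name -> (N x n_grid) array.
    """

    subject_id: Optional[str]
    grid: SparsityGrid
    global_curves: dict[str, np.ndarray] = field(default_factory=dict)
    nodal_curves: dict[str, np.ndarray] = field(default_factory=dict)

    def curve(self, metric_name: str, region: Optional[int] = None) -> MetricCurve:
        if region is None:
            return MetricCurve(metric_name, self.global_curves[metric_name], self.subject_id)
        return MetricCurve(
            metric_name, self.nodal_curves[metric_name][region - 1], self.subject_id, region
        )


def run_sweep(
    conn,
    grid: SparsityGrid = SparsityGrid(),
    null_cfg: Optional[NullConfig] = NullConfig(),
    seed: int = 0,
    path_length: str = "harmonic",
    include_nodal: bool = True,
    include_global: bool = True,
) -> SubjectSweep:
    """Binarize, measure, and normalize one subject over the sparsity grid.

    Null-model RNG streams are derived from (seed, sparsity index), so each
    threshold's normalization is reproducible independently of the others.
    With ``null_cfg=None`` the normalized metrics (gamma, lambda, sigma) are
    skipped; with ``include_global=False`` all global curves are skipped,
    which is much faster when only nodal curves are needed.
    """
    svals = grid.values()
    n_grid = svals.size
    subject_id = getattr(conn, "subject_id", None)
    result = SubjectSweep(subject_id=subject_id, grid=grid)

    g0 = None
    glob: dict[str, np.ndarray] = (
        {m: np.empty(n_grid) for m in GLOBAL_METRIC_NAMES} if include_global else {}
    )
    if include_global and null_cfg is None:
        for m in ("gamma", "lambda", "sigma"):
            del glob[m]
    nodal: dict[str, np.ndarray] = {}
    null_seeds = np.random.SeedSequence(seed).generate_state(n_grid) % (2**31)

    for t, s in enumerate(svals):
        g = binarize_by_sparsity(conn, float(s))
        if g0 is None:
            n_nodes = g.n_nodes
            if include_nodal:
                nodal = {m: np.empty((n_nodes, n_grid)) for m in NODAL_METRIC_NAMES}
            g0 = g
        census = path_census(g, compute_betweenness=include_nodal)
        if include_global:
            gm = global_metrics(g, census=census, path_length=path_length)
            glob["c_p"][t] = gm.c_p
            glob["l_p"][t] = gm.l_p
            glob["e_glob"][t] = gm.e_glob
            glob["e_loc"][t] = gm.e_loc
        if include_global and null_cfg is not None:
            nsw = normalize_small_world(
                g,
                n_null=null_cfg.n_null,
                swap_factor=null_cfg.swap_factor,
                seed=int(null_seeds[t]),
                real_c_p=gm.c_p,
                real_l_p=(1.0 / gm.e_glob if gm.e_glob > 0 else math.inf),
            )
            glob["gamma"][t] = nsw.gamma
            glob["lambda"][t] = nsw.lam
            glob["sigma"][t] = nsw.sigma
        if include_nodal:
            nm = nodal_metrics(g, census=census)
            nodal["degree"][:, t] = nm.degree
            nodal["efficiency"][:, t] = nm.efficiency
            nodal["betweenness"][:, t] = nm.betweenness

    result.global_curves = glob
    result.nodal_curves = nodal
    return result


def auc(curve, grid: SparsityGrid):
    """Trapezoidal AUC of a metric curve over the sparsity grid.

    Accepts a MetricCurve (returns an AUCRecord) or a plain vector (returns a
    float).  Any non-finite value makes the AUC undefined: the record is
    flagged with NaN (plain vectors raise).
    """
    svals = grid.values()
    values = curve.values if isinstance(curve, MetricCurve) else np.asarray(curve, float)
    if values.shape[-1] != svals.size:
        raise ValueError("curve length does not match grid size")
    finite = np.isfinite(values).all()
    if isinstance(curve, MetricCurve):
        if not finite:
            return AUCRecord(curve.metric_name, math.nan, curve.subject_id, curve.region, True)
        return AUCRecord(
            curve.metric_name,
            float(np.trapezoid(values, svals)),
            curve.subject_id,
            curve.region,
        )
    if not finite:
        raise ValueError("curve contains non-finite values; AUC undefined")
    return np.trapezoid(values, svals, axis=-1)
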