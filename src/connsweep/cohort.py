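"""Synthetic two-group resting-state ROI time-series cohorts.

Real resting-state BOLD data for a small expert/novice cohort are simulated
as band-limited, temporally autocorrelated multivariate Gaussian signals
whose population covariance carries a small-world (ring-lattice plus random
rewiring) topology.  A localized group effect is planted by incrementing the
covariance on existing lattice edges among a designated ROI set, which shifts
the nodal centrality of those regions in one group only.

The generator exists so the full pipeline (preprocessing, connectivity,
sparsity sweep, null-model normalization, permutation inference) can be run
and validated end to end without any scan data.  Every random draw is owned
by a numpy Generator seeded from ``CohortSpec.seed``; identical specs yield
bit-identical cohorts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import networkx as nx
import numpy as np

__all__ = [
    "BaseGraphConfig",
    "NuisanceConfig",
    "CohortSpec",
    "SubjectTimeSeries",
    "build_base_adjacency",
    "build_group_covariance",
    "simulate_subject",
    "generate_cohort",
]

N_CONFOUNDS = 8  # global signal walk + linear drift + six motion-like series


@dataclass(frozen=True)
class BaseGraphConfig:
    """Watts-Strogatz base topology for the planted covariance."""

    neighbors_k: int = 10
    rewire_prob: float = 0.1

    def validate(self, n_rois: int) -> None:
        if self.neighbors_k < 2 or self.neighbors_k % 2 != 0:
            raise ValueError("neighbors_k must be an even count >= 2")
        if self.neighbors_k >= n_rois:
            raise ValueError("neighbors_k must be smaller than n_rois")
        if not 0.0 <= self.rewire_prob <= 1.0:
            raise ValueError("rewire_prob must be a probability")


@dataclass(frozen=True)
class NuisanceConfig:
    """Amplitudes of shared confound components (unit-variance regressors)."""

    global_amp: float = 1.0
    drift_amp: float = 1.0
    motion_amp: float = 0.3

    def validate(self) -> None:
        if min(self.global_amp, self.drift_amp, self.motion_amp) < 0:
            raise ValueError("nuisance amplitudes must be nonnegative")


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic two-group cohort.

    Defaults mirror the study conditions: 17 experts vs 16 novices, 110 ROIs,
    120 volumes at TR = 2.34 s (first 4 discarded downstream), and expert
    training durations of 12.47 +/- 1.50 years.
    """

    n_group_a: int = 17
    n_group_b: int = 16
    n_rois: int = 110
    n_volumes: int = 120
    n_discard: int = 4
    tr_seconds: float = 2.34
    base_graph: BaseGraphConfig = field(default_factory=BaseGraphConfig)
    edge_weight: float = 0.25
    diag_boost: float = 1.5
    effect_rois: tuple[int, ...] = (106, 107, 108, 109, 110)  # 1-based
    effect_delta: float = 0.35
    ar_coefficient: float = 0.3
    nuisance: NuisanceConfig = field(default_factory=NuisanceConfig)
    training_mean_years: float = 12.47
    training_sd_years: float = 1.50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_volumes <= self.n_discard:
            raise ValueError("n_volumes must exceed n_discard")
        if self.n_rois < 3:
            raise ValueError("n_rois must be >= 3")
        if self.n_group_a < 1 or self.n_group_b < 1:
            raise ValueError("both groups need at least one subject")
        if self.edge_weight <= 0 or self.diag_boost <= 0:
            raise ValueError("edge_weight and diag_boost must be positive")
        if not 0.0 <= self.ar_coefficient < 1.0:
            raise ValueError("ar_coefficient must lie in [0, 1)")
        if self.training_sd_years <= 0:
            raise ValueError("training_sd_years must be positive")
        bad = [r for r in self.effect_rois if not 1 <= r <= self.n_rois]
        if bad:
            raise ValueError(f"effect_rois out of range 1..{self.n_rois}: {bad}")
        if len(set(self.effect_rois)) != len(self.effect_rois):
            raise ValueError("effect_rois contains duplicates")
        self.base_graph.validate(self.n_rois)
        self.nuisance.validate()

    @property
    def n_subjects(self) -> int:
        return self.n_group_a + self.n_group_b

    def roi_labels(self) -> list[str]:
        return [f"ROI{idx:03d}" for idx in range(1, self.n_rois + 1)]


@dataclass
class SubjectTimeSeries:
    """One subject's T x N ROI signal matrix with acquisition metadata.

    ``confounds`` holds the exact nuisance regressors that were added during
    simulation (T x 8), so preprocessing can regress the true confounds.
    """

    subject_id: str
    group: str  # "A" (expert-like) or "B" (novice-like)
    data: np.ndarray
    tr_seconds: float
    training_years: Optional[float] = None
    confounds: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be a T x N matrix")
        if self.data.shape[0] < 8:
            raise ValueError("need at least 8 timepoints")
        if not np.isfinite(self.data).all():
            raise ValueError("time series contains non-finite values")
        if self.group not in ("A", "B"):
            raise ValueError(f"unknown group label {self.group!r}")
        if self.confounds is not None:
            self.confounds = np.asarray(self.confounds, dtype=float)
            if self.confounds.shape[0] != self.data.shape[0]:
                raise ValueError("confounds must have one row per volume")

    @property
    def n_timepoints(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


def build_base_adjacency(spec: CohortSpec) -> np.ndarray:
    """Watts-Strogatz adjacency shared by the two groups (0/1, symmetric).

    Deterministic in ``spec.seed``; the rewiring RNG stream is separate from
    the per-subject noise streams.
    """
    graph_seed = int(np.random.SeedSequence([spec.seed, 0x5757]).generate_state(1)[0] % (2**31))
    g = nx.watts_strogatz_graph(
        spec.n_rois, spec.base_graph.neighbors_k, spec.base_graph.rewire_prob, seed=graph_seed
    )
    a = nx.to_numpy_array(g, nodelist=range(spec.n_rois), dtype=float)
    return a


def build_group_covariance(
    spec: CohortSpec, group: str, base_adjacency: Optional[np.ndarray] = None
) -> np.ndarray:
    """Population covariance ``edge_weight * A + diag_boost * I`` for a group.

    For group "A" only, entries (i, j) with both ROIs in ``effect_rois`` and
    A_ij = 1 are incremented by ``effect_delta``.  Raises if the result is not
    positive-definite.
    """
    if group not in ("A", "B"):
        raise ValueError(f"unknown group label {group!r}")
    a = build_base_adjacency(spec) if base_adjacency is None else np.asarray(base_adjacency, float)
    cov = spec.edge_weight * a + spec.diag_boost * np.eye(spec.n_rois)
    if group == "A" and spec.effect_delta != 0.0 and len(spec.effect_rois) >= 2:
        idx = np.asarray(spec.effect_rois, dtype=int) - 1
        sub = np.ix_(idx, idx)
        cov[sub] += spec.effect_delta * a[sub]
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig <= 0.0:
        raise ValueError(
            f"constructed covariance is not positive-definite "
            f"(smallest eigenvalue {min_eig:.6g})"
        )
    return cov


def _standardize(x: np.ndarray) -> np.ndarray:
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _make_confounds(n_volumes: int, rng: np.random.Generator) -> np.ndarray:
    """T x 8 unit-variance confound regressors (pre-amplitude)."""
    cols = []
    cols.append(_standardize(np.cumsum(rng.standard_normal(n_volumes))))  # global walk
    drift = np.linspace(-1.0, 1.0, n_volumes) * rng.choice([-1.0, 1.0])
    cols.append(_standardize(drift))
    for _ in range(6):  # motion-like slow drifts
        cols.append(_standardize(np.cumsum(rng.standard_normal(n_volumes))))
    return np.column_stack(cols)


def simulate_subject(
    cov: np.ndarray,
    spec: CohortSpec,
    subject_seed: int,
    subject_id: str = "sub",
    group: str = "A",
    training_years: Optional[float] = None,
) -> SubjectTimeSeries:
    """Simulate one subject: MVN draws, AR(1) smoothing, shared confounds.

    Rows are i.i.d. N(0, cov) before AR(1) smoothing with
    ``x_t <- phi x_{t-1} + sqrt(1 - phi^2) x_t``, which preserves the
    stationary covariance.  Confounds (scaled by the spec amplitudes) are then
    added: a global random-walk signal to every ROI, one linear drift, and six
    motion-like regressors entering each ROI with N(0,1) loadings.
    """
    cov = np.asarray(cov, dtype=float)
    rng = np.random.default_rng(subject_seed)
    t = spec.n_volumes
    n = cov.shape[0]
    chol = np.linalg.cholesky(cov)
    x = rng.standard_normal((t, n)) @ chol.T

    phi = spec.ar_coefficient
    if phi > 0.0:
        scale = math.sqrt(1.0 - phi * phi)
        for k in range(1, t):
            x[k] = phi * x[k - 1] + scale * x[k]

    confounds = _make_confounds(t, rng)
    amps = spec.nuisance
    if amps.global_amp > 0:
        x += amps.global_amp * confounds[:, [0]]
    if amps.drift_amp > 0:
        x += amps.drift_amp * confounds[:, [1]]
    if amps.motion_amp > 0:
        loadings = rng.standard_normal((6, n))
        x += amps.motion_amp * (confounds[:, 2:] @ loadings)

    return SubjectTimeSeries(
        subject_id=subject_id,
        group=group,
        data=x,
        tr_seconds=spec.tr_seconds,
        training_years=training_years,
        confounds=confounds,
    )


def subject_seeds(spec: CohortSpec) -> np.ndarray:
    """Deterministic per-subject seeds (< 2**31) derived from ``spec.seed``."""
    ss = np.random.SeedSequence([spec.seed, 0x5ab])
    return ss.generate_state(spec.n_subjects) % (2**31)


def _draw_training_years(spec: CohortSpec, rng: np.random.Generator) -> np.ndarray:
    """Normal(mean, sd) truncated at zero by redrawing."""
    out = rng.normal(spec.training_mean_years, spec.training_sd_years, spec.n_group_a)
    for _ in range(100):
        neg = out < 0
        if not neg.any():
            break
        out[neg] = rng.normal(spec.training_mean_years, spec.training_sd_years, int(neg.sum()))
    return np.maximum(out, 0.0)


def generate_cohort(spec: CohortSpec):
    """Generate the full cohort.

    Returns ``(subjects, manifest)`` where ``manifest`` is a pandas DataFrame
    with columns subject_id, group, training_years, seed.
    """
    import pandas as pd

    base = build_base_adjacency(spec)
    cov_a = build_group_covariance(spec, "A", base)
    cov_b = build_group_covariance(spec, "B", base)

    train_rng = np.random.default_rng(
        int(np.random.SeedSequence([spec.seed, 0x7ea]).generate_state(1)[0])
    )
    training = _draw_training_years(spec, train_rng)

    seeds = subject_seeds(spec)
    subjects: list[SubjectTimeSeries] = []
    rows = []
    for i in range(spec.n_subjects):
        in_a = i < spec.n_group_a
        group = "A" if in_a else "B"
        sid = f"{'expert' if in_a else 'novice'}{(i if in_a else i - spec.n_group_a) + 1:02d}"
        years = float(training[i]) if in_a else None
        subj = simulate_subject(
            cov_a if in_a else cov_b,
            spec,
            int(seeds[i]),
            subject_id=sid,
            group=group,
            training_years=years,
        )
        subjects.append(subj)
        rows.append(
            {"subject_id": sid, "group": group, "training_years": years, "seed": int(seeds[i])}
        )
    manifest = pd.DataFrame(rows)
    return subjects, manifest
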