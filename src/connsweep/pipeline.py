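"""End-to-end orchestration: cohort -> preprocessing -> connectivity ->
sparsity sweep -> AUC -> permutation inference -> training correlations.

One master seed fixes every random draw (cohort simulation, null-model
rewiring per subject and threshold, permutation splits), so two runs from
the same seed agree bit for bit.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, SubjectTimeSeries, generate_cohort
from .inference import correlate_training, flag_changed_regions, permutation_test_table
from .nulls import NullConfig
from .preprocess import PreprocessConfig, correlation_matrix, preprocess
from .sweep import GLOBAL_METRIC_NAMES, NODAL_METRIC_NAMES, SparsityGrid, auc, run_sweep

logger = logging.getLogger(__name__)

__all__ = ["AnalysisConfig", "CohortAnalysis", "sweep_cohort", "analyze_cohort", "run_all"]


@dataclass(frozen=True)
class AnalysisConfig:
    grid: SparsityGrid = field(default_factory=SparsityGrid)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    null_cfg: Optional[NullConfig] = field(default_factory=NullConfig)
    n_perm: int = 5000
    alpha: float = 0.05
    alpha_family: float = 0.05
    path_length: str = "harmonic"
    seed: int = 0
    n_jobs: int = 1


@dataclass
class CohortAnalysis:
    """Everything the inference stage produces for one cohort."""

    global_auc: pd.DataFrame  # subjects x 7 metrics
    nodal_auc: dict[str, pd.DataFrame]  # metric -> subjects x regions
    groups: pd.Series
    training_years: pd.Series
    global_comparison: pd.DataFrame
    nodal_results: dict[str, pd.DataFrame]
    flagged_regions: pd.DataFrame
    training_correlations: pd.DataFrame
    sigma_curves: Optional[pd.DataFrame] = None  # subjects x grid points
    run_record: dict = field(default_factory=dict)

    def nodal_auc_tidy(self) -> pd.DataFrame:
        frames = []
        for metric, df in self.nodal_auc.items():
            t = df.stack().rename("auc").reset_index()
            t.columns = ["subject_id", "region", "auc"]
            t.insert(1, "metric", metric)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _subject_sweep_seeds(seed: int, n_subjects: int) -> np.ndarray:
    return np.random.SeedSequence([seed, 0x10ad]).generate_state(n_subjects) % (2**31)


def sweep_cohort(
    subjects: Sequence[SubjectTimeSeries],
    cfg: AnalysisConfig,
    roi_labels: Optional[Sequence[str]] = None,
    include_nodal: bool = True,
):
    """Preprocess every subject, build Fisher-z connectivity, run the sweep.

    Returns ``(sweeps, groups, training)``.  Per-subject null RNG streams are
    pre-assigned, so results do not depend on execution order or job count.
    """
    seeds = _subject_sweep_seeds(cfg.seed, len(subjects))

    def one(subj, s):
        pp = preprocess(subj, cfg.preprocess)
        conn = correlation_matrix(pp, roi_labels=roi_labels)
        return run_sweep(
            conn,
            grid=cfg.grid,
            null_cfg=cfg.null_cfg,
            seed=int(s),
            path_length=cfg.path_length,
            include_nodal=include_nodal,
        )

    if cfg.n_jobs != 1:
        from joblib import Parallel, delayed

        sweeps = Parallel(n_jobs=cfg.n_jobs)(
            delayed(one)(subj, s) for subj, s in zip(subjects, seeds)
        )
    else:
        sweeps = [one(subj, s) for subj, s in zip(subjects, seeds)]

    groups = pd.Series([s.group for s in subjects], index=[s.subject_id for s in subjects])
    training = pd.Series(
        [s.training_years for s in subjects], index=groups.index, dtype=float
    )
    return sweeps, groups, training


def analyze_cohort(
    subjects: Sequence[SubjectTimeSeries],
    cfg: AnalysisConfig = AnalysisConfig(),
    roi_labels: Optional[Sequence[str]] = None,
) -> CohortAnalysis:
    """Full analysis of an in-memory cohort."""
    sweeps, groups, training = sweep_cohort(subjects, cfg, roi_labels=roi_labels)
    n_rois = next(iter(sweeps[0].nodal_curves.values())).shape[0]
    region_ids = (
        list(roi_labels) if roi_labels is not None else [f"ROI{i:03d}" for i in range(1, n_rois + 1)]
    )

    global_names = [m for m in GLOBAL_METRIC_NAMES if m in sweeps[0].global_curves]
    global_auc = pd.DataFrame(
        {
            m: [auc(sw.global_curves[m], cfg.grid) for sw in sweeps]
            for m in global_names
        },
        index=groups.index,
    )
    nodal_auc = {
        m: pd.DataFrame(
            np.vstack([auc(sw.nodal_curves[m], cfg.grid) for sw in sweeps]),
            index=groups.index,
            columns=region_ids,
        )
        for m in NODAL_METRIC_NAMES
    }

    is_a = (groups == "A").to_numpy()
    perm_seeds = np.random.SeedSequence([cfg.seed, 0x9e4]).generate_state(4) % (2**31)

    glob_tbl = permutation_test_table(
        global_auc.loc[is_a], global_auc.loc[~is_a], n_perm=cfg.n_perm, seed=int(perm_seeds[0])
    )
    ga, gb = global_auc.loc[is_a], global_auc.loc[~is_a]
    global_comparison = pd.DataFrame(
        {
            "mean_A": ga.mean(),
            "sd_A": ga.std(ddof=1),
            "mean_B": gb.mean(),
            "sd_B": gb.std(ddof=1),
            "p": glob_tbl["p"],
            "direction": glob_tbl["direction"],
        }
    )

    nodal_results = {
        m: permutation_test_table(
            nodal_auc[m].loc[is_a],
            nodal_auc[m].loc[~is_a],
            n_perm=cfg.n_perm,
            seed=int(perm_seeds[1 + k]),
            metric_name=m,
        )
        for k, m in enumerate(NODAL_METRIC_NAMES)
    }
    flagged = flag_changed_regions(nodal_results, alpha=cfg.alpha)

    train_a = training[is_a].dropna()
    corr_frames = []
    if len(train_a) >= 3:
        for m in NODAL_METRIC_NAMES:
            tbl = correlate_training(
                nodal_auc[m].loc[train_a.index],
                train_a.to_numpy(),
                alpha_family=cfg.alpha_family,
            )
            tbl.insert(0, "metric", m)
            corr_frames.append(tbl)
        training_correlations = pd.concat(corr_frames)
    else:
        logger.warning("fewer than 3 subjects with training durations; skipping correlations")
        training_correlations = pd.DataFrame(
            columns=["metric", "r", "p", "significant_bonferroni", "significant_uncorrected"]
        )

    sigma_curves = None
    if "sigma" in global_names:
        sigma_curves = pd.DataFrame(
            np.vstack([sw.global_curves["sigma"] for sw in sweeps]),
            index=groups.index,
            columns=[f"{s:.2f}" for s in cfg.grid.values()],
        )

    record = {
        "package_version": __version__,
        "config": {
            "grid": dataclasses.asdict(cfg.grid),
            "preprocess": dataclasses.asdict(cfg.preprocess),
            "null_cfg": dataclasses.asdict(cfg.null_cfg) if cfg.null_cfg else None,
            "n_perm": cfg.n_perm,
            "alpha": cfg.alpha,
            "alpha_family": cfg.alpha_family,
            "path_length": cfg.path_length,
            "seed": cfg.seed,
        },
        "n_subjects": int(len(subjects)),
        "n_group_a": int(is_a.sum()),
        "n_group_b": int((~is_a).sum()),
        "n_rois": int(n_rois),
    }

    return CohortAnalysis(
        global_auc=global_auc,
        nodal_auc=nodal_auc,
        groups=groups,
        training_years=training,
        global_comparison=global_comparison,
        nodal_results=nodal_results,
        flagged_regions=flagged,
        training_correlations=training_correlations,
        sigma_curves=sigma_curves,
        run_record=record,
    )


def run_all(
    spec: CohortSpec,
    cfg: AnalysisConfig = AnalysisConfig(),
    roi_labels: Optional[Sequence[str]] = None,
) -> CohortAnalysis:
    """Generate a synthetic cohort from ``spec`` and analyze it."""
    subjects, manifest = generate_cohort(spec)
    result = analyze_cohort(subjects, cfg, roi_labels=roi_labels)
    from .io import spec_to_dict

    result.run_record["cohort_spec"] = spec_to_dict(spec)
    clean = manifest.astype(object).where(manifest.notna(), None)
    result.run_record["manifest"] = clean.to_dict(orient="list")
    return result
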