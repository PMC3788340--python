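"""Plain-text cohort and result I/O.

All on-disk formats are TSV or JSON: one time-series TSV per subject (rows =
volumes, columns = ROI labels), an optional confound TSV per subject, a
cohort manifest, and the analysis result tables.  Tables round floats to 3
decimals; the JSON run record keeps full precision so a run is reproducible
from the record alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Optional, Sequence, Union

import pandas as pd

from .cohort import CohortSpec, SubjectTimeSeries
from .parcellation import ParcellationTable

logger = logging.getLogger(__name__)

__all__ = ["write_cohort", "read_cohort", "write_results", "spec_to_dict", "spec_from_dict"]

_FLOAT_FMT = "%.3f"


def spec_to_dict(spec: CohortSpec) -> dict:
    d = dataclasses.asdict(spec)
    d["effect_rois"] = list(spec.effect_rois)
    return d


def spec_from_dict(d: dict) -> CohortSpec:
    from .cohort import BaseGraphConfig, NuisanceConfig

    d = dict(d)
    if isinstance(d.get("base_graph"), dict):
        d["base_graph"] = BaseGraphConfig(**d["base_graph"])
    if isinstance(d.get("nuisance"), dict):
        d["nuisance"] = NuisanceConfig(**d["nuisance"])
    if "effect_rois" in d:
        d["effect_rois"] = tuple(d["effect_rois"])
    return CohortSpec(**d)


def write_cohort(
    subjects: Sequence[SubjectTimeSeries],
    manifest: pd.DataFrame,
    spec: CohortSpec,
    out_dir: Union[str, Path],
    roi_labels: Optional[Sequence[str]] = None,
) -> Path:
    """Write per-subject TSVs, confound TSVs, manifest, and the spec JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    labels = list(roi_labels) if roi_labels is not None else spec.roi_labels()
    manifest = manifest.copy()
    manifest["file"] = [f"{s.subject_id}.tsv" for s in subjects]
    for subj in subjects:
        pd.DataFrame(subj.data, columns=labels).to_csv(
            out / f"{subj.subject_id}.tsv", sep="\t", index=False
        )
        if subj.confounds is not None:
            cols = ["global", "drift"] + [f"motion{k}" for k in range(1, 7)]
            pd.DataFrame(subj.confounds, columns=cols).to_csv(
                out / f"{subj.subject_id}_confounds.tsv", sep="\t", index=False
            )
    manifest.to_csv(out / "cohort_manifest.tsv", sep="\t", index=False)
    with open(out / "cohort_spec.json", "w") as fh:
        json.dump(spec_to_dict(spec), fh, indent=2)
    return out


def read_cohort(
    manifest_path: Union[str, Path],
    data_dir: Optional[Union[str, Path]] = None,
    parcellation: Optional[ParcellationTable] = None,
    tr_seconds: Optional[float] = None,
) -> list[SubjectTimeSeries]:
    """Load a cohort from a manifest TSV plus per-subject time-series TSVs.

    Validates group labels, per-subject file presence, absence of NaNs, and
    dimensional consistency across subjects (and against the parcellation
    when one is supplied).  All problems are gathered into one error report.
    """
    manifest_path = Path(manifest_path)
    data_dir = Path(data_dir) if data_dir is not None else manifest_path.parent
    manifest = pd.read_csv(manifest_path, sep="\t")
    for col in ("subject_id", "group", "file"):
        if col not in manifest.columns:
            raise ValueError(f"manifest missing column {col!r}")

    if tr_seconds is None:
        spec_path = data_dir / "cohort_spec.json"
        if spec_path.exists():
            with open(spec_path) as fh:
                tr_seconds = float(json.load(fh)["tr_seconds"])
        else:
            raise ValueError("tr_seconds not given and no cohort_spec.json found")

    subjects: list[SubjectTimeSeries] = []
    errors: list[str] = []
    n_cols: Optional[int] = None
    for row in manifest.itertuples(index=False):
        sid = row.subject_id
        if row.group not in ("A", "B"):
            errors.append(f"{sid}: unknown group label {row.group!r}")
            continue
        path = data_dir / row.file
        if not path.exists():
            errors.append(f"{sid}: missing file {path.name}")
            continue
        df = pd.read_csv(path, sep="\t")
        if df.isna().any().any():
            errors.append(f"{sid}: NaN cells in {path.name}")
            continue
        if n_cols is None:
            n_cols = df.shape[1]
        elif df.shape[1] != n_cols:
            errors.append(f"{sid}: {df.shape[1]} columns, expected {n_cols}")
            continue
        if parcellation is not None and df.shape[1] != parcellation.n_rois:
            errors.append(
                f"{sid}: {df.shape[1]} columns vs {parcellation.n_rois}-ROI parcellation"
            )
            continue
        conf_path = data_dir / f"{sid}_confounds.tsv"
        confounds = (
            pd.read_csv(conf_path, sep="\t").to_numpy(float) if conf_path.exists() else None
        )
        training = getattr(row, "training_years", None)
        if training is not None and pd.isna(training):
            training = None
        subjects.append(
            SubjectTimeSeries(
                subject_id=str(sid),
                group=str(row.group),
                data=df.to_numpy(float),
                tr_seconds=tr_seconds,
                training_years=float(training) if training is not None else None,
                confounds=confounds,
            )
        )
    if errors:
        raise ValueError("cohort validation failed:\n  " + "\n  ".join(errors))
    return subjects


def _write_table(df: pd.DataFrame, path: Path, index_label: Optional[str] = None) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index_label is not None,
              index_label=index_label)


def write_results(result, out_dir: Union[str, Path]) -> Path:
    """Write the analysis result tables and JSON run record.

    ``result`` is a ``pipeline.CohortAnalysis``.  Emits: per-subject AUC
    tables (global and nodal, tidy), the global-metric group comparison, the
    flagged-regions table split by direction per nodal metric, the
    training-correlation table, and ``run_record.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    tidy = result.nodal_auc_tidy()
    _write_table(tidy, out / "auc_nodal.tsv")
    ga = result.global_auc.copy()
    ga.insert(0, "group", result.groups.to_numpy())
    _write_table(ga, out / "auc_global.tsv", index_label="subject_id")
    _write_table(result.global_comparison, out / "global_comparison.tsv", index_label="metric")
    _write_table(result.flagged_regions, out / "flagged_regions.tsv", index_label="region")
    _write_table(
        result.training_correlations, out / "training_correlations.tsv", index_label="region"
    )
    with open(out / "run_record.json", "w") as fh:
        json.dump(result.run_record, fh, indent=2, sort_keys=True)
    return out
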