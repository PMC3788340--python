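"""ROI-level BOLD signal preprocessing and functional connectivity.

The preprocessing chain is the ROI-level analog of a standard resting-state
pipeline: discard initial volumes, remove per-ROI linear trends, apply an
ideal (frequency-domain) band-pass filter over 0.01-0.08 Hz, and regress out
nuisance signals (supplied confound regressors plus, optionally, the global
signal defined as the mean across ROI columns).  The order is fixed:
discard, detrend, filter, regress.

Connectivity is pairwise Pearson correlation between ROI time courses,
variance-stabilized with the Fisher z transform (artanh).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import SubjectTimeSeries

logger = logging.getLogger(__name__)

__all__ = [
    "PreprocessConfig",
    "ConnectivityMatrix",
    "SeedFCMap",
    "preprocess",
    "bandpass_ideal",
    "correlation_matrix",
    "fisher_z",
    "seed_fc_map",
    "group_fc_tests",
]


@dataclass(frozen=True)
class PreprocessConfig:
    discard_initial: int = 4
    band_low_hz: float = 0.01
    band_high_hz: float = 0.08
    include_global_signal: bool = True

    def __post_init__(self) -> None:
        if self.discard_initial < 0:
            raise ValueError("discard_initial must be nonnegative")
        if not 0.0 <= self.band_low_hz < self.band_high_hz:
            raise ValueError("need 0 <= band_low_hz < band_high_hz")


@dataclass
class ConnectivityMatrix:
    """Symmetric N x N Pearson-r (and Fisher-z) interregional connectivity.

    The z matrix is derived lazily from r so that a degenerate r = +/-1 entry
    (duplicate ROI columns) is representable; the Fisher transform raises only
    when ``z_matrix`` is actually requested.
    """

    r_matrix: np.ndarray
    roi_labels: Optional[list[str]] = None
    subject_id: Optional[str] = None

    def __post_init__(self) -> None:
        r = np.asarray(self.r_matrix, float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r_matrix must be square")
        if not np.isfinite(r).all():
            raise ValueError("r_matrix must be finite")
        if np.abs(r - r.T).max() > 1e-12:
            raise ValueError("r_matrix must be symmetric")
        if np.abs(np.diag(r)).max() > 0:
            raise ValueError("r_matrix must have zero diagonal")
        self.r_matrix = 0.5 * (r + r.T)
        self._z: Optional[np.ndarray] = None

    @property
    def z_matrix(self) -> np.ndarray:
        if self._z is None:
            self._z = fisher_z(self.r_matrix)
        return self._z

    @property
    def n_rois(self) -> int:
        return self.r_matrix.shape[0]


@dataclass
class SeedFCMap:
    """Fisher-z seed-to-ROI connectivity values for one subject."""

    seed_label: str
    z_values: np.ndarray
    target_labels: Optional[list[str]] = None


def bandpass_ideal(data: np.ndarray, tr_seconds: float, low_hz: float, high_hz: float) -> np.ndarray:
    """Ideal DFT band-pass: zero every coefficient with frequency outside
    [low_hz, high_hz]; conjugate symmetry is preserved by operating on the
    real FFT.  Idempotent by construction."""
    nyquist = 0.5 / tr_seconds
    if high_hz > nyquist:
        raise ValueError(f"band_high_hz {high_hz} exceeds Nyquist {nyquist:.4g} Hz")
    t = data.shape[0]
    freqs = np.fft.rfftfreq(t, d=tr_seconds)
    keep = (freqs >= low_hz) & (freqs <= high_hz)
    spec = np.fft.rfft(data, axis=0)
    spec[~keep] = 0.0
    return np.fft.irfft(spec, n=t, axis=0)


def _ols_residuals(y: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def preprocess(
    ts: SubjectTimeSeries,
    cfg: PreprocessConfig = PreprocessConfig(),
    nuisance_regressors: Optional[np.ndarray] = None,
) -> SubjectTimeSeries:
    """Discard -> detrend -> ideal band-pass -> nuisance regression.

    ``nuisance_regressors`` may cover either all volumes or only the retained
    ones; when absent, the subject's stored confounds are used if present.
    The global signal (mean across ROIs, computed after filtering) is appended
    to the design when ``cfg.include_global_signal``.
    """
    if cfg.discard_initial >= ts.n_timepoints:
        raise ValueError("discard_initial must be smaller than the number of volumes")
    x = ts.data[cfg.discard_initial :].copy()
    t = x.shape[0]

    if nuisance_regressors is None and ts.confounds is not None:
        nuisance_regressors = ts.confounds
    if nuisance_regressors is not None:
        reg = np.asarray(nuisance_regressors, float)
        if reg.shape[0] == ts.n_timepoints:
            reg = reg[cfg.discard_initial :]
        if reg.shape[0] != t:
            raise ValueError(
                f"nuisance regressors have {reg.shape[0]} rows; expected {t} "
                f"after discarding {cfg.discard_initial} volumes"
            )
    else:
        reg = None

    # linear detrend (OLS line per ROI, removes mean + slope)
    trend_design = np.column_stack([np.ones(t), np.arange(t, dtype=float)])
    x = _ols_residuals(x, trend_design)

    x = bandpass_ideal(x, ts.tr_seconds, cfg.band_low_hz, cfg.band_high_hz)

    design_cols = [np.ones(t)]
    if reg is not None:
        design_cols.append(reg)
    if cfg.include_global_signal:
        design_cols.append(x.mean(axis=1, keepdims=True))
    design = np.column_stack(design_cols)
    if design.shape[1] > 1:
        x = _ols_residuals(x, design)

    return SubjectTimeSeries(
        subject_id=ts.subject_id,
        group=ts.group,
        data=x,
        tr_seconds=ts.tr_seconds,
        training_years=ts.training_years,
        confounds=None,
    )


def fisher_z(r):
    """Fisher z transform artanh(r) = 0.5 ln((1+r)/(1-r)); requires |r| < 1.

    Applied to a matrix, the diagonal is left at 0 and only off-diagonal
    entries are checked/transformed.
    """
    r = np.asarray(r, dtype=float)
    if r.ndim == 2 and r.shape[0] == r.shape[1]:
        off = ~np.eye(r.shape[0], dtype=bool)
        if np.abs(r[off]).max(initial=0.0) >= 1.0:
            raise ValueError("correlation magnitude >= 1; Fisher z undefined")
        z = np.zeros_like(r)
        z[off] = np.arctanh(r[off])
        return z
    if np.abs(r).max(initial=0.0) >= 1.0:
        raise ValueError("correlation magnitude >= 1; Fisher z undefined")
    out = np.arctanh(r)
    return float(out) if out.ndim == 0 else out


def correlation_matrix(
    ts: SubjectTimeSeries, roi_labels: Optional[Sequence[str]] = None
) -> ConnectivityMatrix:
    """Pairwise Pearson r between ROI columns; diagonal set to 0; Fisher z
    computed alongside.  Raises (naming the ROI) on zero-variance columns."""
    x = ts.data
    sd = x.std(axis=0)
    dead = np.flatnonzero(sd == 0)
    if dead.size:
        labels = list(roi_labels) if roi_labels is not None else None
        names = [labels[i] if labels else f"ROI{i + 1:03d}" for i in dead]
        raise ValueError(f"zero-variance ROI column(s): {', '.join(names)}")
    r = np.corrcoef(x, rowvar=False)
    r = np.clip(0.5 * (r + r.T), -1.0, 1.0)
    np.fill_diagonal(r, 0.0)
    return ConnectivityMatrix(
        r_matrix=r,
        roi_labels=list(roi_labels) if roi_labels is not None else None,
        subject_id=ts.subject_id,
    )


def seed_fc_map(
    ts: SubjectTimeSeries,
    seed_rois: Sequence[int],
    roi_labels: Optional[Sequence[str]] = None,
    seed_label: Optional[str] = None,
) -> SeedFCMap:
    """Fisher-z map of the mean seed signal against every non-seed ROI.

    ``seed_rois`` are 1-based ROI indices.  A target perfectly collinear with
    the seed (|r| = 1) is a contract violation and raises.
    """
    n = ts.n_rois
    seed_idx = np.asarray(sorted(set(int(i) for i in seed_rois))) - 1
    if seed_idx.size == 0:
        raise ValueError("seed_rois must be nonempty")
    if seed_idx.min() < 0 or seed_idx.max() >= n:
        raise ValueError(f"seed ROI index out of range 1..{n}")
    seed_signal = ts.data[:, seed_idx].mean(axis=1)
    if seed_signal.std() == 0:
        raise ValueError("seed signal has zero variance")
    targets = np.setdiff1d(np.arange(n), seed_idx)
    x = ts.data[:, targets]
    sd = x.std(axis=0)
    if (sd == 0).any():
        bad = targets[sd == 0] + 1
        raise ValueError(f"zero-variance ROI column(s): {bad.tolist()}")
    s = (seed_signal - seed_signal.mean()) / seed_signal.std()
    xc = (x - x.mean(axis=0)) / sd
    r = (xc * s[:, None]).mean(axis=0)
    z = fisher_z(r)
    labels = (
        [list(roi_labels)[i] for i in targets] if roi_labels is not None else None
    )
    return SeedFCMap(
        seed_label=seed_label or "+".join(str(i + 1) for i in seed_idx),
        z_values=z,
        target_labels=labels,
    )


def group_fc_tests(maps_a: Sequence[SeedFCMap], maps_b: Sequence[SeedFCMap]) -> pd.DataFrame:
    """Per-ROI group comparison of seed-FC z maps.

    Pooled-variance two-sample t between groups, BH-FDR q across ROIs, plus
    one-sample t vs 0 within each group.  A ROI where both groups have zero
    variance yields NaN t/p with a logged warning instead of raising.
    """
    if len(maps_a) < 2 or len(maps_b) < 2:
        raise ValueError("need at least two subjects per group")
    za = np.vstack([m.z_values for m in maps_a])
    zb = np.vstack([m.z_values for m in maps_b])
    if za.shape[1] != zb.shape[1]:
        raise ValueError("groups have mismatched ROI counts")

    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(za, zb, axis=0, equal_var=True)
        t1a, p1a = stats.ttest_1samp(za, 0.0, axis=0)
        t1b, p1b = stats.ttest_1samp(zb, 0.0, axis=0)
    n_nan = int(np.isnan(p).sum())
    if n_nan:
        logger.warning("group_fc_tests: %d ROI(s) with degenerate variance -> NaN p", n_nan)

    from statsmodels.stats.multitest import multipletests

    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]

    labels = maps_a[0].target_labels
    return pd.DataFrame(
        {
            "roi": labels if labels is not None else np.arange(1, za.shape[1] + 1),
            "mean_A": za.mean(axis=0),
            "mean_B": zb.mean(axis=0),
            "t": t,
            "p_uncorrected": p,
            "q_fdr": q,
            "t_one_sample_A": t1a,
            "p_one_sample_A": p1a,
            "t_one_sample_B": t1b,
            "p_one_sample_B": p1b,
        }
    )
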