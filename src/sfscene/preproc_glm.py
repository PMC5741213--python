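"""Signal normalization, GLM fitting, pattern extraction and ROI definition.

The univariate path converts each run to percent signal change relative to
its fixation baseline and fits a GLM with HRF-convolved condition
regressors plus nuisance (drift, motion). The multivariate path fits a
nuisance-only GLM, extracts the residual volumes of every block at a 4 s
lag (4 volumes per 8 s block at TR = 2 s) and averages them into one
multi-voxel pattern per block: 8 runs × 16 blocks → 128 pattern samples
per subject. ROIs are defined from contrast t-maps by thresholding and
keeping the largest 6-connected cluster.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage as _ndi

from .expdesign import (
    ALL_CONDITIONS,
    Condition,
    DesignMatrix,
    RunSchedule,
    build_nuisance_matrix,
    condition_by_label,
)
from .synthbold import BoldRun, RoiSpec

__all__ = [
    "GlmFit",
    "PatternSample",
    "percent_signal_change",
    "fixation_baseline_volumes",
    "smooth_spatial",
    "fit_glm",
    "contrast_tstats",
    "extract_block_patterns",
    "extract_subject_patterns",
    "define_roi_by_contrast",
    "patterns_to_frame",
    "frame_to_patterns",
]


class GlmError(ValueError):
    """Degenerate input to the GLM machinery."""


@dataclass(frozen=True)
class GlmFit:
    """Per-voxel ordinary least squares fit."""

    betas: np.ndarray  # V×R
    residuals: np.ndarray  # V×T
    names: tuple[str, ...]
    dof: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[:, self.names.index(name)]


@dataclass(frozen=True)
class PatternSample:
    """One averaged multi-voxel pattern — the decoder's atom."""

    vector: np.ndarray
    condition: Condition
    run_id: int
    subject_id: str

    def __post_init__(self) -> None:
        v = np.asarray(self.vector, dtype=float)
        if not np.all(np.isfinite(v)):
            raise GlmError("pattern sample contains non-finite values")
        object.__setattr__(self, "vector", v)


def fixation_baseline_volumes(schedule: RunSchedule) -> np.ndarray:
    """Volume indices of the late fixation baseline of one run.

    Uses the last 6 s (3 volumes at TR = 2 s) of each 12 s post-block
    fixation period, avoiding hemodynamic bleed-over from the preceding
    block; the lead-in is excluded. A volume i covers times
    [i*TR, (i+1)*TR).
    """
    tr = schedule.tr_s
    idx: list[int] = []
    for b in schedule.blocks:
        fix_start = b.onset_s + b.duration_s
        late_start = fix_start + 6.0
        late_end = fix_start + 12.0
        i0 = int(np.ceil(late_start / tr - 1e-9))
        i1 = int(np.ceil(late_end / tr - 1e-9))
        idx.extend(range(i0, min(i1, schedule.n_volumes)))
    return np.array(sorted(set(idx)), dtype=int)


def percent_signal_change(run: BoldRun, fixation_volumes: np.ndarray | None = None) -> BoldRun:
    """Normalize a run to percent signal change relative to fixation.

    Per voxel: ``100 * (x - mu_fix) / mu_fix`` where ``mu_fix`` is the mean
    over the designated fixation volumes of that run.
    """
    if fixation_volumes is None:
        fixation_volumes = fixation_baseline_volumes(run.schedule)
    fixation_volumes = np.asarray(fixation_volumes, dtype=int)
    if fixation_volumes.size == 0:
        raise GlmError("no fixation volumes designated")
    mu = run.data[:, fixation_volumes].mean(axis=1)
    bad = np.flatnonzero(np.abs(mu) < 1e-12)
    if bad.size:
        raise GlmError(f"zero fixation baseline in voxels {bad.tolist()[:20]}")
    data = 100.0 * (run.data - mu[:, None]) / mu[:, None]
    return BoldRun(data, run.tr_s, run.schedule, run.subject_id, run.run_id, motion=run.motion)


def smooth_spatial(volume: np.ndarray, fwhm_mm: float, voxel_size_mm: float | tuple = 2.0) -> np.ndarray:
    """Gaussian spatial smoothing with the kernel stated in mm FWHM.

    sigma per axis is ``FWHM / (2*sqrt(2*ln 2))`` converted to voxel units;
    ``fwhm_mm = 0`` is the identity. Reflective boundaries conserve the
    total image sum.
    """
    if fwhm_mm < 0:
        raise GlmError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return np.asarray(volume, dtype=float).copy()
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (np.ndim(volume),))
    sigma = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / vs
    return _ndi.gaussian_filter(np.asarray(volume, dtype=float), sigma=sigma, mode="reflect")


def _design_values(X: DesignMatrix | np.ndarray) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(X, DesignMatrix):
        return X.values, X.names
    X = np.asarray(X, dtype=float)
    return X, tuple(f"x{j}" for j in range(X.shape[1]))


def fit_glm(Y: np.ndarray, X: DesignMatrix | np.ndarray) -> GlmFit:
    """Ordinary least squares fit of every voxel time series on ``X``.

    ``Y`` is voxels × time. Raises if the design is rank deficient, naming
    the collinear columns.
    """
    Xv, names = _design_values(X)
    Y = np.asarray(Y, dtype=float)
    T, R = Xv.shape
    if Y.shape[1] != T:
        raise GlmError(f"data has {Y.shape[1]} volumes but design has {T} rows")
    if T <= R:
        raise GlmError(f"need more volumes ({T}) than regressors ({R})")
    q, r = np.linalg.qr(Xv)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        culprits = [names[j] for j in np.flatnonzero(bad)]
        raise GlmError(f"design matrix is rank deficient; collinear columns: {culprits}")
    betas = np.linalg.solve(r, q.T @ Y.T).T  # V×R
    residuals = Y - betas @ Xv.T
    return GlmFit(betas, residuals, names, dof=T - R)


def contrast_tstats(fit: GlmFit, X: DesignMatrix | np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Voxelwise t-statistic of the contrast ``weights' @ beta``.

    ``weights`` must sum to zero (a differential contrast).
    """
    Xv, _ = _design_values(X)
    w = np.asarray(weights, dtype=float)
    if abs(w.sum()) > 1e-9:
        raise GlmError("contrast weights must sum to 0")
    if w.shape[0] != fit.betas.shape[1]:
        raise GlmError("contrast length does not match number of regressors")
    sigma2 = (fit.residuals**2).sum(axis=1) / fit.dof
    xtx_inv = np.linalg.inv(Xv.T @ Xv)
    denom = np.sqrt(sigma2 * float(w @ xtx_inv @ w))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, fit.betas @ w / denom, 0.0)
    return t


def extract_block_patterns(
    residuals: np.ndarray,
    schedule: RunSchedule,
    subject_id: str = "sub-01",
    run_id: int = 0,
    lag_s: float = 4.0,
    n_acquisitions: int = 4,
    average: bool = True,
) -> list[PatternSample]:
    """Extract lagged block patterns from one run's residuals (V×T).

    For each block the ``n_acquisitions`` volumes starting at
    ``onset + lag_s`` are taken (a time t belongs to volume floor(t/TR))
    and, if ``average``, averaged into a single PatternSample.
    """
    tr = schedule.tr_s
    T = residuals.shape[1]
    out: list[PatternSample] = []
    for b in schedule.blocks:
        i0 = int(np.floor((b.onset_s + lag_s) / tr + 1e-9))
        idx = np.arange(i0, i0 + n_acquisitions)
        if idx[-1] >= T:
            raise GlmError(
                f"block at {b.onset_s} s needs volume {idx[-1]} but the run has only {T}"
            )
        vols = residuals[:, idx]
        if average:
            out.append(PatternSample(vols.mean(axis=1), b.condition, run_id, subject_id))
        else:
            for v in vols.T:
                out.append(PatternSample(v.copy(), b.condition, run_id, subject_id))
    return out


def extract_subject_patterns(
    runs: list[BoldRun],
    drift_order: int = 2,
    use_motion: bool = True,
    lag_s: float = 4.0,
) -> list[PatternSample]:
    """Full multivariate preprocessing of one subject.

    Fits the nuisance-only GLM (per-run drift plus the runs' motion
    parameters when available) to the concatenated runs, then extracts and
    averages the lagged block volumes of every run: with the default design
    8 runs × 16 blocks × 4 acquisitions → 512 extracted volumes averaged
    into 128 pattern samples.
    """
    if not runs:
        raise GlmError("no runs given")
    schedules = [r.schedule for r in runs]
    motion = None
    if use_motion and all(r.motion is not None for r in runs):
        motion = np.vstack([r.motion for r in runs])
    X = build_nuisance_matrix(schedules, drift_order=drift_order, motion=motion)
    Y = np.hstack([r.data for r in runs])
    fit = fit_glm(Y, X)
    samples: list[PatternSample] = []
    offset = 0
    for r in runs:
        res = fit.residuals[:, offset : offset + r.n_volumes]
        samples.extend(
            extract_block_patterns(res, r.schedule, r.subject_id, r.run_id, lag_s=lag_s)
        )
        offset += r.n_volumes
    return samples


def define_roi_by_contrast(
    t_map: np.ndarray,
    threshold_t: float,
    min_cluster: int = 1,
    name: str = "roi",
    ap_axis: int = 1,
) -> RoiSpec:
    """Define an ROI from a 3-D t-map: threshold, 6-connected clusters,
    drop clusters below ``min_cluster`` voxels, keep the largest.

    Returns an empty RoiSpec (not an exception) when no voxel survives.
    """
    t_map = np.asarray(t_map, dtype=float)
    if t_map.ndim != 3:
        raise GlmError("t-map must be 3-D")
    mask = t_map > threshold_t
    labels, n = _ndi.label(mask, structure=_ndi.generate_binary_structure(3, 1))
    best_coords = np.empty((0, 3), dtype=int)
    best_size = 0
    for k in range(1, n + 1):
        coords = np.argwhere(labels == k)
        if len(coords) >= min_cluster and len(coords) > best_size:
            best_size = len(coords)
            best_coords = coords
    return RoiSpec(name, best_coords, ap_axis)


# ---------------------------------------------------------------------------
# Tabular pattern I/O (one row per sample: subject, run, condition, voxels)


def patterns_to_frame(samples: list[PatternSample]) -> pd.DataFrame:
    if not samples:
        raise GlmError("no samples to tabulate")
    V = samples[0].vector.size
    rows = []
    for s in samples:
        rows.append(
            {
                "subject": s.subject_id,
                "run": s.run_id,
                "condition": s.condition.label,
                "category": s.condition.category or "",
                **{f"v{j}": s.vector[j] for j in range(V)},
            }
        )
    return pd.DataFrame(rows)


def frame_to_patterns(df: pd.DataFrame) -> list[PatternSample]:
    vox_cols = [c for c in df.columns if c.startswith("v") and c[1:].isdigit()]
    vox_cols.sort(key=lambda c: int(c[1:]))
    return [
        PatternSample(
            row[vox_cols].to_numpy(dtype=float),
            condition_by_label(row["condition"]),
            int(row["run"]),
            str(row["subject"]),
        )
        for _, row in df.iterrows()
    ]
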