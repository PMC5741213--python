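"""Synthetic multi-subject block-design BOLD data with known ground truth.

Stands in for scanned subjects: each region of interest (ROI) gets a
unit-norm random voxel pattern per condition, a shared "frequency axis"
pattern (added with opposite sign for low- versus high-frequency
conditions) and an optional per-condition mean-activation offset. Voxel
time series are the HRF-convolved block regressors weighted by these
patterns, on top of a baseline, AR(1) Gaussian noise, polynomial drift and
motion-coupled nuisance. The generator returns the embedded ground truth so
downstream recovery can be verified.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
from scipy import signal as _spsig

from .expdesign import (
    ALL_CONDITIONS,
    DEFAULT_TR_S,
    HRFParams,
    RunSchedule,
    _ortho_poly,
    _task_regressors,
)

__all__ = [
    "SyntheticConfig",
    "RoiSpec",
    "BoldRun",
    "make_box_roi",
    "make_condition_patterns",
    "simulate_subject",
    "split_roi_ap",
    "save_run_nifti",
    "load_run_nifti",
]


class SimulationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic BOLD generator.

    Effect sizes are amplitudes of the embedded signal in the same units as
    ``noise_sd`` (so with the default ``noise_sd = 1`` they are relative to
    the noise standard deviation). Each may be a scalar or a mapping keyed
    by ``(roi_name, condition_label)``, ``roi_name`` or ``condition_label``
    for region- or condition-specific signal strength.

    - ``effect_size``: amplitude of the condition-specific (category)
      pattern.
    - ``freq_effect``: amplitude of the shared frequency-axis pattern
      (positive for high-frequency conditions, negative for low), which
      makes binary frequency decoding tunable independently of category
      decoding.
    - ``univariate_amp``: per-condition mean-activation offset added
      uniformly to all voxels, driving univariate contrasts.
    """

    n_subjects: int = 10
    n_voxels: int = 100
    effect_size: float | Mapping = 1.0
    freq_effect: float | Mapping = 1.0
    univariate_amp: float | Mapping = 0.0
    noise_sd: float = 1.0
    ar1_coef: float = 0.3
    drift_amp: float = 0.5
    motion_amp: float = 0.3
    baseline: float = 100.0
    tr_s: float = DEFAULT_TR_S
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise SimulationError("need at least 2 subjects")
        if not 0 <= self.ar1_coef < 1:
            raise SimulationError("ar1_coef must be in [0, 1)")
        if self.noise_sd < 0:
            raise SimulationError("noise_sd must be non-negative")


def _resolve(value: float | Mapping, roi: str, cond) -> float:
    """Resolve a scalar-or-mapping effect to a number for (roi, condition).

    Mapping keys are tried from specific to general: ``(roi, label)``,
    ``label``, ``(roi, sf_condition)``, ``sf_condition`` (FS/LSF/HSF),
    ``(roi, frequency_class)``, ``frequency_class`` (low/high), ``roi``.
    A mapping with no matching key contributes 0.
    """
    if isinstance(value, Mapping):
        keys = [(roi, cond.label), cond.label]
        for attr in (cond.sf_condition, cond.frequency_class):
            if attr is not None:
                keys += [(roi, attr), attr]
        keys.append(roi)
        for key in keys:
            if key in value:
                return float(value[key])
        return 0.0
    v = float(value)
    if v < 0:
        raise SimulationError("effect sizes must be non-negative")
    return v


@dataclass(frozen=True)
class RoiSpec:
    """A named set of voxels on an integer 3-D grid.

    ``ap_axis`` names the coordinate axis that orders voxels from posterior
    (small) to anterior (large), used by :func:`split_roi_ap`.
    """

    name: str
    voxels: np.ndarray
    ap_axis: int = 1

    def __post_init__(self) -> None:
        vox = np.asarray(self.voxels, dtype=int).reshape(-1, 3)
        if len(np.unique(vox, axis=0)) != len(vox):
            raise SimulationError(f"ROI {self.name!r} has duplicate voxel coordinates")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)

    @property
    def is_empty(self) -> bool:
        return self.n_voxels == 0


def make_box_roi(name: str, origin: tuple[int, int, int], shape: tuple[int, int, int],
                 ap_axis: int = 1) -> RoiSpec:
    """Axis-aligned box ROI of ``prod(shape)`` voxels starting at ``origin``."""
    grids = np.meshgrid(*(np.arange(o, o + s) for o, s in zip(origin, shape)), indexing="ij")
    return RoiSpec(name, np.column_stack([g.ravel() for g in grids]), ap_axis)


@dataclass(frozen=True)
class BoldRun:
    """One run of voxel time series (V×T) with its schedule attached."""

    data: np.ndarray
    tr_s: float
    schedule: RunSchedule
    subject_id: str
    run_id: int
    motion: np.ndarray | None = None

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(data)):
            raise SimulationError("BOLD data contains non-finite values")
        if data.shape[1] != self.schedule.n_volumes:
            raise SimulationError(
                f"run has {data.shape[1]} volumes but the schedule implies "
                f"{self.schedule.n_volumes}"
            )
        object.__setattr__(self, "data", data)

    @property
    def n_voxels(self) -> int:
        return self.data.shape[0]

    @property
    def n_volumes(self) -> int:
        return self.data.shape[1]


def make_condition_patterns(
    config: SyntheticConfig, roi: RoiSpec, seed: int
) -> dict[str, np.ndarray]:
    """Draw unit-norm voxel patterns for the 16 conditions plus the
    shared frequency axis.

    Patterns are independent Gaussian directions, so patterns of different
    scene categories within a frequency condition are mutually independent
    draws; the extra key ``"__freq_axis__"`` holds the pattern shared by all
    conditions of one frequency class. Deterministic per seed.
    """
    rng = np.random.default_rng(seed)
    V = roi.n_voxels
    patterns: dict[str, np.ndarray] = {}
    for cond in ALL_CONDITIONS:
        v = rng.standard_normal(V)
        patterns[cond.label] = v / np.linalg.norm(v)
    v = rng.standard_normal(V)
    patterns["__freq_axis__"] = v / np.linalg.norm(v)
    return patterns


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, int], sd: float, phi: float) -> np.ndarray:
    """AR(1) noise with marginal SD ``sd`` and lag-1 autocorrelation ``phi``."""
    if sd == 0:
        return np.zeros(shape)
    innov = rng.standard_normal(shape) * sd * np.sqrt(1.0 - phi**2)
    # stationary start so the marginal variance is sd^2 from volume 0
    innov[:, 0] = rng.standard_normal(shape[0]) * sd
    return _spsig.lfilter([1.0], [1.0, -phi], innov, axis=1)


def _freq_sign(cond) -> float:
    return {"high": 1.0, "low": -1.0}.get(cond.frequency_class, 0.0)


def simulate_subject(
    config: SyntheticConfig,
    rois: list[RoiSpec],
    schedules: list[RunSchedule],
    subject_id: str = "sub-01",
    seed: int | None = None,
    hrf_params: HRFParams | None = None,
):
    """Simulate all runs of one subject over the given ROIs.

    Voxels of all ROIs are stacked into a single V×T matrix per run (in ROI
    order); the returned ground truth carries the per-ROI row slices, the
    condition patterns and resolved effect sizes, the motion time courses
    and all seeds, so recovery can be tested exactly.

    Returns
    -------
    runs : list of BoldRun
    truth : dict with keys ``roi_slices``, ``patterns``, ``effects``,
        ``seed``, ``config``.
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    pattern_seed = int(rng.integers(2**31))
    patterns = {
        roi.name: make_condition_patterns(config, roi, pattern_seed + i)
        for i, roi in enumerate(rois)
    }
    roi_slices: dict[str, slice] = {}
    offset = 0
    for roi in rois:
        roi_slices[roi.name] = slice(offset, offset + roi.n_voxels)
        offset += roi.n_voxels
    V = offset

    effects = {
        roi.name: {
            c.label: {
                "effect_size": _resolve(config.effect_size, roi.name, c),
                "freq_effect": _resolve(config.freq_effect, roi.name, c),
                "univariate_amp": _resolve(config.univariate_amp, roi.name, c),
            }
            for c in ALL_CONDITIONS
        }
        for roi in rois
    }

    # per-condition voxel weight vector (V,) built once per subject
    weights = np.zeros((len(ALL_CONDITIONS), V))
    for roi in rois:
        sl = roi_slices[roi.name]
        p = patterns[roi.name]
        for j, c in enumerate(ALL_CONDITIONS):
            e = effects[roi.name][c.label]
            weights[j, sl] = (
                e["effect_size"] * p[c.label]
                + e["freq_effect"] * _freq_sign(c) * p["__freq_axis__"]
                + e["univariate_amp"]
            )

    runs = []
    for run_id, sched in enumerate(schedules):
        T = sched.n_volumes
        task = _task_regressors(sched, hrf_params)  # T×16
        data = config.baseline + weights.T @ task.T  # V×T
        data += _ar1_noise(rng, (V, T), config.noise_sd, config.ar1_coef)
        if config.drift_amp > 0:
            basis = _ortho_poly(T, 2)[:, 1:]  # linear + quadratic, unit norm
            coefs = rng.standard_normal((V, basis.shape[1])) * config.drift_amp * np.sqrt(T)
            data += coefs @ basis.T
        motion = None
        if config.motion_amp > 0:
            motion = np.cumsum(rng.standard_normal((T, 6)) * 0.05, axis=0)
            loadings = rng.standard_normal((V, 6)) * config.motion_amp
            data += loadings @ motion.T
        runs.append(
            BoldRun(data, sched.tr_s, sched, subject_id, run_id, motion=motion)
        )
    truth = {
        "roi_slices": roi_slices,
        "patterns": patterns,
        "effects": effects,
        "weights": weights,
        "seed": config.seed if seed is None else seed,
        "config": config,
    }
    return runs, truth


def split_roi_ap(roi: RoiSpec) -> tuple[RoiSpec, RoiSpec]:
    """Split an ROI into posterior/anterior halves of near-equal size.

    Voxels are stably sorted along the posterior→anterior coordinate and
    split at the median position; with an odd count the posterior half gets
    the extra voxel.
    """
    if roi.n_voxels < 2:
        raise SimulationError(f"cannot split ROI {roi.name!r} with <2 voxels")
    order = np.argsort(roi.voxels[:, roi.ap_axis], kind="stable")
    n_post = (roi.n_voxels + 1) // 2
    post = roi.voxels[order[:n_post]]
    ant = roi.voxels[order[n_post:]]
    return (
        RoiSpec(f"p{roi.name}", post, roi.ap_axis),
        RoiSpec(f"a{roi.name}", ant, roi.ap_axis),
    )


# ---------------------------------------------------------------------------
# NIfTI round-trip so real scanner data could be substituted downstream


def save_run_nifti(run: BoldRun, rois: list[RoiSpec], path: str | Path) -> None:
    """Write one run as 4-D NIfTI, placing each voxel at its grid coordinate."""
    import nibabel as nib

    coords = np.vstack([r.voxels for r in rois])
    if coords.shape[0] != run.n_voxels:
        raise SimulationError("ROI voxel count does not match run data")
    dims = coords.max(axis=0) + 1
    vol = np.zeros((*dims, run.n_volumes), dtype=np.float32)
    vol[coords[:, 0], coords[:, 1], coords[:, 2], :] = run.data
    img = nib.Nifti1Image(vol, affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, run.tr_s))
    nib.save(img, str(path))


def load_run_nifti(
    path: str | Path,
    rois: list[RoiSpec],
    schedule: RunSchedule,
    subject_id: str = "sub-01",
    run_id: int = 0,
) -> BoldRun:
    """Read a 4-D NIfTI back into a BoldRun over the given ROI voxels."""
    import nibabel as nib

    vol = np.asarray(nib.load(str(path)).get_fdata())
    coords = np.vstack([r.voxels for r in rois])
    data = vol[coords[:, 0], coords[:, 1], coords[:, 2], :]
    return BoldRun(data, schedule.tr_s, schedule, subject_id, run_id)
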