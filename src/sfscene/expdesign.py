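"""Block-design schedules and HRF-convolved design matrices.

The experiment has 16 conditions: 12 scene conditions (4 categories ×
{FS, LSF, HSF}) and 4 band-limited noise conditions (0.75, 1.5, 3, 6 cpd).
Each run presents every condition once in randomized order, in 8 s blocks
each followed by 12 s of fixation; with a 10 s lead-in fixation a run lasts
330 s (165 volumes at TR = 2 s). Task regressors are 8 s boxcars convolved
with a canonical double-gamma hemodynamic response function; nuisance
regressors are per-run polynomial drift plus optional motion columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _sps

__all__ = [
    "Condition",
    "RunSchedule",
    "Block",
    "HRFParams",
    "DesignMatrix",
    "CATEGORIES",
    "SCENE_SF_CONDITIONS",
    "NOISE_BANDS_CPD",
    "ALL_CONDITIONS",
    "condition_by_label",
    "make_schedule",
    "hrf_kernel",
    "build_design_matrix",
    "build_nuisance_matrix",
    "write_events_tsv",
]

CATEGORIES = ("beach", "forest", "highway", "city")
SCENE_SF_CONDITIONS = ("FS", "LSF", "HSF")
NOISE_BANDS_CPD = (0.75, 1.5, 3.0, 6.0)

BLOCK_S = 8.0
FIXATION_S = 12.0
DEFAULT_LEAD_IN_S = 10.0
DEFAULT_TR_S = 2.0


class ScheduleError(ValueError):
    """Inconsistent block schedule."""


@dataclass(frozen=True)
class Condition:
    """One of the 16 experimental conditions.

    Scene conditions carry a ``category`` and an ``sf_condition``
    (FS/LSF/HSF); noise conditions carry a ``noise_band_cpd``.
    ``frequency_class`` is "low" for LSF scenes and the 0.75/1.5 cpd noise
    bands, "high" for HSF scenes and the 3/6 cpd bands, and None for FS.
    """

    label: str
    category: str | None = None
    sf_condition: str | None = None
    noise_band_cpd: float | None = None
    frequency_class: str | None = None

    @property
    def is_scene(self) -> bool:
        return self.category is not None

    @property
    def is_noise(self) -> bool:
        return self.noise_band_cpd is not None


def _freq_class_scene(sf: str) -> str | None:
    return {"LSF": "low", "HSF": "high"}.get(sf)


def _freq_class_noise(band: float) -> str:
    return "low" if band <= 1.5 else "high"


ALL_CONDITIONS: tuple[Condition, ...] = tuple(
    Condition(
        label=f"{cat}_{sf}",
        category=cat,
        sf_condition=sf,
        frequency_class=_freq_class_scene(sf),
    )
    for cat in CATEGORIES
    for sf in SCENE_SF_CONDITIONS
) + tuple(
    Condition(
        label=f"noise_{band:g}",
        noise_band_cpd=band,
        frequency_class=_freq_class_noise(band),
    )
    for band in NOISE_BANDS_CPD
)

_BY_LABEL = {c.label: c for c in ALL_CONDITIONS}


def condition_by_label(label: str) -> Condition:
    return _BY_LABEL[label]


@dataclass(frozen=True)
class Block:
    condition: Condition
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class RunSchedule:
    """Ordered block timings of one run."""

    blocks: tuple[Block, ...]
    tr_s: float = DEFAULT_TR_S
    lead_in_s: float = DEFAULT_LEAD_IN_S
    total_duration_s: float = 0.0

    def __post_init__(self) -> None:
        onsets = [b.onset_s for b in self.blocks]
        if any(b2 <= b1 for b1, b2 in zip(onsets, onsets[1:])):
            raise ScheduleError("block onsets must be strictly increasing")
        for b in self.blocks:
            for v in (b.onset_s, b.duration_s):
                if abs(round(v * 10) - v * 10) > 1e-9:
                    raise ScheduleError(
                        f"onsets/durations must align to 0.1 s, got {v}"
                    )
        for b1, b2 in zip(self.blocks, self.blocks[1:]):
            if b2.onset_s < b1.onset_s + b1.duration_s:
                raise ScheduleError(
                    f"blocks overlap at {b2.onset_s} s (previous block ends "
                    f"at {b1.onset_s + b1.duration_s} s)"
                )

    @property
    def n_volumes(self) -> int:
        n = self.total_duration_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise ScheduleError("run duration is not a whole number of volumes")
        return int(round(n))

    def conditions(self) -> list[Condition]:
        return [b.condition for b in self.blocks]


def make_schedule(
    seed: int,
    n_runs: int = 8,
    lead_in_s: float = DEFAULT_LEAD_IN_S,
    block_s: float = BLOCK_S,
    fixation_s: float = FIXATION_S,
    tr_s: float = DEFAULT_TR_S,
) -> list[RunSchedule]:
    """Build seeded randomized block schedules for ``n_runs`` runs.

    Each run is an independent permutation of the 16 conditions; every block
    lasts ``block_s`` seconds and is followed by ``fixation_s`` seconds of
    fixation. With the defaults a run lasts ``lead_in_s + 16*20 = 330`` s.
    """
    rng = np.random.default_rng(seed)
    runs = []
    for _ in range(n_runs):
        order = rng.permutation(len(ALL_CONDITIONS))
        blocks = tuple(
            Block(ALL_CONDITIONS[k], lead_in_s + i * (block_s + fixation_s), block_s)
            for i, k in enumerate(order)
        )
        total = lead_in_s + len(ALL_CONDITIONS) * (block_s + fixation_s)
        runs.append(RunSchedule(blocks, tr_s=tr_s, lead_in_s=lead_in_s, total_duration_s=total))
    return runs


@dataclass(frozen=True)
class HRFParams:
    """Canonical double-gamma hemodynamic response parameters (seconds)."""

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion_s: float = 1.0
    undershoot_dispersion_s: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length_s: float = 32.0

    def __post_init__(self) -> None:
        if self.length_s < 24.0:
            raise ScheduleError("HRF kernel must cover at least 24 s")


def hrf_kernel(params: HRFParams | None = None, dt_s: float = DEFAULT_TR_S) -> np.ndarray:
    """Sample the double-gamma HRF at spacing ``dt_s``, unit peak.

    The kernel is the difference of two gamma densities (peak minus scaled
    undershoot); with the default parameters it peaks near 5 s, starts at 0
    and dips below zero in the undershoot.
    """
    p = params or HRFParams()
    t = np.arange(0.0, p.length_s + dt_s / 2, dt_s)
    peak = _sps.gamma.pdf(t, p.peak_delay_s / p.peak_dispersion_s, scale=p.peak_dispersion_s)
    under = _sps.gamma.pdf(
        t, p.undershoot_delay_s / p.undershoot_dispersion_s, scale=p.undershoot_dispersion_s
    )
    h = peak - p.undershoot_ratio * under
    if h.sum() * dt_s <= 0:
        raise ScheduleError("HRF kernel must integrate to a positive value")
    return h / h.max()


@dataclass(frozen=True)
class DesignMatrix:
    """T×R design matrix with named regressors."""

    values: np.ndarray
    names: tuple[str, ...]
    tr_s: float

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.names):
            raise ScheduleError("regressor names do not match matrix columns")

    @property
    def n_volumes(self) -> int:
        return self.values.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=list(self.names))


def _ortho_poly(n: int, order: int) -> np.ndarray:
    """Discrete orthonormal polynomial basis (orders 0..order) on n samples."""
    x = np.linspace(-1.0, 1.0, n)
    V = np.vander(x, order + 1, increasing=True)
    Q, R = np.linalg.qr(V)
    # fix signs so the constant column is positive and trends ascend
    return Q * np.sign(np.diag(R))


def _task_regressors(
    schedule: RunSchedule, hrf_params: HRFParams | None, dt_s: float = 0.1
) -> np.ndarray:
    """HRF-convolved boxcar per condition, sampled at volume times (T×16)."""
    T = schedule.n_volumes
    n_fine = int(round(schedule.total_duration_s / dt_s))
    kernel = hrf_kernel(hrf_params, dt_s)
    out = np.zeros((T, len(ALL_CONDITIONS)))
    idx = {c.label: j for j, c in enumerate(ALL_CONDITIONS)}
    vol_samples = (np.arange(T) * schedule.tr_s / dt_s).round().astype(int)
    for b in schedule.blocks:
        box = np.zeros(n_fine)
        i0 = int(round(b.onset_s / dt_s))
        i1 = int(round((b.onset_s + b.duration_s) / dt_s))
        box[i0:i1] = 1.0
        reg = np.convolve(box, kernel)[:n_fine]
        out[:, idx[b.condition.label]] += reg[vol_samples]
    return out


def build_design_matrix(
    schedules: list[RunSchedule],
    hrf_params: HRFParams | None = None,
    drift_order: int = 2,
    motion: np.ndarray | None = None,
    include_task: bool = True,
) -> DesignMatrix:
    """Assemble the concatenated-run design matrix.

    Task columns (one per condition, shared across runs) are 8 s boxcars
    convolved with the HRF and sampled at volume acquisition times. Each run
    contributes its own orthonormal polynomial drift columns up to
    ``drift_order`` (order 0 is the run intercept). ``motion``, if given, is
    a full-length T×M array appended unchanged.
    """
    if not schedules:
        raise ScheduleError("no run schedules given")
    tr = schedules[0].tr_s
    n_vols = [s.n_volumes for s in schedules]
    T = sum(n_vols)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if include_task:
        task = np.vstack([_task_regressors(s, hrf_params) for s in schedules])
        keep = [j for j in range(task.shape[1]) if np.any(task[:, j] != 0)]
        if include_task and not keep:
            raise ScheduleError("all task regressors are empty")
        for j in keep:
            cols.append(task[:, j])
            names.append(ALL_CONDITIONS[j].label)
    offset = 0
    for r, (s, n) in enumerate(zip(schedules, n_vols)):
        basis = _ortho_poly(n, drift_order)
        for k in range(drift_order + 1):
            col = np.zeros(T)
            col[offset : offset + n] = basis[:, k]
            cols.append(col)
            names.append(f"run{r}_drift{k}")
        offset += n
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape[0] != T:
            raise ScheduleError(
                f"motion regressors have {motion.shape[0]} rows, expected {T}"
            )
        for m in range(motion.shape[1]):
            cols.append(motion[:, m])
            names.append(f"motion{m}")
    return DesignMatrix(np.column_stack(cols), tuple(names), tr)


def build_nuisance_matrix(
    schedules: list[RunSchedule],
    drift_order: int = 2,
    motion: np.ndarray | None = None,
) -> DesignMatrix:
    """Nuisance-only design (drift + motion), used before pattern extraction."""
    return build_design_matrix(
        schedules, drift_order=drift_order, motion=motion, include_task=False
    )


def write_events_tsv(schedule: RunSchedule, path: str | Path) -> pd.DataFrame:
    """Write one run's block timings as a BIDS-style events.tsv."""
    df = pd.DataFrame(
        {
            "onset": [b.onset_s for b in schedule.blocks],
            "duration": [b.duration_s for b in schedule.blocks],
            "trial_type": [b.condition.label for b in schedule.blocks],
        }
    )
    df.to_csv(path, sep="\t", index=False)
    return df
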