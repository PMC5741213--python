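"""End-to-end orchestration: design → synthetic subjects → GLM → decoding → stats.

A single master seed drives every stage through a documented splitting rule
(child seed = SHA-256 hash of master seed, stage name and subject id,
reduced below 2**31), so a full experiment is bit-reproducible. The default
experiment emulates the study conditions: 10 subjects, 8 runs of 16
conditions, ROIs PPA, RSC, OPA and LOC with the PPA split into posterior
and anterior halves (generated as separate pattern regions so their signal
can differ, analyzed both separately and as their union), 4-way category
decoding per frequency condition, binary frequency decoding for scenes and
noise, and univariate HSF-vs-LSF contrasts.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .decode import DecoderConfig, DecodingResult, decode_category, decode_frequency
from .expdesign import CATEGORIES, build_design_matrix, make_schedule, write_events_tsv
from .preproc_glm import (
    PatternSample,
    extract_subject_patterns,
    fit_glm,
    percent_signal_change,
)
from .stats import GroupStats, StatsError, one_sample_t, paired_t
from .synthbold import (
    RoiSpec,
    SyntheticConfig,
    make_box_roi,
    simulate_subject,
    split_roi_ap,
)

__all__ = [
    "PipelineConfig",
    "PipelineError",
    "child_seed",
    "default_rois",
    "run_experiment",
    "univariate_contrast",
]

DEFAULT_ROI_NAMES = ("PPA", "RSC", "OPA", "LOC")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message carries the stage name."""


def child_seed(master_seed: int, *parts) -> int:
    """Deterministic child seed from the master seed and stage labels."""
    key = ":".join([str(master_seed), *map(str, parts)])
    digest = hashlib.sha256(key.encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass(frozen=True)
class PipelineConfig:
    """Master configuration of a full synthetic experiment."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    decoder: DecoderConfig = field(default_factory=DecoderConfig)
    n_runs: int = 8
    roi_names: tuple[str, ...] = DEFAULT_ROI_NAMES
    split_ppa: bool = True
    drift_order: int = 2
    master_seed: int = 0
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(
            {
                "synthetic": {
                    k: ({str(kk): vv for kk, vv in v.items()} if isinstance(v, Mapping) else v)
                    for k, v in vars(self.synthetic).items()
                },
                "decoder": vars(self.decoder),
                "n_runs": self.n_runs,
                "roi_names": list(self.roi_names),
                "split_ppa": self.split_ppa,
                "drift_order": self.drift_order,
                "master_seed": self.master_seed,
            },
            sort_keys=True,
            default=str,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _box_shape(n_voxels: int) -> tuple[int, int, int]:
    """Pick a box with a clear anterior-posterior (axis 1) extent."""
    depth = max(2, int(round(n_voxels ** (1 / 3))))
    while n_voxels % depth:
        depth -= 1
    rest = n_voxels // depth
    width = max(1, int(round(np.sqrt(rest))))
    while rest % width:
        width -= 1
    return (width, depth, rest // width)


def default_rois(config: PipelineConfig) -> list[RoiSpec]:
    """Generator regions: axis-aligned boxes of ``n_voxels`` each.

    With ``split_ppa`` the PPA box is generated as two separate regions
    (pPPA, aPPA) so their embedded signal can be configured independently;
    the analysis-level PPA is their union.
    """
    shape = _box_shape(config.synthetic.n_voxels)
    rois: list[RoiSpec] = []
    for i, name in enumerate(config.roi_names):
        box = make_box_roi(name, (i * (shape[0] + 2), 0, 0), shape)
        if config.split_ppa and name == "PPA":
            rois.extend(split_roi_ap(box))  # pPPA, aPPA
        else:
            rois.append(box)
    return rois


def analysis_roi_map(config: PipelineConfig) -> dict[str, tuple[str, ...]]:
    """Analysis ROI name → the generator region names it spans."""
    out: dict[str, tuple[str, ...]] = {}
    for name in config.roi_names:
        if config.split_ppa and name == "PPA":
            out["PPA"] = ("pPPA", "aPPA")
            out["pPPA"] = ("pPPA",)
            out["aPPA"] = ("aPPA",)
        else:
            out[name] = (name,)
    return out


def univariate_contrast(
    betas_by_subject: list[Mapping[str, float]],
    condition_a: str,
    condition_b: str,
    roi: str = "",
) -> GroupStats:
    """Paired two-tailed t-test between ROI-mean betas of two conditions.

    ``betas_by_subject`` holds one mapping per subject from condition label
    to the ROI-mean beta.
    """
    if condition_a == condition_b:
        raise StatsError("cannot contrast a condition with itself")
    a = [s[condition_a] for s in betas_by_subject]
    b = [s[condition_b] for s in betas_by_subject]
    return paired_t(a, b, tail="two", comparison=f"{roi}: {condition_a} vs {condition_b}")


def _scene_mean_betas(fit, sf_condition: str, rows: np.ndarray) -> float:
    cols = [f"{cat}_{sf_condition}" for cat in CATEGORIES]
    return float(np.mean([fit.beta(c)[rows].mean() for c in cols]))


def _restrict(sample: PatternSample, rows: np.ndarray) -> PatternSample:
    return PatternSample(
        sample.vector[rows], sample.condition, sample.run_id, sample.subject_id
    )


def run_experiment(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic experiment and aggregate group statistics.

    Returns a dict with ``subjects`` (per-subject decoding results),
    ``group`` (DataFrame of t/p/d per ROI × analysis: category decoding in
    FS/LSF/HSF, frequency decoding for scenes and noise, vs chance),
    ``univariate`` (HSF-vs-LSF paired contrasts per ROI) and
    ``config_hash``. When ``config.out_dir`` is set, per-subject
    events.tsv/decoding JSON and group TSV tables are written there.
    """
    config = config or PipelineConfig()
    stage = "setup"
    try:
        rois = default_rois(config)
        roi_map = analysis_roi_map(config)
        out_dir = Path(config.out_dir) if config.out_dir else None
        if out_dir:
            out_dir.mkdir(parents=True, exist_ok=True)

        subject_results: dict[str, dict] = {}
        acc: dict[tuple, dict] = {}
        uni_betas: dict[str, list[dict[str, float]]] = {n: [] for n in roi_map}

        for si in range(config.synthetic.n_subjects):
            sub = f"sub-{si + 1:02d}"
            stage = f"simulate:{sub}"
            schedules = make_schedule(
                child_seed(config.master_seed, "schedule", sub), n_runs=config.n_runs
            )
            runs, truth = simulate_subject(
                config.synthetic,
                rois,
                schedules,
                subject_id=sub,
                seed=child_seed(config.master_seed, "subject", sub),
            )
            stage = f"preproc:{sub}"
            psc_runs = [percent_signal_change(r) for r in runs]

            # univariate path: full GLM on percent-signal-change data
            motion = (
                np.vstack([r.motion for r in runs])
                if all(r.motion is not None for r in runs)
                else None
            )
            X = build_design_matrix(schedules, drift_order=config.drift_order, motion=motion)
            fit = fit_glm(np.hstack([r.data for r in psc_runs]), X)

            # multivariate path: nuisance-only GLM residuals → patterns
            stage = f"patterns:{sub}"
            patterns = extract_subject_patterns(psc_runs, drift_order=config.drift_order)

            stage = f"decode:{sub}"
            sub_res: dict[str, dict] = {}
            for aname, parents in roi_map.items():
                rows = np.concatenate(
                    [
                        np.arange(truth["roi_slices"][p].start, truth["roi_slices"][p].stop)
                        for p in parents
                    ]
                )
                roi_samples = [_restrict(s, rows) for s in patterns]
                res: dict[str, DecodingResult] = {}
                for sf in ("FS", "LSF", "HSF"):
                    res[f"category_{sf}"] = decode_category(
                        roi_samples, sf, config.decoder, sub, aname
                    )
                res["frequency_scenes"] = decode_frequency(
                    roi_samples, "scenes", config.decoder, sub, aname
                )
                res["frequency_noise"] = decode_frequency(
                    roi_samples, "noise", config.decoder, sub, aname
                )
                sub_res[aname] = {k: v.to_dict() for k, v in res.items()}
                for k, v in res.items():
                    acc.setdefault((aname, k), {"chance": v.chance_level})[sub] = v.mean_accuracy
                uni_betas[aname].append(
                    {sf: _scene_mean_betas(fit, sf, rows) for sf in ("FS", "LSF", "HSF")}
                )
            subject_results[sub] = sub_res
            if out_dir:
                sdir = out_dir / sub
                sdir.mkdir(exist_ok=True)
                for r, sched in enumerate(schedules):
                    write_events_tsv(sched, sdir / f"run-{r + 1}_events.tsv")
                (sdir / "decoding.json").write_text(
                    json.dumps(sub_res, indent=2, sort_keys=True)
                )

        stage = "group"
        group_rows = []
        for (aname, analysis), values in sorted(acc.items()):
            chance = values.pop("chance")
            accs = [values[s] for s in sorted(values)]
            try:
                gs = one_sample_t(accs, chance, tail="one",
                                  comparison=f"{aname} {analysis} vs chance")
                t, p, d = gs.t, gs.p, gs.d
            except StatsError:  # zero variance across subjects (e.g. all at ceiling)
                t, p, d = np.nan, np.nan, np.nan
            group_rows.append(
                {
                    "roi": aname,
                    "analysis": analysis,
                    "mean_accuracy": float(np.mean(accs)),
                    "chance": chance,
                    "t": t,
                    "p": p,
                    "d": d,
                    "n": len(accs),
                }
            )
        group = pd.DataFrame(group_rows)

        uni_rows = []
        for aname, per_sub in uni_betas.items():
            try:
                gs = univariate_contrast(per_sub, "HSF", "LSF", roi=aname)
                t, p, d, n = gs.t, gs.p, gs.d, gs.n
            except StatsError:
                t, p, d, n = np.nan, np.nan, np.nan, len(per_sub)
            uni_rows.append(
                {
                    "roi": aname,
                    "contrast": "HSF-LSF",
                    "mean_diff": float(np.mean([s["HSF"] - s["LSF"] for s in per_sub])),
                    "t": t,
                    "p": p,
                    "d": d,
                    "n": n,
                }
            )
        univariate = pd.DataFrame(uni_rows)

        if out_dir:
            gdir = out_dir / "group"
            gdir.mkdir(exist_ok=True)
            group.to_csv(gdir / "decoding_stats.tsv", sep="\t", index=False)
            univariate.to_csv(gdir / "univariate_stats.tsv", sep="\t", index=False)

        return {
            "subjects": subject_results,
            "group": group,
            "univariate": univariate,
            "config_hash": config.config_hash(),
        }
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(
            f"stage {stage!r} failed (config {config.config_hash()}): {exc}"
        ) from exc
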