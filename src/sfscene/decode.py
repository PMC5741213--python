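"""Leave-one-run-out (LORO) linear SVM decoding of multi-voxel patterns.

A linear support vector machine is trained on the pattern samples of all
but one run and tested on the left-out run, repeating over every run. The
penalty parameter defaults to C = 5e-6: with few, high-dimensional and
hence linearly separable training samples, a very low C favors large-margin
boundaries that generalize better out of sample. Multiclass problems use
one-vs-one voting; ties are broken by the largest summed decision value,
then by the lowest class index. Patterns are used exactly as produced by
the preprocessing — no per-fold feature scaling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
from sklearn.svm import SVC

from .preproc_glm import PatternSample

__all__ = [
    "DecoderConfig",
    "DecodingResult",
    "DecodingError",
    "loro_cv",
    "decode_category",
    "decode_frequency",
]

DEFAULT_C = 5e-6


class DecodingError(ValueError):
    """Invalid decoding setup (missing classes, too few runs, ...)."""


@dataclass(frozen=True)
class DecoderConfig:
    """Linear SVM decoding configuration."""

    c_param: float = DEFAULT_C
    multiclass_scheme: str = "one-vs-one"

    def __post_init__(self) -> None:
        if self.c_param <= 0:
            raise DecodingError("c_param must be positive")
        if self.multiclass_scheme not in ("one-vs-one",):
            raise DecodingError(f"unsupported multiclass scheme {self.multiclass_scheme!r}")


@dataclass(frozen=True)
class DecodingResult:
    """Per-fold and mean LORO accuracies with the task's chance level."""

    per_fold_accuracy: tuple[float, ...]
    chance_level: float
    classes: tuple[str, ...]
    fold_runs: tuple[int, ...]
    subject_id: str = ""
    roi: str = ""

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_fold_accuracy))

    def to_dict(self) -> dict:
        return {
            "per_fold_accuracy": list(self.per_fold_accuracy),
            "mean_accuracy": self.mean_accuracy,
            "chance_level": self.chance_level,
            "classes": list(self.classes),
            "fold_runs": list(self.fold_runs),
            "subject_id": self.subject_id,
            "roi": self.roi,
        }


def _ovo_predict(clf: SVC, classes: np.ndarray, X: np.ndarray) -> np.ndarray:
    """One-vs-one majority vote from pairwise decision values.

    Ties go to the class with the largest summed signed decision value,
    then to the lowest class index.
    """
    n_cls = len(classes)
    if n_cls == 2:
        d = clf.decision_function(X)
        return np.where(d > 0, clf.classes_[1], clf.classes_[0])
    dec = clf.decision_function(X)  # n_samples × n_pairs, ovo ordering
    votes = np.zeros((X.shape[0], n_cls))
    scores = np.zeros((X.shape[0], n_cls))
    k = 0
    for i in range(n_cls):
        for j in range(i + 1, n_cls):
            d = dec[:, k]
            votes[:, i] += d > 0
            votes[:, j] += d <= 0
            scores[:, i] += d
            scores[:, j] -= d
            k += 1
    # lexicographic: votes, then summed decision value, then low index
    winner = np.empty(X.shape[0], dtype=int)
    for s in range(X.shape[0]):
        best = np.flatnonzero(votes[s] == votes[s].max())
        if len(best) > 1:
            best = best[scores[s, best] == scores[s, best].max()]
        winner[s] = best[0]
    return clf.classes_[winner]


def loro_cv(
    samples: Sequence[PatternSample],
    label_fn: Callable[[PatternSample], str],
    config: DecoderConfig | None = None,
    subject_id: str = "",
    roi: str = "",
) -> DecodingResult:
    """Leave-one-run-out cross-validated linear SVM decoding.

    For each run r the classifier is trained on all samples with run != r
    and tested on run r; the result collects per-fold accuracies. Raises if
    a class is absent from any training fold.
    """
    config = config or DecoderConfig()
    if not samples:
        raise DecodingError("no samples to decode")
    X = np.vstack([s.vector for s in samples])
    y = np.array([label_fn(s) for s in samples])
    runs = np.array([s.run_id for s in samples])
    run_ids = np.unique(runs)
    if len(run_ids) < 2:
        raise DecodingError("leave-one-run-out needs at least 2 runs")
    classes = np.unique(y)
    accs = []
    for r in run_ids:
        train = runs != r
        test = ~train
        assert not set(runs[train]) & set(runs[test])  # no leakage across folds
        missing = sorted(str(c) for c in set(classes) - set(y[train]))
        if missing:
            raise DecodingError(
                f"class(es) {missing} absent from the training fold leaving out run {r}"
            )
        clf = SVC(kernel="linear", C=config.c_param, decision_function_shape="ovo")
        clf.fit(X[train], y[train])
        pred = _ovo_predict(clf, classes, X[test])
        accs.append(float(np.mean(pred == y[test])))
    return DecodingResult(
        per_fold_accuracy=tuple(accs),
        chance_level=1.0 / len(classes),
        classes=tuple(str(c) for c in classes),
        fold_runs=tuple(int(r) for r in run_ids),
        subject_id=subject_id,
        roi=roi,
    )


def decode_category(
    samples: Sequence[PatternSample],
    condition: str,
    config: DecoderConfig | None = None,
    subject_id: str = "",
    roi: str = "",
) -> DecodingResult:
    """4-way scene-category decoding within one frequency condition.

    ``condition`` is FS, LSF or HSF; samples are filtered to the four scene
    categories of that condition (4 categories × 8 runs = 32 samples in the
    default design). Chance level is 0.25.
    """
    if condition not in ("FS", "LSF", "HSF"):
        raise DecodingError(f"unknown scene condition {condition!r}")
    sel = [s for s in samples if s.condition.is_scene and s.condition.sf_condition == condition]
    if not sel:
        raise DecodingError(f"no scene samples for condition {condition}")
    return loro_cv(sel, lambda s: s.condition.category, config, subject_id, roi)


def decode_frequency(
    samples: Sequence[PatternSample],
    stimulus_class: str = "scenes",
    config: DecoderConfig | None = None,
    subject_id: str = "",
    roi: str = "",
    average_within_class: bool = False,
) -> DecodingResult:
    """Binary low- vs high-spatial-frequency decoding. Chance level 0.5.

    For ``scenes`` the LSF and HSF scene samples are used, ignoring the
    scene category (8 samples per run). For ``noise`` the four band
    conditions are relabeled low (0.75, 1.5 cpd) vs high (3, 6 cpd),
    4 samples per run; with ``average_within_class`` the two band patterns
    of each class are first averaged within each run (2 samples per run).
    """
    if stimulus_class == "scenes":
        sel = [s for s in samples if s.condition.is_scene and s.condition.frequency_class]
    elif stimulus_class == "noise":
        sel = [s for s in samples if s.condition.is_noise]
    else:
        raise DecodingError(f"unknown stimulus class {stimulus_class!r}")
    if not sel:
        raise DecodingError(f"no samples for stimulus class {stimulus_class}")
    if stimulus_class == "noise" and average_within_class:
        from .preproc_glm import PatternSample as _PS
        from .expdesign import Condition

        merged = []
        for r in sorted({s.run_id for s in sel}):
            for fc in ("low", "high"):
                group = [s for s in sel if s.run_id == r and s.condition.frequency_class == fc]
                if not group:
                    raise DecodingError(f"run {r} lacks {fc}-frequency noise samples")
                vec = np.mean([s.vector for s in group], axis=0)
                cond = Condition(label=f"noise_{fc}", frequency_class=fc)
                merged.append(_PS(vec, cond, r, group[0].subject_id))
        sel = merged
    return loro_cv(sel, lambda s: s.condition.frequency_class, config, subject_id, roi)


def save_result(result: DecodingResult, path: str | Path, config: DecoderConfig | None = None) -> None:
    """Write a decoding result (plus the config it used) as JSON."""
    payload = result.to_dict()
    if config is not None:
        payload["config"] = {"c_param": config.c_param, "multiclass_scheme": config.multiclass_scheme}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))
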