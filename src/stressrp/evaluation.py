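"""Leave-one-recording-out evaluation of the stress classifiers.

Folds are formed over whole recordings: each fold trains on all recordings
but one and tests on the held-out one, so no subject/session information
leaks between train and test.  Class rebalancing (undersampling or
duplication oversampling) is applied to the *training* split of each fold
only; test windows are never resampled.

Metrics follow the percentage-scale formulas

    accuracy  = (XP + XN) / (XP + XN + YP + YN) * 100
    precision = XP / (XP + YP) * 100
    recall    = XP / (XP + YN) * 100
    F1        = 2 * precision * recall / (precision + recall)

with XP/XN/YP/YN the true-positive/true-negative/false-positive/
false-negative counts and "stressed" the positive class; AUC is the
Mann-Whitney statistic (ties credited 1/2) on the stressed-class
probability.  Pooled metrics micro-average by summing fold counts.
"""

from __future__ import annotations

import dataclasses
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from stressrp import preprocess
from stressrp.models import (
    CLASSES,
    ModelSpec,
    TrainConfig,
    build_frozen_vgg_baseline,
    build_multimodal_1d_cnn,
    build_multimodal_cnn,
    build_unimodal_cnn,
    train_model,
)
from stressrp.recurrence import EmbeddingConfig, window_to_rp_images
from stressrp.synthetic import CHANNELS, RecordingSet, SimParams, simulate_cohort

__all__ = [
    "ConfusionCounts",
    "Metrics",
    "GridSearchSpace",
    "ExperimentConfig",
    "EvalReport",
    "NEURAL_TAGS",
    "CLASSICAL_TAGS",
    "loro_split",
    "grid_search",
    "confusion_counts",
    "classification_metrics",
    "roc_auc",
    "run_experiment",
]


@dataclass(frozen=True)
class ConfusionCounts:
    """Two-class confusion counts; ``xp``/``xn``/``yp``/``yn`` are the
    true-positive, true-negative, false-positive and false-negative counts
    for the designated positive class."""

    xp: int
    xn: int
    yp: int
    yn: int

    def __post_init__(self) -> None:
        if min(self.xp, self.xn, self.yp, self.yn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def total(self) -> int:
        return self.xp + self.xn + self.yp + self.yn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.xp + other.xp, self.xn + other.xn,
                               self.yp + other.yp, self.yn + other.yn)


@dataclass(frozen=True)
class Metrics:
    """Percentage-scale classification metrics; AUC on [0, 1] when defined."""

    accuracy: float
    precision: float
    recall: float
    f1: float
    auc: float | None = None

    def __post_init__(self) -> None:
        for name in ("accuracy", "precision", "recall", "f1"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0 + 1e-9:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.auc is not None and not 0.0 <= self.auc <= 1.0 + 1e-12:
            raise ValueError(f"auc={self.auc} outside [0, 1]")


def loro_split(recording_set: RecordingSet | list[str],
               ) -> list[tuple[list[str], str]]:
    """Leave-one-recording-out folds, ordered by recording id.

    Returns ``(train_ids, test_id)`` pairs: each recording is the test
    singleton of exactly one fold.
    """
    ids = (recording_set.ids if isinstance(recording_set, RecordingSet)
           else list(recording_set))
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate recording ids: {ids}")
    if len(ids) < 2:
        raise ValueError("leave-one-recording-out needs >= 2 recordings")
    ordered = sorted(ids)
    return [([i for i in ordered if i != test], test) for test in ordered]


def confusion_counts(y_true, y_pred,
                     positive: str = "stressed") -> ConfusionCounts:
    """Exhaustive two-class confusion tally with the given positive class."""
    if len(y_true) != len(y_pred):
        raise ValueError(f"length mismatch: {len(y_true)} vs {len(y_pred)}")
    xp = xn = yp = yn = 0
    for t, p in zip(y_true, y_pred):
        if t not in CLASSES or p not in CLASSES:
            raise ValueError(f"unknown label in pair ({t!r}, {p!r})")
        if t == positive:
            if p == positive:
                xp += 1
            else:
                yn += 1
        else:
            if p == positive:
                yp += 1
            else:
                xn += 1
    return ConfusionCounts(xp, xn, yp, yn)


def classification_metrics(c: ConfusionCounts) -> Metrics:
    """Accuracy/precision/recall/F1 on the 0-100 scale.

    Zero-denominator precision, recall or F1 are defined as 0.
    """
    if c.total == 0:
        raise ValueError("cannot compute metrics on zero counts")
    accuracy = (c.xp + c.xn) / c.total * 100.0
    precision = c.xp / (c.xp + c.yp) * 100.0 if c.xp + c.yp else 0.0
    recall = c.xp / (c.xp + c.yn) * 100.0 if c.xp + c.yn else 0.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    return Metrics(accuracy=accuracy, precision=precision, recall=recall,
                   f1=f1)


def roc_auc(scores, labels) -> float:
    """Mann-Whitney AUC of the stressed-class scores; ties count 1/2."""
    scores = np.asarray(scores, dtype=float)
    pos = np.array([lbl == "stressed" for lbl in labels])
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2)
                 / (n_pos * n_neg))


@dataclass(frozen=True)
class GridSearchSpace:
    """Hyperparameter candidates for grid search.

    The default grid covers learning-rate decades 0.1 down to 1e-5,
    batch sizes up to 20 and epoch counts up to 30, coarsened to stay
    desk-tractable; :meth:`full` enumerates every batch size 1-20 and
    epoch count 1-30.
    """

    learning_rates: tuple[float, ...] = (0.1, 0.01, 0.001, 1e-4, 1e-5)
    batch_sizes: tuple[int, ...] = (1, 2, 4, 8, 16, 20)
    epochs: tuple[int, ...] = (5, 10, 15, 20, 30)

    def __post_init__(self) -> None:
        if not (self.learning_rates and self.batch_sizes and self.epochs):
            raise ValueError("grid dimensions must be non-empty")
        if (min(self.learning_rates) <= 0 or min(self.batch_sizes) < 1
                or min(self.epochs) < 1):
            raise ValueError("grid values must be positive")

    @classmethod
    def full(cls) -> "GridSearchSpace":
        return cls(learning_rates=(0.1, 0.01, 0.001, 1e-4, 1e-5),
                   batch_sizes=tuple(range(1, 21)),
                   epochs=tuple(range(1, 31)))

    def configs(self, seed: int = 0) -> list[TrainConfig]:
        """All candidates in deterministic lexicographic order."""
        return [TrainConfig(learning_rate=lr, batch_size=b, epochs=e,
                            seed=seed)
                for lr in sorted(self.learning_rates)
                for b in sorted(self.batch_sizes)
                for e in sorted(self.epochs)]


def grid_search(space: GridSearchSpace, dataset, protocol,
                seed: int = 0) -> TrainConfig:
    """Pick the config with the highest mean validation accuracy.

    ``protocol(dataset, config)`` must return a scalar validation accuracy.
    Ties break toward the first candidate in lexicographic config order; a
    singleton space is returned without invoking the protocol.
    """
    if dataset is None or (hasattr(dataset, "__len__") and len(dataset) == 0):
        raise ValueError("grid search needs a non-empty dataset")
    candidates = space.configs(seed=seed)
    if len(candidates) == 1:
        return candidates[0]
    best_config, best_score = None, -np.inf
    for config in candidates:
        score = float(protocol(dataset, config))
        if score > best_score:
            best_config, best_score = config, score
    return best_config


NEURAL_TAGS = ("multimodal-cnn", "unimodal-cnn:fgsr", "unimodal-cnn:hgsr",
               "unimodal-cnn:hr", "multimodal-1d-cnn", "frozen-vgg")
CLASSICAL_TAGS = ("xgboost", "random-forest", "svm", "logistic-regression")


@dataclass
class ExperimentConfig:
    """Everything needed to reproduce one evaluation run."""

    n_recordings: int = 9
    sim_params: SimParams = field(default_factory=SimParams)
    window_length_s: float = 30.0
    stride_s: float | None = None
    embedding: EmbeddingConfig = field(default_factory=EmbeddingConfig)
    image_size: int = 64
    model_spec: ModelSpec = field(default_factory=ModelSpec)
    train_config: TrainConfig = field(default_factory=TrainConfig)
    balancing: str = "undersample"
    model_tags: tuple[str, ...] = ("multimodal-cnn",)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.balancing not in ("none", "undersample", "oversample"):
            raise ValueError(f"unknown balancing mode {self.balancing!r}")
        known = set(NEURAL_TAGS) | set(CLASSICAL_TAGS)
        unknown = [t for t in self.model_tags if t not in known]
        if unknown:
            raise ValueError(f"unknown model tags {unknown}; "
                             f"choose from {sorted(known)}")


@dataclass
class EvalReport:
    """Per-fold and pooled metrics for every evaluated model."""

    config: dict
    results: dict = field(default_factory=dict)

    CSV_HEADER = ("model,window_s,balancing,fold,test_recording,n_train,"
                  "n_test,accuracy,auc,precision_stressed,recall_stressed,"
                  "f1_stressed,precision_relaxed,recall_relaxed,f1_relaxed")

    def to_dict(self) -> dict:
        return {"config": self.config, "results": self.results}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def to_csv(self, path: str | Path | None = None) -> str:
        lines = [self.CSV_HEADER]
        window = self.config.get("window_length_s")
        balancing = self.config.get("balancing")
        for tag, res in self.results.items():
            rows = res["folds"] + [res["pooled"]]
            for row in rows:
                stressed = row["per_class"]["stressed"]
                relaxed = row["per_class"]["relaxed"]
                auc = row["auc"]
                lines.append(",".join(str(v) for v in (
                    tag, window, balancing, row["fold"],
                    row.get("test_recording", "-"),
                    row["n_train"], row["n_test"],
                    f"{row['accuracy']:.4f}",
                    "-" if auc is None else f"{auc:.6f}",
                    f"{stressed['precision']:.4f}",
                    f"{stressed['recall']:.4f}", f"{stressed['f1']:.4f}",
                    f"{relaxed['precision']:.4f}",
                    f"{relaxed['recall']:.4f}", f"{relaxed['f1']:.4f}",
                )))
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    def pooled_accuracy(self, tag: str) -> float:
        return self.results[tag]["pooled"]["accuracy"]

    def pooled_auc(self, tag: str) -> float | None:
        return self.results[tag]["pooled"]["auc"]


def repeat_experiment(config: ExperimentConfig,
                      seeds: list[int],
                      recording_set: RecordingSet | None = None) -> dict:
    """Run an experiment under several master seeds; report mean +/- SD.

    Returns ``{tag: {"accuracy_mean", "accuracy_sd", "auc_mean", "auc_sd",
    "n_runs"}}`` over the pooled metrics of each run.
    """
    if not seeds:
        raise ValueError("need at least one seed")
    per_tag: dict[str, dict[str, list[float]]] = {}
    for seed in seeds:
        report = run_experiment(dataclasses.replace(config, seed=seed),
                                recording_set)
        for tag in config.model_tags:
            entry = per_tag.setdefault(tag, {"accuracy": [], "auc": []})
            entry["accuracy"].append(report.pooled_accuracy(tag))
            auc = report.pooled_auc(tag)
            if auc is not None:
                entry["auc"].append(auc)
    out = {}
    for tag, entry in per_tag.items():
        acc = np.array(entry["accuracy"])
        auc = np.array(entry["auc"])
        out[tag] = {
            "accuracy_mean": float(acc.mean()),
            "accuracy_sd": float(acc.std(ddof=1)) if len(acc) > 1 else 0.0,
            "auc_mean": float(auc.mean()) if auc.size else None,
            "auc_sd": (float(auc.std(ddof=1)) if auc.size > 1 else 0.0),
            "n_runs": len(seeds),
        }
    return out


def _derive_seed(*parts) -> int:
    ints = [p if isinstance(p, int) else zlib.crc32(str(p).encode())
            for p in parts]
    return int(np.random.SeedSequence(ints).generate_state(1)[0] % (2**31))


def _balance(windows, mode: str, seed: int):
    if mode == "undersample":
        return preprocess.undersample_majority(windows, seed)
    if mode == "oversample":
        counts = preprocess.class_counts(windows)
        return preprocess.oversample_with_replacement(
            windows, max(counts.values()), seed)
    return list(windows)


class _Representations:
    """Lazy per-window feature caches shared across folds and models."""

    def __init__(self, windows, config: ExperimentConfig):
        self.windows = windows
        self.config = config
        self._rp = None
        self._seq = None
        self._features = None

    @property
    def labels(self) -> list[str]:
        return [w.label for w in self.windows]

    def rp(self) -> np.ndarray:
        if self._rp is None:
            cfg = self.config
            stacks = []
            for w in self.windows:
                images = window_to_rp_images(w, out_size=cfg.image_size,
                                             config=cfg.embedding)
                stacks.append(np.stack([images[c].pixels for c in CHANNELS]))
            self._rp = np.stack(stacks).astype(np.float32)
        return self._rp

    def seq(self) -> np.ndarray:
        if self._seq is None:
            self._seq = np.stack([
                np.stack([preprocess.minmax_normalize(w.channels[c])
                          for c in CHANNELS])
                for w in self.windows]).astype(np.float32)
        return self._seq

    def features(self) -> np.ndarray:
        if self._features is None:
            self._features = np.stack([
                preprocess.extract_tabular_features(w).values
                for w in self.windows])
        return self._features


def _build_neural(tag: str, config: ExperimentConfig, seed: int):
    spec = dataclasses.replace(config.model_spec,
                               input_size=config.image_size)
    if tag == "multimodal-cnn":
        return build_multimodal_cnn(spec, seed=seed)
    if tag.startswith("unimodal-cnn:"):
        return build_unimodal_cnn(spec, tag.split(":", 1)[1], seed=seed)
    if tag == "multimodal-1d-cnn":
        return build_multimodal_1d_cnn(spec, seed=seed)
    if tag == "frozen-vgg":
        return build_frozen_vgg_baseline(spec, seed=seed)
    raise ValueError(f"not a neural tag: {tag}")


def _build_classical(tag: str, seed: int):
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.svm import SVC
    from xgboost import XGBClassifier

    if tag == "xgboost":
        return XGBClassifier(n_estimators=100, max_depth=4,
                             random_state=seed, n_jobs=1,
                             eval_metric="logloss")
    if tag == "random-forest":
        return RandomForestClassifier(n_estimators=200, random_state=seed,
                                      n_jobs=1)
    if tag == "svm":
        return make_pipeline(StandardScaler(),
                             SVC(probability=True, random_state=seed))
    if tag == "logistic-regression":
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000,
                                                random_state=seed))
    raise ValueError(f"not a classical tag: {tag}")


def _select(tag: str, reps: _Representations, idx: np.ndarray) -> np.ndarray:
    if tag in CLASSICAL_TAGS:
        return reps.features()[idx]
    if tag == "multimodal-1d-cnn":
        return reps.seq()[idx]
    x = reps.rp()[idx]
    if tag.startswith("unimodal-cnn:"):
        channel = tag.split(":", 1)[1]
        return x[:, CHANNELS.index(channel):CHANNELS.index(channel) + 1]
    return x


def _fold_record(fold_name, test_recording, n_train, n_test,
                 y_true, y_pred, scores) -> dict:
    per_class = {}
    for cls in CLASSES:
        m = classification_metrics(confusion_counts(y_true, y_pred,
                                                    positive=cls))
        per_class[cls] = {"precision": m.precision, "recall": m.recall,
                          "f1": m.f1}
    overall = classification_metrics(confusion_counts(y_true, y_pred))
    try:
        auc = roc_auc(scores, y_true)
    except ValueError:
        auc = None
    c = confusion_counts(y_true, y_pred)
    return {
        "fold": fold_name,
        "test_recording": test_recording,
        "n_train": int(n_train),
        "n_test": int(n_test),
        "counts": {"xp": c.xp, "xn": c.xn, "yp": c.yp, "yn": c.yn},
        "accuracy": overall.accuracy,
        "auc": auc,
        "per_class": per_class,
    }


def run_experiment(config: ExperimentConfig,
                   recording_set: RecordingSet | None = None) -> EvalReport:
    """Full LORO evaluation loop for every requested model tag.

    Simulates a cohort when no ``recording_set`` is given.  Per fold:
    rebalance the training split only, train, predict the held-out
    recording, tally counts.  Pooled metrics are micro-averages of the
    summed fold counts; pooled AUC is computed over all pooled test scores.
    """
    if recording_set is None:
        recording_set = simulate_cohort(
            config.n_recordings, config.sim_params,
            seed=_derive_seed(config.seed, "cohort"))

    windows = []
    for rec in recording_set.recordings:
        windows.extend(preprocess.segment_windows(
            rec, config.window_length_s, config.stride_s))
    if not windows:
        raise ValueError("no labeled windows produced; check window length")
    reps = _Representations(windows, config)
    position_of = {id(w): i for i, w in enumerate(windows)}
    rec_ids = np.array([w.recording_id for w in windows])
    labels = np.array(reps.labels)
    folds = loro_split(recording_set)

    report = EvalReport(config={
        "n_recordings": len(recording_set.recordings),
        "window_length_s": config.window_length_s,
        "stride_s": config.stride_s,
        "image_size": config.image_size,
        "embedding": dataclasses.asdict(config.embedding),
        "balancing": config.balancing,
        "model_tags": list(config.model_tags),
        "train_config": dataclasses.asdict(config.train_config),
        "seed": config.seed,
        "n_windows": len(windows),
    })

    for tag in config.model_tags:
        fold_rows = []
        pooled_counts = ConfusionCounts(0, 0, 0, 0)
        pooled_scores: list[float] = []
        pooled_true: list[str] = []
        pooled_pred: list[str] = []
        pooled_train = 0
        for fold_index, (train_ids, test_id) in enumerate(folds):
            train_mask = np.isin(rec_ids, train_ids)
            test_mask = rec_ids == test_id
            train_windows = [w for w, m in zip(windows, train_mask) if m]
            balanced = _balance(train_windows, config.balancing,
                                _derive_seed(config.seed, "balance",
                                             fold_index, tag))
            train_idx = np.array([position_of[id(w)] for w in balanced],
                                 dtype=int)
            test_idx = np.flatnonzero(test_mask)

            x_train = _select(tag, reps, train_idx)
            x_test = _select(tag, reps, test_idx)
            y_train = labels[train_idx]
            y_true = list(labels[test_idx])

            model_seed = _derive_seed(config.seed, "model", fold_index, tag)
            if tag in CLASSICAL_TAGS:
                clf = _build_classical(tag, model_seed)
                y_idx = np.array([CLASSES.index(lbl) for lbl in y_train])
                clf.fit(x_train, y_idx)
                proba = clf.predict_proba(x_test)
                scores = proba[:, list(clf.classes_).index(1)]
            else:
                handle = _build_neural(tag, config, model_seed)
                tc = dataclasses.replace(
                    config.train_config,
                    seed=_derive_seed(config.seed, "shuffle", fold_index,
                                      tag))
                trained = train_model(handle, x_train, list(y_train), tc)
                proba = trained.handle.predict_proba(x_test)
                scores = proba[:, CLASSES.index("stressed")]
            y_pred = [CLASSES[1] if s >= 0.5 else CLASSES[0]
                      for s in scores]

            row = _fold_record(fold_index, test_id, len(train_idx),
                               len(test_idx), y_true, y_pred, scores)
            fold_rows.append(row)
            pooled_counts = pooled_counts + confusion_counts(y_true, y_pred)
            pooled_scores.extend(float(s) for s in scores)
            pooled_true.extend(y_true)
            pooled_pred.extend(y_pred)
            pooled_train += len(train_idx)

        pooled = _fold_record("pooled", "-", pooled_train,
                              pooled_counts.total, pooled_true, pooled_pred,
                              pooled_scores)
        report.results[tag] = {"folds": fold_rows, "pooled": pooled}
    return report
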