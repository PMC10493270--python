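"""Two-stage training, subject-wise cross-validation, and metrics.

Stage 1 trains the per-channel transformer on individual CPD maps; stage 2
freezes it, extracts one feature vector per channel per segment, and trains
the graph-convolutional classifier on the electrode graph.  Evaluation uses
subject-exclusive k-fold cross-validation with per-fold metric averaging.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, replace
from typing import Callable, Sequence

import numpy as np

from .nn import Adam, Module, cross_entropy
from .preprocess import PreprocessConfig, preprocess_recording
from .spatial_gcn import SGCM, SGCMConfig, ElectrodeGraph
from .temporal_transformer import TTM, TTMConfig


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CPDDataset:
    """Stacked CPD maps for a cohort: one row per 60-s segment."""

    X: np.ndarray               # (n_segments, n_channels, freq_bins, frames)
    y: np.ndarray               # (n_segments,) integer class labels
    subject_ids: np.ndarray     # (n_segments,) str
    channels: tuple[str, ...]
    class_names: tuple[str, ...]
    freq_axis: np.ndarray

    def __post_init__(self):
        if not (len(self.X) == len(self.y) == len(self.subject_ids)):
            raise ValueError("X, y and subject_ids must have equal length")

    @property
    def n_segments(self) -> int:
        return len(self.y)

    @property
    def map_shape(self) -> tuple[int, int]:
        return self.X.shape[2], self.X.shape[3]


def _standardize_map(log_power: np.ndarray) -> np.ndarray:
    return (log_power - log_power.mean()) / (log_power.std() + 1e-8)


def build_cpd_dataset(recordings, pre_cfg: PreprocessConfig = PreprocessConfig(),
                      class_names: Sequence[str] = ("control", "nmdar", "viral"),
                      ) -> CPDDataset:
    """Preprocess a cohort into model-ready, per-map standardized log-power maps."""
    class_names = tuple(class_names)
    label_to_int = {name: i for i, name in enumerate(class_names)}
    rows, labels, subjects = [], [], []
    channels, freq_axis = None, None
    for rec in recordings:
        if rec.label not in label_to_int:
            raise ValueError(f"unknown label {rec.label!r}; expected {class_names}")
        for seg_maps in preprocess_recording(rec, pre_cfg):
            stack = np.stack([_standardize_map(m.log_values()) for m in seg_maps])
            rows.append(stack)
            labels.append(label_to_int[rec.label])
            subjects.append(rec.subject_id)
            if channels is None:
                channels = tuple(m.channel_name for m in seg_maps)
                freq_axis = seg_maps[0].freq_axis
    if not rows:
        raise ValueError("no segments produced from the supplied recordings")
    return CPDDataset(X=np.stack(rows), y=np.array(labels),
                      subject_ids=np.array(subjects), channels=channels,
                      class_names=class_names, freq_axis=freq_axis)


def subset_classes(ds: CPDDataset, classes: Sequence[str]) -> CPDDataset:
    """Restrict to a label subset, remapping labels to 0..len(classes)-1."""
    classes = tuple(classes)
    if len(set(classes)) != len(classes):
        raise ValueError("classes must be distinct")
    old = {name: i for i, name in enumerate(ds.class_names)}
    keep_ints = [old[c] for c in classes]
    mask = np.isin(ds.y, keep_ints)
    remap = {old[c]: i for i, c in enumerate(classes)}
    y = np.array([remap[v] for v in ds.y[mask]])
    return CPDDataset(X=ds.X[mask], y=y, subject_ids=ds.subject_ids[mask],
                      channels=ds.channels, class_names=classes,
                      freq_axis=ds.freq_axis)


# --------------------------------------------------------------------------
# cross-validation folds
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class FoldPlan:
    """Subject-exclusive fold assignment."""

    k: int
    assignments: dict[str, int]     # subject_id -> fold index

    def __post_init__(self):
        folds = set(self.assignments.values())
        if not folds <= set(range(self.k)):
            raise ValueError("fold indices out of range")

    def test_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.assignments.items() if f == fold}

    def train_subjects(self, fold: int) -> set[str]:
        return {s for s, f in self.assignments.items() if f != fold}


def make_subject_folds(subject_ids: Sequence[str], labels: Sequence[int],
                       k: int = 10, seed: int = 0) -> FoldPlan:
    """Class-stratified, subject-exclusive fold assignment.

    All samples of a subject share one fold; within each class, shuffled
    subjects are dealt round-robin across folds (rotating the starting fold
    between classes to keep fold sizes balanced).
    """
    subject_ids = np.asarray(subject_ids)
    labels = np.asarray(labels)
    subj_label: dict[str, int] = {}
    for s, lab in zip(subject_ids, labels):
        if s in subj_label and subj_label[s] != lab:
            raise ValueError(f"subject {s} appears with conflicting labels")
        subj_label[s] = int(lab)
    if len(subj_label) < k:
        raise ValueError(f"need at least k={k} subjects, got {len(subj_label)}")
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    offset = 0
    for lab in sorted(set(subj_label.values())):
        members = sorted(s for s, v in subj_label.items() if v == lab)
        rng.shuffle(members)
        for i, s in enumerate(members):
            assignments[s] = (i + offset) % k
        offset = (offset + len(members)) % k
    return FoldPlan(k=k, assignments=assignments)


# --------------------------------------------------------------------------
# metrics
# --------------------------------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: float
    recall: float
    precision: float
    f1: float
    confusion: np.ndarray                  # rows: true, cols: predicted
    class_names: tuple[str, ...]
    per_class: dict[str, dict[str, float]]
    auc: dict[str, float] | None = None

    def to_dict(self) -> dict:
        out = {"accuracy": self.accuracy, "recall": self.recall,
               "precision": self.precision, "f1": self.f1,
               "confusion": self.confusion.tolist(),
               "class_names": list(self.class_names),
               "per_class": self.per_class}
        if self.auc is not None:
            out["auc"] = self.auc
        return out


def compute_metrics(y_true, y_pred, n_classes: int,
                    class_names: Sequence[str] | None = None) -> MetricsReport:
    """Accuracy, recall, precision and F1 from TP/TN/FP/FN counts.

    Binary problems report the positive class (label 1); multiclass problems
    report macro averages of the per-class one-vs-rest values.  A class never
    predicted gets precision 0 by convention (likewise recall for a class
    never observed).
    """
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if arr.size and (arr.min() < 0 or arr.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    if class_names is None:
        class_names = tuple(str(i) for i in range(n_classes))
    class_names = tuple(class_names)

    confusion = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(confusion, (y_true, y_pred), 1)
    n = confusion.sum()
    accuracy = float(np.trace(confusion) / n) if n else 0.0

    per_class: dict[str, dict[str, float]] = {}
    precs, recs, f1s = [], [], []
    for c in range(n_classes):
        tp = confusion[c, c]
        fn = confusion[c].sum() - tp
        fp = confusion[:, c].sum() - tp
        prec = float(tp / (tp + fp)) if tp + fp else 0.0
        rec = float(tp / (tp + fn)) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        per_class[class_names[c]] = {"precision": prec, "recall": rec, "f1": f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)

    if n_classes == 2:
        precision, recall, f1 = precs[1], recs[1], f1s[1]
    else:
        precision = float(np.mean(precs))
        recall = float(np.mean(recs))
        f1 = float(np.mean(f1s))
    return MetricsReport(accuracy=accuracy, recall=recall, precision=precision,
                         f1=f1, confusion=confusion, class_names=class_names,
                         per_class=per_class)


def roc_auc(y_true, scores) -> np.ndarray:
    """Per-class one-vs-rest AUC from a (n, n_classes) score matrix."""
    from sklearn.metrics import roc_auc_score

    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=np.float64)
    if scores.ndim != 2 or scores.shape[0] != y_true.shape[0]:
        raise ValueError("scores must be (n_samples, n_classes)")
    if not np.isfinite(scores).all():
        raise ValueError("scores must be finite")
    if len(np.unique(y_true)) < 2:
        raise ValueError("AUC undefined: y_true contains a single class")
    aucs = []
    for c in range(scores.shape[1]):
        y_bin = (y_true == c).astype(int)
        if y_bin.min() == y_bin.max():
            aucs.append(np.nan)
        else:
            aucs.append(float(roc_auc_score(y_bin, scores[:, c])))
    return np.array(aucs)


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TrainConfig:
    stage1_epochs: int = 150
    stage1_lr: float = 1e-4
    stage2_epochs: int = 80
    stage2_lr: float = 1e-4
    batch_size: int = 32
    seed: int = 0

    def __post_init__(self):
        if self.stage1_epochs < 1 or self.stage2_epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.stage1_lr < 0 or self.stage2_lr < 0:
            raise ValueError("learning rates must be >= 0")

    @classmethod
    def test_profile(cls, **overrides) -> "TrainConfig":
        """Reduced-epoch profile for one-CPU runs; learning rates raised to
        compensate for the much shorter schedules."""
        kwargs = dict(stage1_epochs=15, stage1_lr=1e-3,
                      stage2_epochs=8, stage2_lr=2e-2, batch_size=32)
        kwargs.update(overrides)
        return cls(**kwargs)


def _sgd_epochs(forward: Callable, params, X: np.ndarray, y: np.ndarray,
                epochs: int, lr: float, batch_size: int,
                rng: np.random.Generator) -> list[float]:
    opt = Adam(params, lr=lr)
    history = []
    n = len(y)
    for _ in range(epochs):
        order = rng.permutation(n)
        total = 0.0
        for start in range(0, n, batch_size):
            idx = order[start:start + batch_size]
            loss = cross_entropy(forward(X[idx]), y[idx])
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += loss.item() * len(idx)
        history.append(total / n)
    return history


def _predict_logits_ttm(model: TTM, maps: np.ndarray, batch: int = 128) -> np.ndarray:
    out = []
    for start in range(0, len(maps), batch):
        out.append(model(maps[start:start + batch]).logits.data)
    return np.concatenate(out, axis=0)


def _softmax_np(z: np.ndarray) -> np.ndarray:
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def _state_hash(model: Module) -> str:
    h = hashlib.sha256()
    for name, p in sorted(model.named_parameters()):
        h.update(name.encode())
        h.update(np.ascontiguousarray(p.data).tobytes())
    return h.hexdigest()


@dataclass
class Stage1Result:
    model: TTM
    history: list[float]
    channel_accuracy: dict[str, float] | None = None
    channel_f1: dict[str, float] | None = None


def train_stage1(model: TTM, train_ds: CPDDataset, cfg: TrainConfig,
                 rng: np.random.Generator | int = 0,
                 eval_ds: CPDDataset | None = None) -> Stage1Result:
    """Train the shared transformer on all channels' CPD maps.

    If ``eval_ds`` is given, per-channel accuracy and macro-F1 on it are
    reported (the per-channel classification table of stage 1).
    """
    if train_ds.n_segments == 0:
        raise ValueError("empty training dataset")
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    n_ch = len(train_ds.channels)
    f, t = train_ds.map_shape
    Xm = train_ds.X.reshape(-1, f, t)
    ym = np.repeat(train_ds.y, n_ch)
    history = _sgd_epochs(lambda xb: model(xb).logits, model.parameters(),
                          Xm, ym, cfg.stage1_epochs, cfg.stage1_lr,
                          cfg.batch_size, rng)
    result = Stage1Result(model=model, history=history)
    if eval_ds is not None:
        acc, f1 = per_channel_metrics(model, eval_ds)
        result.channel_accuracy, result.channel_f1 = acc, f1
    return result


def per_channel_metrics(model: TTM, ds: CPDDataset
                        ) -> tuple[dict[str, float], dict[str, float]]:
    """Accuracy and macro-F1 of the stage-1 classifier per EEG channel."""
    acc: dict[str, float] = {}
    f1: dict[str, float] = {}
    n_classes = len(ds.class_names)
    for ci, ch in enumerate(ds.channels):
        logits = _predict_logits_ttm(model, ds.X[:, ci])
        pred = logits.argmax(axis=1)
        report = compute_metrics(ds.y, pred, n_classes, ds.class_names)
        acc[ch] = report.accuracy
        macro = float(np.mean([v["f1"] for v in report.per_class.values()]))
        f1[ch] = macro
    return acc, f1


def extract_features(model: TTM, ds: CPDDataset, batch: int = 128) -> np.ndarray:
    """Frozen-transformer node features: (n_segments, n_channels, embed_dim)."""
    n, c = ds.n_segments, len(ds.channels)
    f, t = ds.map_shape
    flat = ds.X.reshape(-1, f, t)
    feats = []
    for start in range(0, len(flat), batch):
        feats.append(model(flat[start:start + batch]).features.data)
    return np.concatenate(feats, axis=0).reshape(n, c, -1)


@dataclass
class Stage2Result:
    model: SGCM
    history: list[float]


def train_stage2(sgcm: SGCM, ttm: TTM, train_ds: CPDDataset,
                 graph: ElectrodeGraph, cfg: TrainConfig,
                 rng: np.random.Generator | int = 0,
                 features: np.ndarray | None = None) -> Stage2Result:
    """Train the graph classifier on frozen-transformer features.

    The transformer is never updated; its weights are verified bit-identical
    before and after (freeze contract).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if tuple(graph.nodes) != tuple(train_ds.channels):
        raise ValueError("graph node order must match dataset channel order")
    before = _state_hash(ttm)
    if features is None:
        features = extract_features(ttm, train_ds)
    history = _sgd_epochs(lambda fb: sgcm(fb, graph), sgcm.parameters(),
                          features, train_ds.y, cfg.stage2_epochs,
                          cfg.stage2_lr, cfg.batch_size, rng)
    if _state_hash(ttm) != before:
        raise RuntimeError("freeze contract violated: stage 2 mutated stage-1 weights")
    return Stage2Result(model=sgcm, history=history)


# --------------------------------------------------------------------------
# cross-validated experiments
# --------------------------------------------------------------------------

@dataclass
class FoldOutcome:
    fold: int
    report: MetricsReport
    stage1_channel_accuracy: dict[str, float]
    stage1_channel_f1: dict[str, float]
    test_subjects: tuple[str, ...]
    y_true: np.ndarray
    y_score: np.ndarray


@dataclass
class ExperimentResult:
    class_names: tuple[str, ...]
    folds: list[FoldOutcome]
    mean_metrics: dict[str, float]
    confusion_total: np.ndarray
    auc_mean: dict[str, float]
    stage1_channel_accuracy_mean: dict[str, float]
    stage1_channel_f1_mean: dict[str, float]
    fold_plan: FoldPlan
    seed: int

    def to_dict(self) -> dict:
        return {
            "class_names": list(self.class_names),
            "mean_metrics": self.mean_metrics,
            "confusion_total": self.confusion_total.tolist(),
            "auc_mean": self.auc_mean,
            "stage1_channel_accuracy_mean": self.stage1_channel_accuracy_mean,
            "stage1_channel_f1_mean": self.stage1_channel_f1_mean,
            "folds": [
                {"fold": fo.fold, "test_subjects": list(fo.test_subjects),
                 **fo.report.to_dict()}
                for fo in self.folds
            ],
            "fold_assignments": self.fold_plan.assignments,
            "seed": self.seed,
        }


def _mask_for(ds: CPDDataset, subjects: set[str]) -> np.ndarray:
    return np.isin(ds.subject_ids, sorted(subjects))


def _take(ds: CPDDataset, mask: np.ndarray) -> CPDDataset:
    return replace(ds, X=ds.X[mask], y=ds.y[mask], subject_ids=ds.subject_ids[mask])


def run_experiment(dataset: CPDDataset, graph: ElectrodeGraph,
                   train_cfg: TrainConfig,
                   ttm_cfg: TTMConfig | None = None,
                   sgcm_cfg: SGCMConfig | None = None,
                   classes: Sequence[str] | None = None,
                   k: int = 10,
                   seed: int | None = None) -> ExperimentResult:
    """Subject-wise k-fold cross-validation of the full two-stage pipeline.

    Metrics are computed per fold and averaged over folds; the confusion
    matrix is additionally aggregated across folds.
    """
    seed = train_cfg.seed if seed is None else seed
    if classes is not None:
        dataset = subset_classes(dataset, classes)
    n_classes = len(dataset.class_names)
    ttm_cfg = ttm_cfg or TTMConfig(n_classes=n_classes)
    sgcm_cfg = sgcm_cfg or SGCMConfig(n_classes=n_classes)
    if ttm_cfg.n_classes != n_classes:
        ttm_cfg = replace(ttm_cfg, n_classes=n_classes)
    if sgcm_cfg.n_classes != n_classes:
        sgcm_cfg = replace(sgcm_cfg, n_classes=n_classes)

    plan = make_subject_folds(dataset.subject_ids, dataset.y, k=k, seed=seed)
    root = np.random.SeedSequence(seed)
    fold_seeds = root.spawn(k)

    folds: list[FoldOutcome] = []
    confusion_total = np.zeros((n_classes, n_classes), dtype=np.int64)
    for fold in range(k):
        test_subjects = plan.test_subjects(fold)
        train_subjects = plan.train_subjects(fold)
        assert not (test_subjects & train_subjects), "subject leakage across folds"
        train_ds = _take(dataset, _mask_for(dataset, train_subjects))
        test_ds = _take(dataset, _mask_for(dataset, test_subjects))
        if test_ds.n_segments == 0:
            warnings.warn(f"fold {fold} has no test segments; skipped")
            continue
        ss_init, ss_shuffle1, ss_shuffle2 = fold_seeds[fold].spawn(3)
        init_rng = np.random.default_rng(ss_init)

        ttm = TTM(ttm_cfg, dataset.map_shape, rng=init_rng)
        s1 = train_stage1(ttm, train_ds, train_cfg,
                          rng=np.random.default_rng(ss_shuffle1),
                          eval_ds=test_ds)
        features_train = extract_features(ttm, train_ds)
        sgcm = SGCM(sgcm_cfg, in_dim=ttm_cfg.embed_dim, rng=init_rng)
        train_stage2(sgcm, ttm, train_ds, graph, train_cfg,
                     rng=np.random.default_rng(ss_shuffle2),
                     features=features_train)

        features_test = extract_features(ttm, test_ds)
        logits = sgcm(features_test, graph).data
        y_pred = logits.argmax(axis=1)
        y_score = _softmax_np(logits)
        report = compute_metrics(test_ds.y, y_pred, n_classes, dataset.class_names)
        try:
            aucs = roc_auc(test_ds.y, y_score)
            report.auc = {name: (None if np.isnan(a) else float(a))
                          for name, a in zip(dataset.class_names, aucs)}
        except ValueError:
            report.auc = None
        confusion_total += report.confusion
        folds.append(FoldOutcome(fold=fold, report=report,
                                 stage1_channel_accuracy=s1.channel_accuracy,
                                 stage1_channel_f1=s1.channel_f1,
                                 test_subjects=tuple(sorted(test_subjects)),
                                 y_true=test_ds.y, y_score=y_score))

    mean_metrics = {
        key: float(np.mean([getattr(fo.report, key) for fo in folds]))
        for key in ("accuracy", "recall", "precision", "f1")
    }
    auc_mean = {}
    for name in dataset.class_names:
        vals = [fo.report.auc[name] for fo in folds
                if fo.report.auc and fo.report.auc.get(name) is not None]
        auc_mean[name] = float(np.mean(vals)) if vals else float("nan")
    ch_acc = {ch: float(np.mean([fo.stage1_channel_accuracy[ch] for fo in folds]))
              for ch in dataset.channels}
    ch_f1 = {ch: float(np.mean([fo.stage1_channel_f1[ch] for fo in folds]))
             for ch in dataset.channels}
    return ExperimentResult(class_names=dataset.class_names, folds=folds,
                            mean_metrics=mean_metrics,
                            confusion_total=confusion_total, auc_mean=auc_mean,
                            stage1_channel_accuracy_mean=ch_acc,
                            stage1_channel_f1_mean=ch_f1,
                            fold_plan=plan, seed=seed)
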