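"""Training loops, subject-wise cross-validation, metrics and benchmarks.

Training uses Adam with cross-entropy loss throughout; the two modality
branches and the fusion head take their learning rates and batch sizes
from :class:`msdafuse.io_formats.RunConfig`.  Evaluation follows the
subject-dependent protocol: stratified five-fold cross-validation within
each subject, per-subject mean/std accuracy, then an unweighted mean over
subjects.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import numpy as np
from scipy import stats as sstats
from sklearn.model_selection import StratifiedKFold
from sklearn.metrics import confusion_matrix as _sk_confusion, f1_score

from . import nn
from .nn import Tensor
from .fusion import (DecisionPair, SelfLearningFusion, concat_decisions,
                     fuse_fixed, grid_search_fixed_weight, modality_dropout)

logger = logging.getLogger("msdafuse")

__all__ = [
    "FoldResult", "SubjectResult", "train", "train_fusion",
    "cross_validate_subject", "aggregate", "paired_t_test", "confusion",
    "accuracy", "decision_benchmark", "run_pipeline",
]


@dataclasses.dataclass
class FoldResult:
    fold_index: int
    accuracy: float
    f1: float
    confusion: np.ndarray

    def __post_init__(self):
        total = int(self.confusion.sum())
        if total and abs(self.accuracy - np.trace(self.confusion) / total) > 1e-9:
            raise ValueError("accuracy inconsistent with confusion matrix")


@dataclasses.dataclass
class SubjectResult:
    subject_id: str
    folds: list[FoldResult]

    @property
    def mean_acc(self) -> float:
        return float(np.mean([f.accuracy for f in self.folds]))

    @property
    def std_acc(self) -> float:
        return float(np.std([f.accuracy for f in self.folds]))

    @property
    def fold_accuracies(self) -> np.ndarray:
        return np.array([f.accuracy for f in self.folds])


def accuracy(preds: np.ndarray, labels: np.ndarray) -> float:
    return float((np.asarray(preds) == np.asarray(labels)).mean())


def confusion(preds: np.ndarray, labels: np.ndarray, n_classes: int = 2) -> np.ndarray:
    """Confusion matrix, rows = true class, columns = predicted."""
    preds = np.asarray(preds)
    labels = np.asarray(labels)
    for name, arr in (("preds", preds), ("labels", labels)):
        if ((arr < 0) | (arr >= n_classes)).any():
            raise ValueError(f"{name} contain values outside 0..{n_classes - 1}")
    return _sk_confusion(labels, preds, labels=list(range(n_classes)))


def paired_t_test(acc_a: np.ndarray, acc_b: np.ndarray) -> tuple[float, float]:
    """Two-sided paired t-test on per-fold accuracy differences.

    Zero-variance differences leave t undefined; by convention p = 1 is
    returned (with a warning), so identical fold vectors never register as
    a significant difference.
    """
    acc_a = np.asarray(acc_a, dtype=float)
    acc_b = np.asarray(acc_b, dtype=float)
    if acc_a.shape != acc_b.shape or acc_a.ndim != 1 or len(acc_a) < 2:
        raise ValueError("need two equal-length vectors with n >= 2")
    diff = acc_a - acc_b
    if np.allclose(diff.std(ddof=1), 0.0):
        warnings.warn("zero-variance differences: paired t undefined, p set to 1")
        return float("nan"), 1.0
    t, p = sstats.ttest_rel(acc_a, acc_b)
    return float(t), float(p)


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    idx = rng.permutation(n)
    for lo in range(0, n, batch_size):
        yield idx[lo:lo + batch_size]


def train(model: nn.Module, X: np.ndarray, y: np.ndarray, *,
          lr: float = 5e-4, batch_size: int = 32, epochs: int = 10,
          seed: int = 0) -> list[float]:
    """Adam + cross-entropy training; returns the per-epoch mean loss."""
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    y = np.asarray(y)
    history: list[float] = []
    model.train()
    for epoch in range(epochs):
        losses = []
        for idx in _batches(len(y), batch_size, rng):
            opt.zero_grad()
            loss = nn.cross_entropy(model.logits(Tensor(X[idx])), y[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(
                    f"non-finite loss at epoch {epoch}: {loss.item()}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
        logger.debug("epoch %d loss %.4f", epoch, history[-1])
    return history


def train_fusion(model: SelfLearningFusion, pair: DecisionPair, *,
                 lr: float = 1e-4, batch_size: int = 32, epochs: int = 20,
                 dropout_p: float = 0.1, seed: int = 0) -> list[float]:
    """Train the self-learning fusion head with per-epoch modality dropout."""
    if pair.labels is None:
        raise ValueError("labelled decision pair required")
    rng = np.random.default_rng(seed)
    opt = nn.Adam(model.parameters(), lr=lr)
    history: list[float] = []
    model.train()
    for epoch in range(epochs):
        dropped = modality_dropout(pair, dropout_p, rng)
        X = concat_decisions(dropped)
        losses = []
        for idx in _batches(pair.n, batch_size, rng):
            opt.zero_grad()
            loss = nn.cross_entropy(model.logits(Tensor(X[idx])),
                                    pair.labels[idx])
            if not np.isfinite(loss.item()):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            loss.backward()
            opt.step()
            losses.append(loss.item())
        history.append(float(np.mean(losses)))
    return history


def predict(model: nn.Module, X: np.ndarray, batch_size: int = 256) -> np.ndarray:
    """Class predictions in evaluation mode."""
    model.eval()
    out = []
    with nn.no_grad():
        for lo in range(0, len(X), batch_size):
            probs = model(Tensor(X[lo:lo + batch_size]))
            out.append(probs.data.argmax(axis=1))
    model.train()
    return np.concatenate(out)


def cross_validate_subject(X: np.ndarray, y: np.ndarray, model_builder, *,
                           subject_id: str = "", k: int = 5, seed: int = 0,
                           train_kwargs: dict | None = None) -> SubjectResult:
    """Stratified k-fold cross-validation with a fresh model per fold."""
    y = np.asarray(y)
    counts = np.bincount(y)
    if (counts[counts > 0] < k).any():
        raise ValueError(f"need at least {k} samples of every class for "
                         f"{k}-fold stratification")
    train_kwargs = dict(train_kwargs or {})
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = []
    for fold_index, (tr, te) in enumerate(skf.split(X, y)):
        if len(np.unique(y[tr])) < len(np.unique(y)):
            raise ValueError(f"class missing from fold {fold_index} training split")
        model = model_builder(fold_index)
        train(model, X[tr], y[tr], seed=seed + fold_index, **train_kwargs)
        preds = predict(model, X[te])
        cm = confusion(preds, y[te], n_classes=len(counts))
        folds.append(FoldResult(
            fold_index=fold_index,
            accuracy=accuracy(preds, y[te]),
            f1=float(f1_score(y[te], preds, average="macro")),
            confusion=cm))
    return SubjectResult(subject_id=subject_id, folds=folds)


def aggregate(results: list[SubjectResult]) -> dict[str, float]:
    """Unweighted mean over subjects of per-subject mean/std accuracy."""
    if not results:
        raise ValueError("no subject results to aggregate")
    return {
        "mean_acc": float(np.mean([r.mean_acc for r in results])),
        "mean_std": float(np.mean([r.std_acc for r in results])),
    }


def decision_benchmark(n_train: int = 1200, n_test: int = 800,
                       complementarity: float = 0.5, seed: int = 0,
                       fusion_epochs: int = 20, dropout_p: float = 0.1
                       ) -> dict[str, float]:
    """End-to-end decision-level fusion benchmark on complementary
    synthetic decisions.

    Trains the self-learning fusion head and grid-searches the fixed
    weight on a training split, then reports held-out accuracies of: each
    single modality, fixed-weight fusion, and self-learning fusion.
    """
    from .synthetic import generate_decisions  # deferred: module cycle
    train_pair, y_tr, _ = generate_decisions(n_train, complementarity, seed=seed)
    test_pair, y_te, _ = generate_decisions(n_test, complementarity, seed=seed + 1)

    acc_eeg = accuracy(test_pair.p_eeg.argmax(axis=1), y_te)
    acc_face = accuracy(test_pair.p_face.argmax(axis=1), y_te)

    k = grid_search_fixed_weight(train_pair)
    acc_fixed = accuracy(fuse_fixed(test_pair, k).argmax(axis=1), y_te)

    model = SelfLearningFusion(n_classes=train_pair.n_classes,
                               rng=np.random.default_rng(seed))
    train_fusion(model, train_pair, epochs=fusion_epochs,
                 dropout_p=dropout_p, seed=seed)
    acc_self = accuracy(model.predict_proba(test_pair).argmax(axis=1), y_te)

    return {
        "acc_eeg": acc_eeg,
        "acc_face": acc_face,
        "acc_fixed": acc_fixed,
        "acc_self": acc_self,
        "fixed_k": k,
    }


def _predict_proba(model: nn.Module, X: np.ndarray,
                   batch_size: int = 128) -> np.ndarray:
    model.eval()
    out = []
    with nn.no_grad():
        for lo in range(0, len(X), batch_size):
            out.append(model(Tensor(X[lo:lo + batch_size])).data)
    model.train()
    return np.concatenate(out)


def run_pipeline(n_subjects: int = 2, n_trials: int = 8,
                 task_seconds: float = 6.0, k_folds: int = 2,
                 branch_epochs: int = 4, fusion_epochs: int = 10,
                 pairing: str = "final", seed: int = 0,
                 out_dir=None) -> dict:
    """End-to-end multimodal run on synthetic EEG + face data.

    Per subject: generate recordings, extract DE tensors, train the EEG
    and face branches with stratified ``k_folds``-fold cross-validation,
    collect out-of-fold probability pairs (each EEG sample paired with a
    face frame of its trial: the frame at its final step by default),
    train the self-learning fusion on half of those decisions and evaluate
    on the other half.  Writes results.csv, confusion CSVs and a run log
    when ``out_dir`` is given.  Scale parameters default to a smoke-test
    size that completes in minutes on one CPU.
    """
    from . import eeg_features as ef
    from . import synthetic as syn
    from .eeg_net import EEGNet, EEGNetConfig
    from .face_net import MSDAC, MSDACConfig
    from .io_formats import default_layout_path, load_layout

    if pairing not in ("final", "center"):
        raise ValueError("pairing must be 'final' or 'center'")
    layout = load_layout(default_layout_path())
    proto = syn.ProtocolSpec(n_subjects=n_subjects, n_trials=n_trials,
                             task_seconds=task_seconds)
    face_cfg = MSDACConfig(stem_channels=(4, 8), branch_channels=8,
                           final_channels=8, fc_hidden=16, input_size=48)
    subject_rows, all_pairs, all_pair_labels = [], [], []
    per_subject: list[dict] = []
    for s in range(n_subjects):
        sid = f"s{s:02d}"
        rs = syn.generate_eeg(proto, seed=seed + 101 * s, subject_id=sid)
        images, frame_labels, trial_idx = syn.generate_faces(
            proto, seed=seed + 101 * s + 1, labels=rs.labels)
        eeg_X, eeg_y, face_X = [], [], []
        fpt = proto.frames_per_trial
        for t, trial in enumerate(rs.trials):
            samples = ef.extract_samples(trial, layout, label=int(rs.labels[t]))
            frames_t = images[trial_idx == t]
            for smp in samples:
                eeg_X.append(smp.tensor)
                eeg_y.append(smp.label)
                idx = (smp.step_span[1] if pairing == "final"
                       else (smp.step_span[0] + smp.step_span[1]) // 2)
                face_X.append(frames_t[min(idx, fpt - 1)])
        eeg_X = np.stack(eeg_X)
        eeg_y = np.array(eeg_y)
        face_X = np.stack(face_X)[:, None, :, :]

        rng_models = np.random.default_rng(seed + 7 * s)
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True,
                              random_state=seed + s)
        eeg_folds, face_folds = [], []
        p_eeg = np.zeros((len(eeg_y), 2))
        p_face = np.zeros((len(eeg_y), 2))
        for fold, (tr, te) in enumerate(skf.split(eeg_X, eeg_y)):
            eeg_model = EEGNet(EEGNetConfig(),
                               rng=np.random.default_rng(rng_models.integers(2**31)))
            train(eeg_model, eeg_X[tr], eeg_y[tr], lr=5e-4, batch_size=32,
                  epochs=branch_epochs, seed=seed + fold)
            face_model = MSDAC(face_cfg,
                               rng=np.random.default_rng(rng_models.integers(2**31)))
            train(face_model, face_X[tr], eeg_y[tr], lr=5e-4, batch_size=32,
                  epochs=branch_epochs, seed=seed + fold)
            p_eeg[te] = _predict_proba(eeg_model, eeg_X[te])
            p_face[te] = _predict_proba(face_model, face_X[te])
            for name, probs, store in (("eeg", p_eeg, eeg_folds),
                                       ("face", p_face, face_folds)):
                preds = probs[te].argmax(axis=1)
                store.append(FoldResult(
                    fold_index=fold, accuracy=accuracy(preds, eeg_y[te]),
                    f1=float(f1_score(eeg_y[te], preds, average="macro")),
                    confusion=confusion(preds, eeg_y[te])))
        pair = DecisionPair(p_eeg=p_eeg, p_face=p_face, labels=eeg_y)
        all_pairs.append(pair)
        all_pair_labels.append(eeg_y)
        eeg_res = SubjectResult(sid, eeg_folds)
        face_res = SubjectResult(sid, face_folds)
        per_subject.append({"subject": sid, "eeg": eeg_res, "face": face_res})
        subject_rows += [
            {"subject": sid, "method": "eeg", "mean_acc": eeg_res.mean_acc,
             "std_acc": eeg_res.std_acc},
            {"subject": sid, "method": "face", "mean_acc": face_res.mean_acc,
             "std_acc": face_res.std_acc},
        ]

    # fusion over pooled out-of-fold decisions: train half, test half
    p_eeg = np.concatenate([p.p_eeg for p in all_pairs])
    p_face = np.concatenate([p.p_face for p in all_pairs])
    labels = np.concatenate(all_pair_labels)
    rng = np.random.default_rng(seed + 13)
    order = rng.permutation(len(labels))
    half = len(labels) // 2
    tr, te = order[:half], order[half:]
    train_pair = DecisionPair(p_eeg[tr], p_face[tr], labels[tr])
    test_pair = DecisionPair(p_eeg[te], p_face[te], labels[te])
    fus = SelfLearningFusion(rng=np.random.default_rng(seed + 17))
    train_fusion(fus, train_pair, epochs=fusion_epochs, seed=seed)
    fused = fus.predict_proba(test_pair)
    preds = fused.argmax(axis=1)
    fusion_cm = confusion(preds, labels[te])
    result = {
        "per_subject": per_subject,
        "aggregate_eeg": aggregate([d["eeg"] for d in per_subject]),
        "aggregate_face": aggregate([d["face"] for d in per_subject]),
        "fusion_accuracy": accuracy(preds, labels[te]),
        "fusion_confusion": fusion_cm,
        "results_rows": subject_rows,
    }
    if out_dir is not None:
        import pandas as pd
        from pathlib import Path
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(subject_rows).to_csv(out / "results.csv", index=False)
        np.savetxt(out / "fusion_confusion.csv", fusion_cm,
                   fmt="%d", delimiter=",")
        for d in per_subject:
            for mod in ("eeg", "face"):
                cm = sum(f.confusion for f in d[mod].folds)
                np.savetxt(out / f"confusion_{d['subject']}_{mod}.csv", cm,
                           fmt="%d", delimiter=",")
        logger.info("pipeline artifacts written to %s", out)
    return result
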