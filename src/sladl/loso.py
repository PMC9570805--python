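"""Leave-one-subject-out (LOSO) training protocol.

To test generalization to unseen people, each participant in turn serves as
the validation set while the network trains on everyone else.  One
"iteration" is a full pass over the training sequences (all sequences form
one padded batch, so an iteration is one optimizer step) followed by a
per-sample accuracy evaluation on the held-out participant.  Early stopping
leaves the monitor inert for an initial grace period of 15 iterations and
then stops once the running-best validation accuracy has failed to improve
for 2 consecutive iterations.  Because random weight initialization makes
runs on identical data differ, the whole training is repeated (5 times by
default, each repeat with its own derived seed) and the repeat with the
highest validation accuracy is kept.  The model returned from a repeat is
the parameter snapshot from its best-validation iteration, not the last.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np

from .cohort import Dataset
from .model import Adam, ModelConfig, SequenceClassifier
from .preprocessing import FeatureSequence, SensorCombination, assemble_features

log = logging.getLogger(__name__)


@dataclass
class TrainingConfig:
    grace_iters: int = 15      # early stopping inert through this iteration
    patience: int = 2          # consecutive non-improving iterations to stop
    repeats: int = 5           # training repeats per fold, best one kept
    max_iters: int = 200       # hard cap on iterations
    learning_rate: float = 1e-3
    clip_norm: float = 1.0
    gru_units: int = 100
    bilstm_units: int = 200
    base_seed: int = 0
    dtype: str = "float32"

    def validate(self) -> None:
        if self.grace_iters < 0 or self.patience < 1 or self.repeats < 1:
            raise ValueError("grace_iters >= 0, patience >= 1, repeats >= 1")
        if self.max_iters <= self.grace_iters + self.patience:
            raise ValueError("max_iters must exceed grace_iters + patience")

    def repeat_seed(self, fold_index: int, repeat: int) -> int:
        """Deterministic, distinct seed per (fold, repeat)."""
        return int(self.base_seed + 1000 * fold_index + repeat)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class FoldResult:
    """Outcome of one LOSO fold after best-of-repeats selection."""

    val_participant_id: str
    train_participant_ids: tuple
    best_repeat_index: int
    val_accuracy: float
    y_true: np.ndarray
    y_pred: np.ndarray
    stopped_at_iter: int
    repeat_accuracies: tuple = ()
    repeat_seeds: tuple = ()

    def __post_init__(self):
        if len(self.y_true) != len(self.y_pred):
            raise ValueError("y_true and y_pred lengths differ")
        if self.val_participant_id in self.train_participant_ids:
            raise ValueError("validation participant leaked into training set")


@dataclass
class LosoResult:
    """All folds of one sensor combination."""

    combination: SensorCombination
    folds: list = field(default_factory=list)

    def fold_for(self, participant_id: str) -> FoldResult:
        for f in self.folds:
            if f.val_participant_id == participant_id:
                return f
        raise KeyError(participant_id)


# ---------------------------------------------------------------------------
# protocol pieces
# ---------------------------------------------------------------------------

def loso_folds(dataset: Dataset) -> list:
    """(train_ids, val_id) per fold; every participant validates once."""
    ids = dataset.participant_ids
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 participants")
    return [(tuple(i for i in ids if i != val), val) for val in ids]


def early_stop_decision(val_acc_trace, cfg: TrainingConfig) -> bool:
    """True if training should stop after the last recorded iteration.

    Improvement means a new running best (strictly greater).  Iterations up
    to and including ``grace_iters`` never count toward the patience streak,
    so the earliest possible stop is iteration ``grace_iters + patience``.
    """
    if len(val_acc_trace) == 0:
        raise ValueError("empty validation-accuracy trace")
    best = -np.inf
    streak = 0
    for it, acc in enumerate(val_acc_trace, start=1):
        if acc > best:
            best = acc
            streak = 0
        elif it > cfg.grace_iters:
            streak += 1
            if streak >= cfg.patience:
                return True
    return False


def pad_batch(feats: list):
    """Stack variable-length feature sequences into a padded batch."""
    lengths = np.array([f.T for f in feats])
    Tmax = int(lengths.max())
    D = feats[0].D
    X = np.zeros((len(feats), Tmax, D), dtype=np.float32)
    Y = np.zeros((len(feats), Tmax), dtype=np.int64)
    for b, f in enumerate(feats):
        X[b, :f.T] = f.X
        Y[b, :f.T] = f.y
    return X, Y, lengths


def train_fold(train_feats: list, val_feat: FeatureSequence,
               cfg: TrainingConfig, repeat_seed: int):
    """Train once on one fold; returns (model, val_acc_trace, stopped_at).

    The returned model carries the parameters of the best-validation
    iteration (earliest iteration on ties).
    """
    cfg.validate()
    if not train_feats:
        raise ValueError("empty training set")
    if any(f.D != val_feat.D for f in train_feats):
        raise ValueError("train/validation channel dimensions differ")
    X, Y, lengths = pad_batch(train_feats)
    model = SequenceClassifier(ModelConfig(
        input_dim=val_feat.D, gru_units=cfg.gru_units,
        bilstm_units=cfg.bilstm_units, seed=repeat_seed, dtype=cfg.dtype))
    opt = Adam(model.params, lr=cfg.learning_rate, clip_norm=cfg.clip_norm)
    trace = []
    best_acc, best_params = -np.inf, model.copy_params()
    stopped_at = 0
    for it in range(1, cfg.max_iters + 1):
        loss, grads, _ = model.loss_and_grads(X, Y, lengths)
        opt.step(model.params, grads)
        acc = float(np.mean(model.predict(val_feat.X) == val_feat.y))
        trace.append(acc)
        log.debug("iter %d loss %.4f val acc %.4f", it, loss, acc)
        if acc > best_acc:
            best_acc, best_params = acc, model.copy_params()
        stopped_at = it
        if early_stop_decision(trace, cfg):
            break
    model.set_params(best_params)
    return model, trace, stopped_at


def _default_trainer(train_feats, val_feat, cfg, seed):
    return train_fold(train_feats, val_feat, cfg, seed)


def train_repeats(train_feats: list, val_feat: FeatureSequence,
                  cfg: TrainingConfig, fold_index: int = 0,
                  trainer=None) -> FoldResult:
    """Run the per-fold repeats and keep the best validation network.

    ``trainer`` (signature ``(train_feats, val_feat, cfg, seed) ->
    (model, trace, stopped_at)``) is injectable for testing.
    """
    cfg.validate()
    trainer = trainer or _default_trainer
    runs = []
    seeds = []
    for r in range(cfg.repeats):
        seed = cfg.repeat_seed(fold_index, r)
        seeds.append(seed)
        model, trace, stopped_at = trainer(train_feats, val_feat, cfg, seed)
        y_pred = np.asarray(model.predict(val_feat.X))
        acc = float(np.mean(y_pred == val_feat.y))
        runs.append((acc, y_pred, stopped_at))
        log.info("fold %d repeat %d: val acc %.4f (stopped at iter %d)",
                 fold_index, r, acc, stopped_at)
    accs = [a for a, _, _ in runs]
    best = int(np.argmax(accs))  # ties resolve to the lowest repeat index
    acc, y_pred, stopped_at = runs[best]
    return FoldResult(
        val_participant_id=val_feat.participant_id,
        train_participant_ids=tuple(f.participant_id for f in train_feats),
        best_repeat_index=best,
        val_accuracy=acc,
        y_true=val_feat.y.copy(),
        y_pred=y_pred,
        stopped_at_iter=stopped_at,
        repeat_accuracies=tuple(accs),
        repeat_seeds=tuple(seeds),
    )


def run_combination(dataset: Dataset, combination: SensorCombination,
                    cfg: TrainingConfig, trainer=None,
                    fold_callback=None) -> LosoResult:
    """Full LOSO over a cohort for one sensor combination."""
    feats = {p.participant_id: assemble_features(rec, tr, combination,
                                                 p.participant_id)
             for p, rec, tr in dataset.participants}
    result = LosoResult(combination=combination)
    for k, (train_ids, val_id) in enumerate(loso_folds(dataset)):
        log.info("combination %s fold %d/%d (validation %s)",
                 combination.name, k + 1, len(dataset), val_id)
        fold = train_repeats([feats[i] for i in train_ids], feats[val_id],
                             cfg, fold_index=k, trainer=trainer)
        result.folds.append(fold)
        if fold_callback is not None:
            fold_callback(fold)
    return result
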