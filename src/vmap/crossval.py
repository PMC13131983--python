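"""Patient-grouped cross-validation and the training loop.

Folds are random balanced partitions at the patient level, so no
patient's maps ever straddle the train and test sides of a fold.  Each
fold trains its own network; every map is predicted exactly once, by the
fold that held its patient out, and the pooled predictions feed the
evaluation statistics.  Per-fold 1-year c-statistics are reported as
mean +/- SD alongside the pooled values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import evalstats
from .errors import ConfigurationError, TrainingError
from .labeling import BinScheme, Category, build_label_table
from .losses import LossConfig, total_loss_and_grads
from .network import Adam, ArchConfig, ConvMixerNet, ModelOutput, build_model, preprocess, random_flip
from .synthmap.cohort import Dataset


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 40
    batch_size: int = 32
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    patience: int = 10
    val_fraction: float = 0.1
    grad_clip: float = 5.0
    augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if min(self.epochs, self.batch_size, self.patience) < 1 or self.learning_rate <= 0:
            raise ConfigurationError("training parameters must be positive")
        if self.optimizer != "adam":
            raise ConfigurationError("only the adam optimizer is implemented")


@dataclass
class FoldAssignment:
    """Patient -> test-fold id (0..k-1)."""

    fold_of: dict
    k: int

    def test_patients(self, fold: int) -> set:
        return {p for p, f in self.fold_of.items() if f == fold}

    def train_patients(self, fold: int) -> set:
        return {p for p, f in self.fold_of.items() if f != fold}


def make_folds(patient_ids, k: int = 5, seed: int = 0) -> FoldAssignment:
    """Random balanced patient-level partition; deterministic in seed."""
    patients = sorted(set(patient_ids))
    if len(patients) < k:
        raise ConfigurationError(f"need at least {k} patients for {k} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(patients))
    fold_of = {}
    for pos, idx in enumerate(order):
        fold_of[patients[idx]] = pos % k
    return FoldAssignment(fold_of=fold_of, k=k)


def _label_arrays(label_df: pd.DataFrame, prefix: str) -> tuple:
    return (
        label_df[f"{prefix}_status"].to_numpy(dtype=np.int64),
        label_df[f"{prefix}_bin"].to_numpy(dtype=np.int64),
    )


def train_fold(
    stacks: np.ndarray,
    labels_pvi: tuple,
    labels_bepvi: tuple,
    arch: ArchConfig,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> tuple:
    """Train one network; returns (model, per-epoch history DataFrame).

    Augmentation (joint left-right flips) applies to training batches
    only; the early-stopping validation split is evaluated unaugmented in
    inference mode, and the best-validation weights are restored.
    """
    loss_cfg = loss_cfg or LossConfig()
    cfg = train_cfg or TrainConfig()
    n = len(stacks)
    rng = np.random.default_rng(cfg.seed)
    model = build_model(arch, seed=int(rng.integers(2**31 - 1)))
    opt = Adam(model, lr=cfg.learning_rate)

    idx = rng.permutation(n)
    n_val = int(round(cfg.val_fraction * n))
    val_idx, tr_idx = idx[:n_val], idx[n_val:]
    if len(tr_idx) == 0:
        raise ConfigurationError("training split is empty")

    def eval_loss(indices) -> float:
        if len(indices) == 0:
            return np.nan
        total, count = 0.0, 0
        for start in range(0, len(indices), cfg.batch_size):
            sel = indices[start : start + cfg.batch_size]
            z_p, z_b = model.forward_logits(stacks[sel], train=False)
            lp = (labels_pvi[0][sel], labels_pvi[1][sel])
            lb = (labels_bepvi[0][sel], labels_bepvi[1][sel])
            loss, _, _ = total_loss_and_grads(z_p, z_b, lp, lb, loss_cfg)
            total += loss * len(sel)
            count += len(sel)
        return total / count

    history = []
    best_val, best_state, patience_left = np.inf, None, cfg.patience
    for epoch in range(cfg.epochs):
        order = rng.permutation(tr_idx)
        epoch_loss, seen = 0.0, 0
        for start in range(0, len(order), cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            batch = stacks[sel]
            if cfg.augment:
                batch = np.stack([random_flip(s, rng) for s in batch])
            z_p, z_b = model.forward_logits(batch, train=True)
            lp = (labels_pvi[0][sel], labels_pvi[1][sel])
            lb = (labels_bepvi[0][sel], labels_bepvi[1][sel])
            loss, dz_p, dz_b = total_loss_and_grads(z_p, z_b, lp, lb, loss_cfg)
            if not np.isfinite(loss):
                raise TrainingError(f"non-finite loss at epoch {epoch}")
            model.zero_grad()
            model.backward_from_logits(dz_p.astype(np.float32), dz_b.astype(np.float32))
            if cfg.grad_clip > 0:
                norm = np.sqrt(sum(float(np.sum(g * g)) for _, g in model.param_pairs()))
                if norm > cfg.grad_clip:
                    scale = cfg.grad_clip / norm
                    for _, g in model.param_pairs():
                        g *= scale
            opt.step()
            epoch_loss += loss * len(sel)
            seen += len(sel)
        val_loss = eval_loss(val_idx)
        history.append(
            {"epoch": epoch, "train_loss": epoch_loss / seen, "val_loss": val_loss}
        )
        monitored = val_loss if np.isfinite(val_loss) else epoch_loss / seen
        if monitored < best_val - 1e-6:
            best_val = monitored
            best_state = [(p.copy()) for p, _ in model.param_pairs()]
            best_bn = [
                (bn.running_mean.copy(), bn.running_var.copy())
                for bn in model._layers()
                if hasattr(bn, "running_mean")
            ]
            patience_left = cfg.patience
        else:
            patience_left -= 1
            if patience_left <= 0:
                break
    if best_state is not None:
        for (p, _), saved in zip(model.param_pairs(), best_state):
            p[...] = saved
        bns = [bn for bn in model._layers() if hasattr(bn, "running_mean")]
        for bn, (m, v) in zip(bns, best_bn):
            bn.running_mean, bn.running_var = m, v
    return model, pd.DataFrame(history)


def predict(model: ConvMixerNet, stacks: np.ndarray, batch_size: int = 64) -> ModelOutput:
    outs_p, outs_b = [], []
    for start in range(0, len(stacks), batch_size):
        out = model.forward(stacks[start : start + batch_size])
        outs_p.append(out.pvi)
        outs_b.append(out.bepvi)
    return ModelOutput(pvi=np.concatenate(outs_p), bepvi=np.concatenate(outs_b))


@dataclass
class CrossvalResult:
    pooled: pd.DataFrame  # labels, fold, per-task probabilities and scores
    eval_result: evalstats.EvalResult
    folds: FoldAssignment
    histories: list = field(default_factory=list)
    models: list = field(default_factory=list)  # one trained network per fold


def run_crossval(
    dataset: Dataset,
    scheme: BinScheme | None = None,
    arch: ArchConfig | None = None,
    loss_cfg: LossConfig | None = None,
    train_cfg: TrainConfig | None = None,
    k: int = 5,
    seed: int = 0,
) -> CrossvalResult:
    """Patient-grouped k-fold training with pooled-prediction evaluation."""
    scheme = scheme or BinScheme.equal()
    side = dataset.samples[0].images.shape[1]
    arch = arch or ArchConfig(side=side, n_bins=scheme.n_bins)
    loss_cfg = loss_cfg or LossConfig()
    train_cfg = train_cfg or TrainConfig()

    labels = build_label_table(dataset, scheme)
    stacks = np.stack([preprocess(s.images) for s in dataset.samples])
    patient_ids = labels["patient_id"].to_numpy()
    folds = make_folds(patient_ids, k=k, seed=seed)

    n = len(dataset.samples)
    probs_pvi = np.full((n, arch.n_outputs), np.nan)
    probs_bep = np.full((n, arch.n_outputs), np.nan)
    fold_col = np.full(n, -1, dtype=int)
    called = {"PVI": np.zeros(n, dtype=bool), "bePVI": np.zeros(n, dtype=bool)}
    thresholds: dict = {}
    histories = []
    models = []
    for fold in range(k):
        test_mask = np.isin(patient_ids, sorted(folds.test_patients(fold)))
        train_mask = ~test_mask
        assert not (set(patient_ids[train_mask]) & set(patient_ids[test_mask]))
        fold_cfg = TrainConfig(
            **{
                **train_cfg.__dict__,
                "seed": (train_cfg.seed + 1000 * (fold + 1)) % (2**31 - 1),
            }
        )
        model, hist = train_fold(
            stacks[train_mask],
            _label_arrays(labels[train_mask], "pvi"),
            _label_arrays(labels[train_mask], "bepvi"),
            arch,
            loss_cfg,
            fold_cfg,
        )
        out = predict(model, stacks[test_mask])
        probs_pvi[test_mask] = out.pvi
        probs_bep[test_mask] = out.bepvi
        fold_col[test_mask] = fold
        histories.append(hist)
        models.append(model)

        # Youden threshold from this fold's TRAINING maps, applied to its
        # held-out maps: the binary Complete/Incomplete call
        out_tr = predict(model, stacks[train_mask])
        for task, probs_tr, probs_te, prefix in (
            ("PVI", out_tr.pvi, out.pvi, "pvi"),
            ("bePVI", out_tr.bepvi, out.bepvi, "bepvi"),
        ):
            st_tr, bn_tr = _label_arrays(labels[train_mask], prefix)
            sc_tr = evalstats.risk_score(probs_tr, scheme.n_bins, "prognosis")
            try:
                theta = evalstats.dichotomize(sc_tr, st_tr, bn_tr, scheme.n_bins)
            except evalstats.ThresholdError:
                theta = np.inf  # degenerate training fold: call nothing Incomplete
            thresholds.setdefault(task, []).append(theta)
            sc_te = evalstats.risk_score(probs_te, scheme.n_bins, "prognosis")
            called[task][test_mask] = sc_te > theta

    pooled = labels.copy()
    pooled["fold"] = fold_col
    pooled["pvi_incomplete"] = called["PVI"]
    pooled["bepvi_incomplete"] = called["bePVI"]
    K = scheme.n_bins
    for task, probs, prefix in (("PVI", probs_pvi, "pvi"), ("bePVI", probs_bep, "bepvi")):
        pooled[f"{prefix}_score"] = evalstats.risk_score(probs, K, "prognosis")
        pooled[f"{prefix}_score_practice"] = evalstats.risk_score(probs, K, "practice")
        for j in range(arch.n_outputs):
            pooled[f"{prefix}_p{j}"] = probs[:, j]

    result = evalstats.EvalResult()
    per_fold_rows = []
    for task, prefix in (("PVI", "pvi"), ("bePVI", "bepvi")):
        status = pooled[f"{prefix}_status"].to_numpy()
        bins = pooled[f"{prefix}_bin"].to_numpy()
        scores = pooled[f"{prefix}_score"].to_numpy()
        result.auc_by_bin[task] = evalstats.auc_curve(scores, status, bins, K)
        result.c_stat[task] = evalstats.time_dependent_auc(scores, status, bins, K)
        post = status != 1  # post-intervention maps only
        try:
            result.c_stat_post_only[task] = evalstats.time_dependent_auc(
                scores[post], status[post], bins[post], K
            )
        except evalstats.UndefinedMetricError:
            result.c_stat_post_only[task] = None
        for fold in range(k):
            sel = fold_col == fold
            try:
                auc = evalstats.time_dependent_auc(scores[sel], status[sel], bins[sel], K)
            except evalstats.UndefinedMetricError:
                auc = np.nan
            per_fold_rows.append({"task": task, "fold": fold, "c_stat": auc})
    result.per_fold = pd.DataFrame(per_fold_rows)
    result.extras["thresholds"] = thresholds
    return CrossvalResult(
        pooled=pooled, eval_result=result, folds=folds, histories=histories, models=models
    )
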