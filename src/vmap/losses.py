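"""DeepHit-style censored likelihood and ranking losses.

Per task the model emits a probability vector
``p = (p_pre, p_1, ..., p_K, p_free)``.  The likelihood loss is the
negative log of the probability mass consistent with the label:

* Category 1 (pre-intervention):    -log p_pre
* Category 2 (event in bin k):      -log p_k
* Category 3 (event-free):          -log p_free
* censored after c survived bins:   -log (sum_{k>c} p_k + p_free)

so a map censored at c = 0 still teaches "not pre-intervention"
(-log(1 - p_pre)).  The ranking loss penalizes discordant pairs: for
every event i in bin k_i and every j known event-free through k_i, it
adds exp(-(F_i(k_i) - F_j(k_i)) / sigma) with F the task's cumulative
incidence, averaged over valid pairs.  Pre-intervention maps take part
in neither role.

Gradients with respect to the head logits are computed in closed form
(`total_loss_and_grads`) for the numpy training loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InputError
from .labeling import Category, TaskLabel
from .network import ModelOutput, softmax, softmax_vjp

EPS_LOG = 1e-8

_STATUS_CODE = {
    Category.CENSORED: 0,
    Category.PRE: 1,
    Category.EVENT: 2,
    Category.EVENT_FREE: 3,
}


@dataclass(frozen=True)
class LossConfig:
    """Ranking sharpness sigma, ranking weight alpha, per-task weights."""

    sigma: float = 0.1
    alpha: float = 1.0
    w_pvi: float = 1.0
    w_bepvi: float = 1.0

    def __post_init__(self):
        if self.sigma <= 0:
            raise ConfigurationError("sigma must be positive")
        if self.alpha < 0 or self.w_pvi < 0 or self.w_bepvi < 0:
            raise ConfigurationError("loss weights must be non-negative")


def labels_to_arrays(labels) -> tuple:
    """(status, bin) int arrays for a sequence of TaskLabels.

    status follows Category codes (0 censored, 1 pre, 2 event, 3 free);
    bin holds the event bin for events, the censor bin for censored maps
    and 0 otherwise.
    """
    status = np.array([_STATUS_CODE[lab.status] for lab in labels], dtype=np.int64)
    bins = np.array(
        [
            lab.event_bin if lab.status is Category.EVENT
            else (lab.censor_bin if lab.status is Category.CENSORED else 0)
            for lab in labels
        ],
        dtype=np.int64,
    )
    return status, bins


def _label_mass(probs: np.ndarray, status: np.ndarray, bins: np.ndarray) -> np.ndarray:
    """Probability mass consistent with each label, shape (B,)."""
    B, width = probs.shape
    K = width - 2
    if np.any((status == 2) & ((bins < 1) | (bins > K))):
        raise InputError("event bin out of range for this output width")
    mass = np.empty(B)
    pre = status == 1
    mass[pre] = probs[pre, 0]
    ev = status == 2
    mass[ev] = probs[ev, bins[ev]]
    free = status == 3
    mass[free] = probs[free, -1]
    cen = status == 0
    if np.any(cen):
        # surviving mass strictly beyond the censor bin, plus event-free
        tail = np.cumsum(probs[:, ::-1], axis=1)[:, ::-1]  # tail[:, j] = sum_{i>=j} p_i
        mass[cen] = tail[cen, bins[cen] + 1]
    return mass


def likelihood_loss(probs, label: TaskLabel) -> float:
    """Censored negative log-likelihood of a single output vector."""
    probs = np.asarray(probs, dtype=float).reshape(1, -1)
    status, bins = labels_to_arrays([label])
    mass = _label_mass(probs, status, bins)
    return float(-np.log(np.maximum(mass, EPS_LOG))[0])


def _likelihood_batch(probs, status, bins) -> np.ndarray:
    return -np.log(np.maximum(_label_mass(probs, status, bins), EPS_LOG))


def _ranking_pairs(status: np.ndarray, bins: np.ndarray):
    """Yield (i, j, k_i) for every valid ordered pair of one task."""
    events = np.where(status == 2)[0]
    for i in events:
        k = bins[i]
        eligible = (
            (status == 3)
            | ((status == 2) & (bins > k))
            | ((status == 0) & (bins >= k))
        )
        eligible[i] = False
        for j in np.where(eligible)[0]:
            yield i, j, k


def ranking_loss(probs: np.ndarray, labels, cfg: LossConfig) -> float:
    """Mean pairwise concordance penalty for one task's batch."""
    probs = np.asarray(probs, dtype=float)
    status, bins = labels if isinstance(labels, tuple) else labels_to_arrays(labels)
    F = np.cumsum(probs[:, 1:-1], axis=1)
    total = 0.0
    n_pairs = 0
    for i, j, k in _ranking_pairs(status, bins):
        total += np.exp(-(F[i, k - 1] - F[j, k - 1]) / cfg.sigma)
        n_pairs += 1
    return total / n_pairs if n_pairs else 0.0


def total_loss(outputs: ModelOutput, labels_pvi, labels_bepvi, cfg: LossConfig | None = None) -> float:
    """Weighted two-task objective: mean likelihood + alpha * ranking."""
    cfg = cfg or LossConfig()
    value = 0.0
    for probs, labels, w in (
        (outputs.pvi, labels_pvi, cfg.w_pvi),
        (outputs.bepvi, labels_bepvi, cfg.w_bepvi),
    ):
        if w == 0.0:
            continue
        status, bins = labels if isinstance(labels, tuple) else labels_to_arrays(labels)
        lik = _likelihood_batch(np.asarray(probs, dtype=float), status, bins).mean()
        value += w * (lik + cfg.alpha * ranking_loss(probs, (status, bins), cfg))
    return float(value)


# ----------------------------------------------------------------------
# closed-form gradients for training


def _task_loss_and_grad(logits: np.ndarray, status: np.ndarray, bins: np.ndarray,
                        cfg: LossConfig) -> tuple:
    """(loss, dloss/dlogits) for one task over a batch of logits."""
    probs = softmax(logits)
    B, width = probs.shape
    mass = _label_mass(probs, status, bins)
    mass_f = np.maximum(mass, EPS_LOG)
    lik = -np.log(mass_f)

    # d(-log mass)/dp = -S / mass with S the label's selection mask
    S = np.zeros_like(probs)
    pre, ev, free, cen = status == 1, status == 2, status == 3, status == 0
    S[pre, 0] = 1.0
    S[ev, bins[ev]] = 1.0
    S[free, -1] = 1.0
    for i in np.where(cen)[0]:
        S[i, bins[i] + 1 :] = 1.0
    d_probs = -(S / mass_f[:, None]) / B  # gradient of the batch MEAN

    # ranking term on the cumulative incidence F(m) = sum_{k<=m} p_k
    F = np.cumsum(probs[:, 1:-1], axis=1)
    pairs = list(_ranking_pairs(status, bins))
    rank = 0.0
    if pairs and cfg.alpha > 0.0:
        dF = np.zeros_like(F)
        n_pairs = len(pairs)
        for i, j, k in pairs:
            w = np.exp(-(F[i, k - 1] - F[j, k - 1]) / cfg.sigma)
            rank += w
            coef = cfg.alpha * w / (cfg.sigma * n_pairs)
            dF[i, k - 1] -= coef
            dF[j, k - 1] += coef
        rank /= n_pairs
        # F_m depends on p_1..p_m: accumulate reversed cumulative sums
        d_probs[:, 1:-1] += np.cumsum(dF[:, ::-1], axis=1)[:, ::-1]
    elif pairs:
        for i, j, k in pairs:
            rank += np.exp(-(F[i, k - 1] - F[j, k - 1]) / cfg.sigma)
        rank /= len(pairs)

    loss = lik.mean() + cfg.alpha * rank
    return loss, softmax_vjp(probs, d_probs)


def total_loss_and_grads(logits_pvi, logits_bep, labels_pvi, labels_bepvi,
                         cfg: LossConfig | None = None) -> tuple:
    """Total loss and its gradients w.r.t. both heads' logits."""
    cfg = cfg or LossConfig()
    st_p, bn_p = labels_pvi if isinstance(labels_pvi, tuple) else labels_to_arrays(labels_pvi)
    st_b, bn_b = (
        labels_bepvi if isinstance(labels_bepvi, tuple) else labels_to_arrays(labels_bepvi)
    )
    loss_p, dz_p = _task_loss_and_grad(np.asarray(logits_pvi, dtype=float), st_p, bn_p, cfg)
    loss_b, dz_b = _task_loss_and_grad(np.asarray(logits_bep, dtype=float), st_b, bn_b, cfg)
    total = cfg.w_pvi * loss_p + cfg.w_bepvi * loss_b
    return total, cfg.w_pvi * dz_p, cfg.w_bepvi * dz_b
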