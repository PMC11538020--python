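"""Training objectives and loops for the embedding models.

The main objective is *1vsAll with cross-entropy*: every training triple
(s, p, o) contributes the cross-entropy of the true object under a softmax
over the scores of all candidate objects of (s, p, _), plus the symmetric
term for the subject slot.  This is a pseudo-likelihood style objective and
is the regime that separates well-trained factorization models from
margin-ranking baselines.  Negative-sampling alternatives (binary
cross-entropy and margin ranking) are provided for the comparison and as
the cheaper fallback regime for the models where scoring the full
vocabulary per triple is expensive at scale (RotatE, TransH).

The optimizer is Adam with a fixed default rate of 1e-3; softmax terms are
stabilized by max-subtraction.  Training is deterministic given the config
seed and single-threaded execution.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np

from kgelp.data import SplitKG
from kgelp.evaluation import FilterIndex, evaluate
from kgelp.models import EmbeddingModel, ModelConfig, init_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "TrainHistory",
    "HPOResult",
    "one_vs_all_loss",
    "sample_negatives",
    "margin_loss",
    "train",
    "hpo",
]

OBJECTIVES = ("1vsAll-CE", "negsamp-CE", "negsamp-margin")


@dataclass
class TrainConfig:
    objective: str = "1vsAll-CE"
    optimizer: str = "adam"  # adam | adagrad
    negatives: int = 10  # k negatives per positive (negsamp objectives)
    corrupt: str = "both"  # corrupt-subject | corrupt-object | both
    filter_negatives: bool = False
    margin: float = 1.0
    lr: float = 1e-3
    lr_schedule: str = "constant"  # constant | cosine (anneals to lr/100)
    batch_size: int = 512
    max_epochs: int = 50
    reg: float = 0.0
    reg_type: str = "l2"  # l2 | n3
    eval_every: int = 2  # validation cadence in epochs
    patience: int = 5  # evaluations without validation-MRR gain
    valid_sample: int = 500  # validation triples used per evaluation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"objective must be one of {OBJECTIVES}")
        if self.objective != "1vsAll-CE" and self.negatives < 1:
            raise ValueError("negatives must be >= 1 for sampling objectives")
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.objective == "negsamp-margin" and self.margin <= 0:
            raise ValueError("margin must be positive")


@dataclass
class TrainHistory:
    train_loss: list[float] = field(default_factory=list)
    eval_epochs: list[int] = field(default_factory=list)
    valid_mrr: list[float] = field(default_factory=list)
    best_epoch: int = 0
    best_mrr: float = -np.inf
    stopped: str = "max_epochs"

    def to_dict(self) -> dict:
        return asdict(self)


class Adam:
    """Adam with per-parameter moments; complex tables update via their
    real view, which is equivalent to treating Re/Im as separate scalars."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.t = 0
        self.m = {k: np.zeros_like(self._view(v)) for k, v in params.items()}
        self.v = {k: np.zeros_like(self._view(v)) for k, v in params.items()}

    @staticmethod
    def _view(a: np.ndarray) -> np.ndarray:
        return a.view(np.float64) if np.iscomplexobj(a) else a

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        self.t += 1
        c1 = 1 - self.b1**self.t
        c2 = 1 - self.b2**self.t
        for k, p in params.items():
            g = self._view(grads[k])
            m, v = self.m[k], self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            self._view(p)[...] -= self.lr * (m / c1) / (np.sqrt(v / c2) + self.eps)


class Adagrad:
    """Adagrad: per-parameter accumulated squared gradients."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.1,
                 eps: float = 1e-10):
        self.lr, self.eps = lr, eps
        self.g2 = {k: np.zeros_like(Adam._view(v)) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]):
        for k, p in params.items():
            g = Adam._view(grads[k])
            self.g2[k] += g * g
            Adam._view(p)[...] -= self.lr * g / (np.sqrt(self.g2[k]) + self.eps)


def _make_optimizer(config: "TrainConfig", params) -> Adam | Adagrad:
    if config.optimizer == "adam":
        return Adam(params, lr=config.lr)
    if config.optimizer == "adagrad":
        return Adagrad(params, lr=config.lr)
    raise ValueError(f"unknown optimizer {config.optimizer!r}")


# ---------------------------------------------------------------------------
# Objectives


def _softmax_ce(scores: np.ndarray, target: np.ndarray):
    """Row-wise CE of target column under softmax; returns (losses, dscores)."""
    shifted = scores - scores.max(axis=1, keepdims=True)
    exp = np.exp(shifted)
    Z = exp.sum(axis=1)
    probs = exp / Z[:, None]
    rows = np.arange(len(scores))
    losses = np.log(Z) - shifted[rows, target]
    dscores = probs
    dscores[rows, target] -= 1.0
    return losses, dscores


def _one_vs_all(model: EmbeddingModel, batch: np.ndarray, want_grads: bool):
    s, p, o = batch[:, 0], batch[:, 1], batch[:, 2]
    total = 0.0
    grads: dict[str, np.ndarray] | None = None
    scale = 1.0 / (2 * len(batch))
    for direction, e, target in (("tail", s, o), ("head", o, s)):
        scores, cache = model.forward_all(e, p, direction)
        losses, dscores = _softmax_ce(scores, target)
        total += losses.sum() * scale
        if want_grads:
            g = model._backward(cache, dscores * scale)
            grads = g if grads is None else _accumulate(grads, g)
    return total, grads


def _accumulate(a: dict, b: dict) -> dict:
    for k in a:
        a[k] += b[k]
    return a


def one_vs_all_loss(model: EmbeddingModel, batch: np.ndarray) -> float:
    """1vsAll cross-entropy averaged over the batch and both directions.

    With all-equal scores over N entities this equals ln(N) — the uniform
    baseline any learning run must beat.
    """
    batch = np.asarray(batch, dtype=np.int64).reshape(-1, 3)
    if len(batch) == 0:
        raise ValueError("empty batch")
    return float(_one_vs_all(model, batch, want_grads=False)[0])


def sample_negatives(
    batch: np.ndarray,
    k: int,
    n_entities: int,
    mode: str = "both",
    rng: np.random.Generator | None = None,
    filter_set: set | None = None,
    max_resample: int = 20,
) -> tuple[np.ndarray, np.ndarray]:
    """Corrupt one slot of each positive k times.

    Returns (negatives (B*k, 3), slot (B*k,)) with slot 0 = subject
    corrupted, 2 = object corrupted.  Each negative differs from its
    positive in exactly the corrupted slot.  With ``filter_set`` given,
    corruptions that are known-true triples are resampled up to
    ``max_resample`` rounds, after which possibly-true negatives are kept
    with a logged warning (saturated relations cannot always be filtered).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if mode not in ("corrupt-subject", "corrupt-object", "both"):
        raise ValueError(f"bad corruption mode {mode!r}")
    rng = rng or np.random.default_rng()
    batch = np.asarray(batch, dtype=np.int64).reshape(-1, 3)
    neg = np.repeat(batch, k, axis=0)
    n = len(neg)
    if mode == "corrupt-subject":
        slot = np.zeros(n, dtype=np.int64)
    elif mode == "corrupt-object":
        slot = np.full(n, 2, dtype=np.int64)
    else:
        slot = rng.choice([0, 2], size=n)
    rows = np.arange(n)
    original = neg[rows, slot].copy()

    def draw(m):
        return rng.integers(0, n_entities, size=m)

    neg[rows, slot] = draw(n)
    bad = neg[rows, slot] == original
    if filter_set is not None:
        bad |= np.fromiter(
            (tuple(t) in filter_set for t in neg), count=n, dtype=bool
        )
    tries = 0
    while bad.any() and tries < max_resample:
        idx = np.where(bad)[0]
        neg[idx, slot[idx]] = draw(len(idx))
        bad[idx] = neg[idx, slot[idx]] == original[idx]
        if filter_set is not None:
            bad[idx] |= np.fromiter(
                (tuple(t) in filter_set for t in neg[idx]), count=len(idx), dtype=bool
            )
        tries += 1
    if bad.any():
        # identical-to-positive corruptions are never acceptable; known-true
        # ones are tolerated once the resampling budget is exhausted
        idx = np.where(neg[rows, slot] == original)[0]
        if len(idx):
            neg[idx, slot[idx]] = (neg[idx, slot[idx]] + 1) % n_entities
        logger.warning(
            "negative sampling: %d possibly-true negatives kept after %d rounds",
            int(bad.sum()), max_resample,
        )
    return neg, slot


def margin_loss(model, positives, negatives, margin: float):
    """Mean over pairs of max(0, margin - f(pos) + f(neg))."""
    if margin <= 0:
        raise ValueError("margin must be positive")
    positives = np.asarray(positives, dtype=np.int64).reshape(-1, 3)
    negatives = np.asarray(negatives, dtype=np.int64).reshape(-1, 3)
    if len(positives) != len(negatives):
        raise ValueError("positives and negatives must align one-to-one")
    sp = model.score_triples(positives[:, 0], positives[:, 1], positives[:, 2])
    sn = model.score_triples(negatives[:, 0], negatives[:, 1], negatives[:, 2])
    return float(np.maximum(0.0, margin - sp + sn).mean())


def _negsamp_step(model, batch, config: TrainConfig, rng, filter_set):
    neg, _ = sample_negatives(
        batch,
        config.negatives,
        model.n_entities,
        config.corrupt,
        rng,
        filter_set if config.filter_negatives else None,
    )
    k = config.negatives
    sp, cache_p = model._pointwise(batch[:, 0], batch[:, 1], batch[:, 2])
    sn, cache_n = model._pointwise(neg[:, 0], neg[:, 1], neg[:, 2])
    if config.objective == "negsamp-margin":
        # each positive is paired with its k corruptions
        n = len(neg)
        act = (config.margin - np.repeat(sp, k) + sn) > 0
        loss = float(np.maximum(0.0, config.margin - np.repeat(sp, k) + sn).mean())
        w = act.astype(float) / n
        dpos = -w.reshape(-1, k).sum(axis=1)
        dneg = w
    else:
        # negsamp-CE: binary cross-entropy with logits
        n = len(batch) + len(neg)
        loss = float(
            (np.logaddexp(0.0, -sp).sum() + np.logaddexp(0.0, sn).sum()) / n
        )
        dpos = (1.0 / (1.0 + np.exp(-sp)) - 1.0) / n
        dneg = (1.0 / (1.0 + np.exp(-sn))) / n
    g1 = model._pointwise_backward(cache_p, dpos)
    g2 = model._pointwise_backward(cache_n, dneg)
    return loss, _accumulate(g1, g2)


def _reg_penalty(model, batch, config: TrainConfig, grads):
    """Weighted L2/N3 on the embeddings touched by the batch."""
    if config.reg <= 0:
        return 0.0
    lam = config.reg / len(batch)
    loss = 0.0
    for pname, idx in (("entity", batch[:, 0]), ("entity", batch[:, 2]),
                       ("relation", batch[:, 1])):
        if pname not in model.params:  # RotatE stores phases, not vectors
            continue
        rows = model.params[pname][idx]
        if config.reg_type == "l2":
            mag2 = (rows.real**2 + rows.imag**2) if np.iscomplexobj(rows) else rows**2
            loss += lam * mag2.sum()
            g = 2.0 * lam * rows
        elif config.reg_type == "n3":
            mag = np.abs(rows)
            loss += lam * (mag**3).sum()
            g = 3.0 * lam * mag * rows
        else:
            raise ValueError(f"bad reg_type {config.reg_type!r}")
        np.add.at(grads[pname], idx, g)
    return float(loss)


# ---------------------------------------------------------------------------
# Training loop


def train(
    model: EmbeddingModel, split: SplitKG, config: TrainConfig
) -> tuple[EmbeddingModel, TrainHistory]:
    """Stochastic training with periodic filtered-MRR validation.

    Returns the checkpoint with the best validation MRR seen (never a
    worse one), plus the full history.  Early stopping triggers after
    ``patience`` consecutive evaluations without improvement.
    """
    rng = np.random.default_rng(config.seed)
    triples = split.train
    history = TrainHistory()
    optimizer = _make_optimizer(config, model.params)
    filter_index = FilterIndex(split.filter_set)
    n_valid = min(config.valid_sample, len(split.valid))
    valid_idx = rng.choice(len(split.valid), size=n_valid, replace=False)
    valid_sub = split.valid[valid_idx]
    best_params = {k: v.copy() for k, v in model.params.items()}
    since_best = 0

    for epoch in range(1, config.max_epochs + 1):
        if config.lr_schedule == "cosine":
            frac = (epoch - 1) / max(config.max_epochs - 1, 1)
            lo = config.lr / 100.0
            optimizer.lr = lo + 0.5 * (config.lr - lo) * (1 + math.cos(math.pi * frac))
        perm = rng.permutation(len(triples))
        epoch_loss, n_batches = 0.0, 0
        for start in range(0, len(triples), config.batch_size):
            batch = triples[perm[start : start + config.batch_size]]
            if config.objective == "1vsAll-CE":
                loss, grads = _one_vs_all(model, batch, want_grads=True)
            else:
                loss, grads = _negsamp_step(model, batch, config, rng, split.filter_set)
            loss += _reg_penalty(model, batch, config, grads)
            if not math.isfinite(loss):
                raise FloatingPointError(
                    f"training diverged at epoch {epoch}: loss={loss}"
                )
            optimizer.step(model.params, grads)
            model.project_constraints()
            epoch_loss += loss
            n_batches += 1
        history.train_loss.append(epoch_loss / max(n_batches, 1))

        if epoch % config.eval_every == 0 or epoch == config.max_epochs:
            report = evaluate(model, valid_sub, filter_index)
            history.eval_epochs.append(epoch)
            history.valid_mrr.append(report.mrr)
            if report.mrr > history.best_mrr:
                history.best_mrr = report.mrr
                history.best_epoch = epoch
                best_params = {k: v.copy() for k, v in model.params.items()}
                since_best = 0
            else:
                since_best += 1
                if since_best >= config.patience:
                    history.stopped = "early_stop"
                    break

    best = model.copy()
    best.params = best_params
    return best, history


# ---------------------------------------------------------------------------
# Quasi-random hyperparameter optimization


@dataclass
class HPOResult:
    trials: list[tuple[dict, float]]
    best_index: int

    @property
    def best(self) -> tuple[dict, float]:
        return self.trials[self.best_index]


def _map_draw(u: float, spec):
    kind = spec[0]
    if kind == "log":
        lo, hi = spec[1], spec[2]
        return float(np.exp(np.log(lo) + u * (np.log(hi) - np.log(lo))))
    if kind == "uniform":
        lo, hi = spec[1], spec[2]
        return float(lo + u * (hi - lo))
    if kind == "choice":
        values = spec[1]
        return values[min(int(u * len(values)), len(values) - 1)]
    raise ValueError(f"bad search-space spec {spec!r}")


def hpo(
    split: SplitKG,
    model_name: str,
    search_space: dict,
    n_trials: int,
    seed: int,
    base_train: TrainConfig | None = None,
    base_model: ModelConfig | None = None,
) -> HPOResult:
    """Seeded quasi-random (Sobol) search over the declared space.

    ``search_space`` maps TrainConfig/ModelConfig field names ('dim' goes
    to the model) to ('log', lo, hi), ('uniform', lo, hi) or
    ('choice', [values]).  Each trial trains from scratch and is scored by
    best validation MRR; ties keep the earliest trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    from scipy.stats import qmc

    base_train = base_train or TrainConfig(seed=seed)
    base_model = base_model or ModelConfig(model_name, seed=seed)
    keys = list(search_space)
    sampler = qmc.Sobol(d=max(len(keys), 1), scramble=True, seed=seed)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        draws = sampler.random(n_trials)

    trials: list[tuple[dict, float]] = []
    best_index, best_mrr = 0, -np.inf
    for i in range(n_trials):
        assignment = {k: _map_draw(draws[i, j], search_space[k]) for j, k in enumerate(keys)}
        mcfg_fields = {k: v for k, v in assignment.items() if k in ("dim",)}
        tcfg_fields = {k: v for k, v in assignment.items() if k not in ("dim",)}
        mcfg = replace(base_model, name=model_name, **mcfg_fields)
        tcfg = replace(base_train, **tcfg_fields)
        model = init_model(mcfg, split.n_entities, split.n_relations)
        _, history = train(model, split, tcfg)
        trials.append((assignment, history.best_mrr))
        if history.best_mrr > best_mrr:
            best_mrr = history.best_mrr
            best_index = i
    return HPOResult(trials, best_index)
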