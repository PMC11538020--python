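"""Downstream procedures: transfer learning, relation classification,
and leave-one-relation-out pretraining ablation.

Transfer: a factorization model is trained on a small task KG twice under
identical seeds and budgets — once with its entity table initialized from
a checkpoint pretrained on the large KG (relation table always fresh,
since task relations are new labels), once entirely from scratch.  The
comparison of final filtered metrics and epochs-to-peak quantifies how
much of the pretrained entity geometry transfers.

Relation classification: entity-pair -> relation-label prediction
(including an explicit no-interaction class) with a small feed-forward
network over combined pair embeddings.  Three arms: pretrained-frozen,
pretrained-finetuned, scratch.

Ablation: retrain the pretraining model on the KG minus one relation at a
time (same seed and budget) and record the change in held-out HITS@10,
optionally propagating each ablated checkpoint through the transfer tasks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from kgelp.data import KnowledgeGraph, SplitKG, split as split_kg
from kgelp.evaluation import evaluate
from kgelp.models import EmbeddingModel, ModelConfig, init_model
from kgelp.synthetic import GeneratedTask
from kgelp.training import TrainConfig, TrainHistory, train

logger = logging.getLogger(__name__)

__all__ = [
    "TransferConfig",
    "ClassifierConfig",
    "transfer_lp",
    "build_pair_dataset",
    "train_classifier",
    "ablate_relations",
]


@dataclass
class TransferConfig:
    """Both arms share the checkpoint's embedding size, seed and budget."""

    train: TrainConfig
    entity_init: str = "pretrained"  # pretrained | scratch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.entity_init not in ("pretrained", "scratch"):
            raise ValueError("entity_init must be 'pretrained' or 'scratch'")


def _task_split(task: GeneratedTask, ratios=(0.8, 0.1, 0.1), seed: int = 0) -> SplitKG:
    return split_kg(task.kg, ratios, seed)


def _init_task_model(
    checkpoint: EmbeddingModel | None,
    model_config: ModelConfig,
    n_entities: int,
    n_relations: int,
    entity_init: str,
) -> EmbeddingModel:
    model = init_model(model_config, n_entities, n_relations)
    if entity_init == "pretrained":
        if checkpoint is None:
            raise ValueError("pretrained init requires a checkpoint")
        if checkpoint.n_entities < n_entities:
            raise ValueError(
                f"checkpoint covers {checkpoint.n_entities} entities, task needs "
                f"{n_entities}: unmapped task entities"
            )
        if checkpoint.dim != model_config.dim:
            raise ValueError("embedding size is fixed to the checkpoint's d")
        # entity table from the checkpoint; relation table stays fresh
        model.params["entity"] = checkpoint.params["entity"][:n_entities].copy()
    return model


def _epochs_to_fraction(history: TrainHistory, frac: float = 0.95) -> int:
    """First evaluated epoch reaching ``frac`` of the best validation MRR."""
    return epochs_to_level(history.eval_epochs, history.valid_mrr,
                           frac * history.best_mrr)


def epochs_to_level(eval_epochs, valid_mrr, level: float) -> int:
    """First evaluated epoch whose validation MRR reaches ``level``.

    Used to compare arms against a common performance bar ("epochs to
    reach similar or better performance"); falls back to the last
    evaluated epoch if the level is never reached.
    """
    for epoch, mrr in zip(eval_epochs, valid_mrr):
        if mrr >= level:
            return epoch
    return eval_epochs[-1] if len(eval_epochs) else 0


def transfer_lp(
    task: GeneratedTask,
    checkpoint: EmbeddingModel | None,
    config: TransferConfig,
    split_seed: int = 0,
) -> dict:
    """Train pretrained-init and scratch arms on a task KG; report both.

    Returns per-arm final filtered MRR/HITS@10, epochs-to-peak (first
    epoch attaining the best validation MRR), epochs to reach 95% of the
    arm's own best validation MRR, and — when both arms run — epochs to
    reach 95% of the scratch arm's best ("epochs to similar or better
    performance", the headline speed comparison).
    """
    sp = _task_split(task, seed=split_seed)
    out: dict[str, dict] = {"task": task.spec.name, "arms": {}}
    for arm in ("pretrained", "scratch"):
        if arm == "pretrained" and checkpoint is None:
            continue
        mcfg = ModelConfig(
            checkpoint.config.name if checkpoint else "ComplEx",
            dim=checkpoint.dim if checkpoint else 32,
            seed=config.seed,
        )
        model = _init_task_model(
            checkpoint, mcfg, task.kg.n_entities, task.kg.n_relations, arm
        )
        trained, history = train(model, sp, config.train)
        report = evaluate(trained, sp.test, sp.filter_set)
        out["arms"][arm] = {
            "mrr": report.mrr,
            "hits@10": report.hits[10],
            "best_valid_mrr": history.best_mrr,
            "epochs_to_peak": history.best_epoch,
            "epochs_to_95": _epochs_to_fraction(history, 0.95),
            "history": history.to_dict(),
        }
    if "pretrained" in out["arms"] and "scratch" in out["arms"]:
        # epochs for each arm to reach 95% of the scratch arm's best MRR —
        # "fewer epochs to reach similar or better performance"
        bar = 0.95 * out["arms"]["scratch"]["best_valid_mrr"]
        for arm, rep_arm in out["arms"].items():
            h = rep_arm["history"]
            rep_arm["epochs_to_scratch95"] = epochs_to_level(
                h["eval_epochs"], h["valid_mrr"], bar
            )
    return out


# ---------------------------------------------------------------------------
# Relation classification


def build_pair_dataset(
    task: GeneratedTask, no_interaction_ratio: float, seed: int
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Labelled entity pairs: task triples plus no-interaction negatives.

    Returns (pairs (N, 2), labels (N,), label_names) where the last label
    is the explicit no-interaction class.  Negatives are drawn from the
    task's held-out pool of pairs that score below every task relation's
    threshold, so they collide with neither the task KG nor the planted
    facts.
    """
    rng = np.random.default_rng(seed)
    t = task.kg.triples
    pairs = [t[:, [0, 2]]]
    labels = [t[:, 1]]
    names = list(task.kg.relations)
    n_neg = int(round(no_interaction_ratio * len(t)))
    if n_neg > 0:
        pool = task.no_interaction_pairs
        if n_neg > len(pool):
            raise ValueError(
                f"no-interaction pool too small: {len(pool)} < {n_neg}"
            )
        take = pool[rng.choice(len(pool), size=n_neg, replace=False)]
        pairs.append(take)
        labels.append(np.full(n_neg, len(names), dtype=np.int64))
        names.append("no_interaction")
    pairs = np.vstack(pairs)
    labels = np.concatenate(labels)
    perm = rng.permutation(len(pairs))
    return pairs[perm], labels[perm], names


@dataclass
class ClassifierConfig:
    source: str = "scratch"  # pretrained-frozen | pretrained-finetuned | scratch
    dim: int = 32  # embedding size (scratch arm); pretrained arms inherit
    hidden: int = 32
    combine: str = "concat"  # concat | hadamard | sum
    batch_size: int = 512
    lr: float = 1e-4
    epochs: int = 200
    test_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.source not in ("pretrained-frozen", "pretrained-finetuned", "scratch"):
            raise ValueError(f"bad embedding source {self.source!r}")
        if self.combine not in ("concat", "hadamard", "sum"):
            raise ValueError(f"bad combine mode {self.combine!r}")


def _as_real_embedding(table: np.ndarray) -> np.ndarray:
    """Complex tables flatten to [Re | Im] features."""
    if np.iscomplexobj(table):
        return np.concatenate([table.real, table.imag], axis=1)
    return np.asarray(table, dtype=np.float64)


class PairClassifier:
    """One-hidden-layer softmax network over combined pair embeddings.

    Parameters: the (possibly trainable) entity embedding table plus
    W1/b1/W2/b2.  Trained with Adam and cross-entropy.
    """

    def __init__(self, embedding: np.ndarray, n_classes: int, config: ClassifierConfig):
        rng = np.random.default_rng(config.seed)
        self.config = config
        self.embedding = embedding.copy()
        d = self.embedding.shape[1]
        d_in = 2 * d if config.combine == "concat" else d
        h = config.hidden
        limit = np.sqrt(6.0 / (d_in + h))
        self.W1 = rng.uniform(-limit, limit, (d_in, h))
        self.b1 = np.zeros(h)
        limit = np.sqrt(6.0 / (h + n_classes))
        self.W2 = rng.uniform(-limit, limit, (h, n_classes))
        self.b2 = np.zeros(n_classes)

    def _combine(self, pairs: np.ndarray):
        a = self.embedding[pairs[:, 0]]
        b = self.embedding[pairs[:, 1]]
        mode = self.config.combine
        if mode == "concat":
            return np.concatenate([a, b], axis=1)
        return a * b if mode == "hadamard" else a + b

    def forward(self, pairs: np.ndarray):
        x = self._combine(pairs)
        z1 = x @ self.W1 + self.b1
        a1 = np.maximum(z1, 0.0)
        logits = a1 @ self.W2 + self.b2
        return logits, (x, z1, a1)

    def predict_proba(self, pairs: np.ndarray) -> np.ndarray:
        logits, _ = self.forward(pairs)
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        return e / e.sum(axis=1, keepdims=True)


def train_classifier(
    pairs: np.ndarray,
    labels: np.ndarray,
    embedding: np.ndarray,
    config: ClassifierConfig,
) -> tuple[PairClassifier, dict]:
    """Fit the pair classifier and report macro AUROC/AUPRC/MAP.

    The embedding argument supplies the pretrained table for the
    pretrained arms (complex tables are flattened to [Re | Im]); the
    scratch arm receives a fresh random table of width ``config.dim``.
    Frozen arms leave the embedding bit-identical; the fine-tuned arm
    updates the rows touched by training pairs.  Metrics are one-vs-rest
    macro averages on a held-out fraction; MAP is the macro mean of the
    per-class average precision.
    """
    labels = np.asarray(labels, dtype=np.int64)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("classification needs at least two classes")
    n_classes = int(labels.max()) + 1
    rng = np.random.default_rng(config.seed)

    if config.source == "scratch":
        n_ent = int(pairs.max()) + 1 if embedding is None else len(embedding)
        table = rng.uniform(-0.1, 0.1, (n_ent, 2 * config.dim))
    else:
        if embedding is None:
            raise ValueError("pretrained arms need an embedding table")
        table = _as_real_embedding(embedding)
    finetune = config.source == "pretrained-finetuned"

    n = len(pairs)
    n_test = max(int(round(config.test_fraction * n)), 1)
    perm = rng.permutation(n)
    test_idx, train_idx = perm[:n_test], perm[n_test:]

    clf = PairClassifier(table, n_classes, config)
    frozen_before = clf.embedding.copy()

    # Adam state
    params = {"W1": clf.W1, "b1": clf.b1, "W2": clf.W2, "b2": clf.b2}
    if finetune:
        params["embedding"] = clf.embedding
    m = {k: np.zeros_like(v) for k, v in params.items()}
    v = {k: np.zeros_like(v_) for k, v_ in params.items()}
    t_step = 0

    for _ in range(config.epochs):
        order = rng.permutation(len(train_idx))
        for start in range(0, len(order), config.batch_size):
            idx = train_idx[order[start : start + config.batch_size]]
            bp, by = pairs[idx], labels[idx]
            logits, (x, z1, a1) = clf.forward(bp)
            logits -= logits.max(axis=1, keepdims=True)
            e = np.exp(logits)
            probs = e / e.sum(axis=1, keepdims=True)
            dlogits = probs
            dlogits[np.arange(len(by)), by] -= 1.0
            dlogits /= len(by)
            grads = {
                "W2": a1.T @ dlogits,
                "b2": dlogits.sum(0),
            }
            da1 = dlogits @ clf.W2.T
            dz1 = da1 * (z1 > 0)
            grads["W1"] = x.T @ dz1
            grads["b1"] = dz1.sum(0)
            if finetune:
                dx = dz1 @ clf.W1.T
                demb = np.zeros_like(clf.embedding)
                d_emb_dim = clf.embedding.shape[1]
                if config.combine == "concat":
                    np.add.at(demb, bp[:, 0], dx[:, :d_emb_dim])
                    np.add.at(demb, bp[:, 1], dx[:, d_emb_dim:])
                elif config.combine == "sum":
                    np.add.at(demb, bp[:, 0], dx)
                    np.add.at(demb, bp[:, 1], dx)
                else:  # hadamard
                    np.add.at(demb, bp[:, 0], dx * clf.embedding[bp[:, 1]])
                    np.add.at(demb, bp[:, 1], dx * clf.embedding[bp[:, 0]])
                grads["embedding"] = demb
            t_step += 1
            c1 = 1 - 0.9**t_step
            c2 = 1 - 0.999**t_step
            for k, p in params.items():
                g = grads[k]
                m[k] = 0.9 * m[k] + 0.1 * g
                v[k] = 0.999 * v[k] + 0.001 * g * g
                p -= config.lr * (m[k] / c1) / (np.sqrt(v[k] / c2) + 1e-8)

    if not finetune:
        assert np.array_equal(clf.embedding, frozen_before)

    probs = clf.predict_proba(pairs[test_idx])
    report = classification_metrics(labels[test_idx], probs)
    report["source"] = config.source
    report["n_test"] = int(n_test)
    return clf, report


def classification_metrics(y_true: np.ndarray, probs: np.ndarray) -> dict:
    """Macro one-vs-rest AUROC, AUPRC, and MAP (= macro mean AP)."""
    present = np.unique(y_true)
    aurocs, aps = [], []
    for c in present:
        y = (y_true == c).astype(int)
        if y.min() == y.max():
            continue  # degenerate class in this split
        aurocs.append(roc_auc_score(y, probs[:, c]))
        aps.append(average_precision_score(y, probs[:, c]))
    return {
        "auroc": float(np.mean(aurocs)),
        "auprc": float(np.mean(aps)),
        "map": float(np.mean(aps)),
    }


# ---------------------------------------------------------------------------
# Relation ablation


def ablate_relations(
    pretrain_kg: KnowledgeGraph,
    model_config: ModelConfig,
    train_config: TrainConfig,
    split_seed: int = 0,
    ratios=(0.8, 0.1, 0.1),
    reverse_relations: set[int] | None = None,
    tasks: list[GeneratedTask] | None = None,
    transfer_config: TransferConfig | None = None,
    eval_triples: int | None = None,
) -> pd.DataFrame:
    """Leave-one-relation-out retraining, all runs identically seeded.

    For each relation r the KG minus all r-triples is re-split with the
    same seed, the model retrained with the same config, and evaluated on
    its own (reduced) test set; the table reports HITS@10 deltas against
    the full-KG baseline, plus per-task transfer deltas when a task suite
    is given.  Relations whose removal would empty a split are skipped
    with a logged reason.
    """
    if pretrain_kg.n_relations < 2:
        raise ValueError("ablation needs at least two relations")
    reverse_relations = reverse_relations or set()

    def run(kg: KnowledgeGraph) -> tuple[float, EmbeddingModel]:
        sp = split_kg(kg, ratios, split_seed)
        rel_present = set(np.unique(kg.triples[:, 1]).tolist())
        sp = sp.with_train_reverses(kg, reverse_relations & rel_present)
        model = init_model(model_config, kg.n_entities, kg.n_relations)
        trained, _ = train(model, sp, train_config)
        test = sp.test if eval_triples is None else sp.test[:eval_triples]
        report = evaluate(trained, test, sp.filter_set)
        return report.hits[10], trained

    base_hits, base_model = run(pretrain_kg)
    rows = [{"removed": "(none)", "hits@10": base_hits, "delta": 0.0}]

    task_base: dict[str, float] = {}
    if tasks:
        for task in tasks:
            rep = transfer_lp(task, base_model, transfer_config, split_seed)
            task_base[task.spec.name] = rep["arms"]["pretrained"]["hits@10"]
            rows[0][f"task_{task.spec.name}_hits@10"] = task_base[task.spec.name]

    for r in range(pretrain_kg.n_relations):
        keep = pretrain_kg.triples[:, 1] != r
        if keep.sum() == 0 or (~keep).sum() == 0:
            logger.warning("skipping relation %d: removal empties the KG", r)
            continue
        reduced = pretrain_kg.replace_triples(pretrain_kg.triples[keep])
        try:
            hits, model_r = run(reduced)
        except ValueError as err:
            logger.warning("skipping relation %s: %s", pretrain_kg.relations[r], err)
            continue
        row = {
            "removed": pretrain_kg.relations[r],
            "hits@10": hits,
            "delta": hits - base_hits,
        }
        if tasks:
            for task in tasks:
                rep = transfer_lp(task, model_r, transfer_config, split_seed)
                h = rep["arms"]["pretrained"]["hits@10"]
                row[f"task_{task.spec.name}_hits@10"] = h
                row[f"task_{task.spec.name}_delta"] = h - task_base[task.spec.name]
        rows.append(row)
    return pd.DataFrame(rows)
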