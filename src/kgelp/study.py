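"""Canonical study conditions: the experiments the package is built around.

This module pins the configurations used by the acceptance experiments and
the reproduction script so that tests, scripts and documentation all run
the same study: the default synthetic KG (~600 entities, 8 relations,
~21.6k triples, 5% noise, dominant symmetric drug-drug relation), an
80/10/10 split with reverse augmentation of the symmetric relations
applied to the training partition only, and fixed desk-scale training
recipes chosen to converge in seconds per run on one CPU.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from kgelp import data
from kgelp.data import SplitKG
from kgelp.models import ModelConfig, init_model
from kgelp.synthetic import (
    default_config, default_task_specs, generate_pretrain_kg, generate_task_kgs,
)
from kgelp.training import TrainConfig, train

SPLIT_RATIOS = (0.8, 0.1, 0.1)

#: 1vsAll-CE recipe for factorization models on the default KG.
PRETRAIN_RECIPE = TrainConfig(
    objective="1vsAll-CE",
    optimizer="adagrad",
    lr=0.5,
    reg=1e-3,
    reg_type="n3",
    batch_size=512,
    max_epochs=100,
    eval_every=10,
    patience=6,
    valid_sample=400,
)

#: negative-sampling + margin-ranking baseline regime, equal epoch budget.
MARGIN_RECIPE = replace(
    PRETRAIN_RECIPE,
    objective="negsamp-margin",
    optimizer="adam",
    negatives=10,
    margin=1.0,
    lr=1e-2,
    reg=0.0,
)


def TRANSFER_RECIPE(seed: int) -> TrainConfig:
    """Task-KG training arm: small batches (task KGs hold a few hundred
    triples), per-epoch validation so epochs-to-level is well resolved,
    no early stopping within the fixed budget."""
    return TrainConfig(
        optimizer="adagrad", lr=0.3, batch_size=64, max_epochs=60,
        eval_every=1, patience=100, valid_sample=100, seed=seed,
    )


def study_kg(seed: int):
    """Default synthetic KG plus its ground truth."""
    return generate_pretrain_kg(default_config(seed))


def study_split(kg, seed: int) -> SplitKG:
    """80/10/10 split with train-only reverse augmentation (DDI/PPI)."""
    sym = {kg.relation_index[r] for r, s in (kg.schema or {}).items() if s.symmetric}
    sp = data.split(kg, SPLIT_RATIOS, seed)
    return sp.with_train_reverses(kg, sym) if sym else sp


def pretrain(kg, split: SplitKG, model_name: str, seed: int,
             dim: int = 32, recipe: TrainConfig | None = None):
    """Train one embedding model under the study recipe; returns
    (best model, history)."""
    recipe = replace(recipe or PRETRAIN_RECIPE, seed=seed)
    model = init_model(
        ModelConfig(model_name, dim=dim, seed=seed), kg.n_entities, kg.n_relations
    )
    return train(model, split, recipe)


def study_tasks(gt, seed: int):
    return generate_task_kgs(gt, default_task_specs(), seed)
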