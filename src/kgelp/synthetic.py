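"""Synthetic biomedical knowledge graphs with a planted factorization.

The generator emulates the statistical shape of a large heterogeneous
biomedical KG: six typed entity classes (drugs, proteins, diseases,
pathways, complexes, genetic disorders), a relation schema with fixed
subject/object classes per relation, a dominant symmetric drug-drug
interaction relation holding roughly half of all triples, a relation
frequency skew spanning two orders of magnitude, and a deliberately
redundant relation that duplicates another relation's facts under a new
label (for ablation experiments).

Ground truth is *planted*: every entity carries a latent complex factor
e in C^d, every relation a factor r (real for symmetric relations, so the
planted score is exactly symmetric), and a pair (s, o) is a true fact of
relation p iff Re(<e_s, r_p, conj(e_o)>) exceeds the relation's inclusion
threshold — thresholds are set by target-count quantiles.  A configurable
noise fraction of each relation's facts is replaced by uniformly random
admissible pairs, which by construction score below threshold.  The
factors are kept for audit (parameter-recovery checks) and never shown to
the models.

Downstream task KGs reuse the same entity factors with *fresh* relation
factors, so pretrained entity embeddings carry transferable signal while
the task relations themselves are new, plus a pool of "no interaction"
pairs scoring below every task threshold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np

from kgelp.data import KnowledgeGraph, RelationSchema

__all__ = [
    "RelationSpec",
    "GeneratorConfig",
    "SyntheticGroundTruth",
    "TaskSpec",
    "GeneratedTask",
    "PlantedScorer",
    "default_config",
    "default_task_specs",
    "generate_pretrain_kg",
    "generate_task_kgs",
    "summarize",
]


@dataclass(frozen=True)
class RelationSpec:
    name: str
    subject_class: str
    object_class: str
    count: int  # emitted triples (symmetric relations count both orientations)
    symmetric: bool = False
    dominant: bool = False
    redundant_with: str | None = None


@dataclass
class GeneratorConfig:
    class_sizes: dict[str, int]
    relations: list[RelationSpec]
    latent_dim: int = 16
    noise: float = 0.05
    class_separation: float = 2.0  # class-center magnitude per block dim (kappa)
    schema_bias: float = 4.0  # relation alignment with its class pair (rho)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.noise < 1:
            raise ValueError("noise fraction must be in [0, 1)")
        if sum(r.dominant for r in self.relations) > 1:
            raise ValueError("at most one relation may be marked dominant")
        for r in self.relations:
            if r.symmetric and r.subject_class != r.object_class:
                raise ValueError(f"symmetric relation {r.name} must join one class")
            if r.symmetric and r.count % 2:
                raise ValueError(
                    f"symmetric relation {r.name} needs an even triple count"
                )


def default_config(seed: int = 0) -> GeneratorConfig:
    """~600 entities over six classes, 8 relations, ~21.6k triples.

    The drug-drug interaction analogue is symmetric and dominant (~46% of
    triples); ``drug_target`` duplicates ``dpi`` fact-for-fact (planted
    redundancy); the rarest relation sits two orders of magnitude below
    the dominant one, mirroring the log-scale frequency skew of real
    biomedical KGs.  The triple budget is spread so that every major
    entity class accumulates roughly twenty or more facts per entity —
    enough observations for its planted factors to be identifiable from
    the training split; the deliberately rare relation is carried by the
    smallest class (complexes).
    """
    return GeneratorConfig(
        class_sizes={
            "drug": 150,
            "protein": 180,
            "disease": 120,
            "pathway": 60,
            "complex": 50,
            "genetic_disorder": 40,
        },
        relations=[
            RelationSpec("ddi", "drug", "drug", 10000, symmetric=True, dominant=True),
            RelationSpec("ppi", "protein", "protein", 3000, symmetric=True),
            RelationSpec("dpi", "drug", "protein", 1800),
            RelationSpec("drug_disease", "drug", "disease", 2600),
            RelationSpec("protein_pathway", "protein", "pathway", 1500),
            RelationSpec("protein_disorder", "protein", "genetic_disorder", 800),
            RelationSpec("drug_target", "drug", "protein", 1800, redundant_with="dpi"),
            RelationSpec("complex_pathway", "complex", "pathway", 100),
        ],
        latent_dim=16,
        noise=0.05,
        seed=seed,
    )


@dataclass
class SyntheticGroundTruth:
    """Latent factors and thresholds the generator planted (audit only)."""

    entity_factors: np.ndarray  # (Ne, d) complex
    relation_factors: dict[str, np.ndarray]  # name -> (d,) complex
    thresholds: dict[str, float]
    class_slices: dict[str, np.ndarray]  # class -> entity indices
    config: GeneratorConfig
    fact_pairs: dict[str, np.ndarray] | None = None  # emitted (s, o) per relation
    class_centers: dict[str, np.ndarray] | None = None  # class -> (d,) complex

    def factor_of(self, name: str) -> np.ndarray:
        return self.relation_factors[name]

    def save(self, prefix: str) -> None:
        arrays = {"entity_factors": self.entity_factors}
        for k, v in self.relation_factors.items():
            arrays[f"rel__{k}"] = v
        for k, v in self.class_slices.items():
            arrays[f"cls__{k}"] = v
        np.savez(str(prefix) + ".npz", **arrays)
        manifest = {"thresholds": self.thresholds, "config": _config_dict(self.config)}
        with open(str(prefix) + ".json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)


def _config_dict(config: GeneratorConfig) -> dict:
    d = asdict(config)
    d["relations"] = [asdict(r) for r in config.relations]
    return d


class PlantedScorer:
    """Oracle scorer over the planted factors (the generator's own model).

    Exposes the same contract as an embedding model so it can run through
    filtered evaluation; on noise-free held-out facts it ranks the true
    completion first by construction.
    """

    def __init__(self, gt: SyntheticGroundTruth, relation_names: list[str]):
        self.E = gt.entity_factors
        self.R = np.stack([gt.relation_factors[n] for n in relation_names])
        self.n_entities = len(self.E)
        # self-pairs are never admissible; exclude the query entity itself
        # for same-class relations so it cannot outrank real candidates
        specs = {r.name: r for r in gt.config.relations}
        self._same_class = np.array([
            specs[n].subject_class == specs[n].object_class
            for n in relation_names
        ]) if all(n in specs for n in relation_names) else np.zeros(
            len(relation_names), dtype=bool)

    def _score(self, e, p, conj_rel: bool):
        e1, p1 = np.atleast_1d(e), np.atleast_1d(p)
        r = np.conj(self.R[p1]) if conj_rel else self.R[p1]
        t = self.E[e1] * r
        out = t.real @ self.E.real.T + t.imag @ self.E.imag.T
        same = self._same_class[p1]
        out[same, e1[same]] = -np.inf
        return out

    def score_all_objects(self, s, p):
        out = self._score(s, p, conj_rel=False)
        return out[0] if np.isscalar(s) else out

    def score_all_subjects(self, p, o):
        out = self._score(o, p, conj_rel=True)
        return out[0] if np.isscalar(o) else out


# ---------------------------------------------------------------------------


def _admissible_pairs(sub_idx: np.ndarray, obj_idx: np.ndarray, symmetric: bool):
    """Candidate (s, o) pairs for a relation; symmetric relations use
    unordered pairs (i < j), distinct entities always."""
    if symmetric:
        i, j = np.triu_indices(len(sub_idx), k=1)
        return np.column_stack([sub_idx[i], sub_idx[j]])
    s = np.repeat(sub_idx, len(obj_idx))
    o = np.tile(obj_idx, len(sub_idx))
    if sub_idx is obj_idx or np.array_equal(sub_idx, obj_idx):
        keep = s != o
        s, o = s[keep], o[keep]
    return np.column_stack([s, o])


def _planted_pair_scores(E, r, pairs):
    t = E[pairs[:, 0]] * r
    eo = E[pairs[:, 1]]
    return (t * np.conj(eo)).real.sum(axis=1)


def _class_centers(config: GeneratorConfig, d: int) -> dict[str, np.ndarray]:
    """Block-structured class centers with exact cross-class cancellation.

    Each unordered class pair used by some relation owns a block of latent
    dimensions.  On the block of pair (A, B) the subject class's center has
    phase 1 and the object class's phase i (same-class blocks stay real), at
    magnitude kappa.  The schema-aligned relation bias (see
    :func:`_relation_factor`) then gives the relation's own class pair a
    baseline score of +kappa^2 * rho per block dimension, the reversed
    orientation a negative baseline, and every other ordered class pair
    exactly zero — so the planted score itself ranks wrong-class candidates
    low, the way typed-entity embeddings separate in real KGs.
    """
    pairs: list[tuple[str, str]] = []
    for spec in config.relations:
        key = tuple(sorted((spec.subject_class, spec.object_class)))
        if key not in pairs:
            pairs.append(key)
    if len(pairs) > d:
        raise ValueError(
            f"latent_dim {d} too small for {len(pairs)} class pairs"
        )
    kappa = config.class_separation
    centers = {cls: np.zeros(d, dtype=complex) for cls in config.class_sizes}
    m = d // len(pairs)
    for j, key in enumerate(pairs):
        dims = slice(j * m, (j + 1) * m)
        # orientation fixed by the first relation using this pair
        spec = next(
            s for s in config.relations
            if tuple(sorted((s.subject_class, s.object_class))) == key
        )
        if spec.subject_class == spec.object_class:
            centers[spec.subject_class][dims] = kappa
        else:
            centers[spec.subject_class][dims] = kappa
            centers[spec.object_class][dims] = kappa * 1j
    return centers


def _relation_factor(rng, d, centers, sub_class, obj_class, symmetric, rho):
    """Random relation factor plus a schema-aligned bias component.

    The bias b_k = conj(mu_A_k) mu_B_k / |mu_A_k mu_B_k| (zero where either
    center vanishes) gives Re(<mu_A, r, conj(mu_B)>) a baseline of
    rho * kappa^2 per shared block dimension for the relation's own class
    pair, while other ordered class pairs cancel exactly under the block
    construction of :func:`_class_centers`.  For a same-class symmetric
    relation the bias is real, keeping the planted score exactly symmetric.
    """
    r = (rng.normal(size=d) + 1j * rng.normal(size=d)) / np.sqrt(2)
    if symmetric:
        r = r.real.astype(complex)
    if not centers:
        return r
    mu_a, mu_b = centers[sub_class], centers[obj_class]
    mag = np.abs(mu_a) * np.abs(mu_b)
    b = np.where(mag > 1e-12, np.conj(mu_a) * mu_b / (mag + 1e-300), 0.0)
    return r + rho * b


def generate_pretrain_kg(config: GeneratorConfig):
    """Generate the pretraining KG; returns (kg, ground_truth).

    Deterministic given the config seed: same seed, byte-identical output.
    """
    rng = np.random.default_rng(config.seed)
    entities: list[str] = []
    classes: dict[str, str] = {}
    class_slices: dict[str, np.ndarray] = {}
    for cls, n in config.class_sizes.items():
        start = len(entities)
        for i in range(n):
            label = f"{cls}_{i:04d}"
            entities.append(label)
            classes[label] = cls
        class_slices[cls] = np.arange(start, start + n)
    ne = len(entities)
    d = config.latent_dim

    # class centers: entities of one type cluster in factor space, as
    # embeddings of typed biomedical entities do; kappa scales separation
    centers = _class_centers(config, d)

    E = (rng.normal(size=(ne, d)) + 1j * rng.normal(size=(ne, d))) / np.sqrt(2)
    for cls, idx in class_slices.items():
        E[idx] += centers[cls]
    rel_factors: dict[str, np.ndarray] = {}
    thresholds: dict[str, float] = {}
    chosen_pairs: dict[str, np.ndarray] = {}
    triples = []
    relation_names = [r.name for r in config.relations]
    schema = {
        r.name: RelationSchema(r.subject_class, r.object_class, r.symmetric)
        for r in config.relations
    }

    for spec in config.relations:
        if spec.redundant_with is not None:
            if spec.redundant_with not in chosen_pairs:
                raise ValueError(
                    f"{spec.name}: redundant_with target {spec.redundant_with!r} "
                    "must be declared earlier"
                )
            rel_factors[spec.name] = rel_factors[spec.redundant_with]
            thresholds[spec.name] = thresholds[spec.redundant_with]
            chosen_pairs[spec.name] = chosen_pairs[spec.redundant_with]
            continue
        r = _relation_factor(rng, d, centers, spec.subject_class,
                             spec.object_class, spec.symmetric,
                             config.schema_bias)
        rel_factors[spec.name] = r

        pairs = _admissible_pairs(
            class_slices[spec.subject_class], class_slices[spec.object_class],
            spec.symmetric,
        )
        n_pairs = spec.count // 2 if spec.symmetric else spec.count
        if n_pairs > len(pairs):
            raise ValueError(
                f"{spec.name}: target {spec.count} exceeds {len(pairs)} admissible pairs"
            )
        scores = _planted_pair_scores(E, r, pairs)
        order = np.argsort(-scores, kind="stable")
        top = order[:n_pairs]
        sel = pairs[top]
        cut = scores[order[n_pairs - 1]]
        below = scores[order[n_pairs]] if n_pairs < len(pairs) else cut - 1.0
        thresholds[spec.name] = float((cut + below) / 2.0)

        n_noise = int(np.floor(config.noise * n_pairs))
        if n_noise:
            selected_keys = set(map(tuple, sel.tolist()))
            replace_at = rng.choice(n_pairs, size=n_noise, replace=False)
            pool = pairs[order[n_pairs:]]
            pool_idx = rng.choice(len(pool), size=n_noise, replace=False)
            sel = sel.copy()
            sel[replace_at] = pool[pool_idx]
            del selected_keys
        chosen_pairs[spec.name] = sel

    for spec in config.relations:
        pidx = relation_names.index(spec.name)
        sel = chosen_pairs[spec.name]
        if spec.symmetric:
            fwd = np.column_stack([sel[:, 0], np.full(len(sel), pidx), sel[:, 1]])
            rev = np.column_stack([sel[:, 1], np.full(len(sel), pidx), sel[:, 0]])
            triples.append(np.vstack([fwd, rev]))
        else:
            triples.append(
                np.column_stack([sel[:, 0], np.full(len(sel), pidx), sel[:, 1]])
            )

    kg = KnowledgeGraph(
        entities, relation_names, np.vstack(triples), schema=schema,
        entity_classes=classes,
    )
    gt = SyntheticGroundTruth(
        E, rel_factors, thresholds, class_slices, config,
        fact_pairs=chosen_pairs, class_centers=centers,
    )
    return kg, gt


# ---------------------------------------------------------------------------
# Downstream task KGs


@dataclass(frozen=True)
class TaskSpec:
    name: str
    relation_labels: tuple[str, ...]
    subject_class: str
    object_class: str
    n_per_relation: int
    no_interaction_ratio: float = 1.0

    def __post_init__(self) -> None:
        if len(self.relation_labels) < 2:
            raise ValueError("a task needs at least two relation labels")
        if self.no_interaction_ratio < 0:
            raise ValueError("no_interaction_ratio must be >= 0")


def default_task_specs() -> list[TaskSpec]:
    """Four polypharmacy-style tasks over the pretraining entities.

    Two drug-drug interaction-effect tasks, a deliberately small
    drug-protein target task (the low-data transfer scenario), and a larger
    drug-protein expression-effect task.
    """
    return [
        TaskSpec("efficacy", ("increases_efficacy", "decreases_efficacy"),
                 "drug", "drug", 250),
        TaskSpec("minerals", ("increases_mineral", "decreases_mineral"),
                 "drug", "drug", 250),
        TaskSpec("dpi", ("inhibits", "activates"), "drug", "protein", 150),
        TaskSpec("dep", ("increases_expression", "decreases_expression"),
                 "drug", "protein", 400),
    ]


@dataclass
class GeneratedTask:
    spec: TaskSpec
    kg: KnowledgeGraph  # positives only; vocabulary = pretraining entities
    no_interaction_pairs: np.ndarray  # (M, 2) entity index pairs
    relation_factors: dict[str, np.ndarray]
    thresholds: dict[str, float]


def generate_task_kgs(
    gt: SyntheticGroundTruth, specs: list[TaskSpec], seed: int
) -> list[GeneratedTask]:
    """Task KGs from the same entity factors under fresh relation factors."""
    pretrain_relations = {r.name for r in gt.config.relations}
    E = gt.entity_factors
    d = E.shape[1]
    entities = [
        f"{cls}_{i:04d}"
        for cls, idx in ((c, gt.class_slices[c]) for c in gt.config.class_sizes)
        for i in range(len(idx))
    ]
    out = []
    for t_i, spec in enumerate(specs):
        overlap = pretrain_relations & set(spec.relation_labels)
        if overlap:
            raise ValueError(f"task relations {overlap} collide with pretraining labels")
        rng = np.random.default_rng(seed + 7919 * t_i)
        pairs = _admissible_pairs(
            gt.class_slices[spec.subject_class], gt.class_slices[spec.object_class],
            symmetric=False,
        )
        if len(pairs) < spec.n_per_relation * len(spec.relation_labels):
            raise ValueError(f"task {spec.name}: admissible pool too small")
        taken = np.zeros(len(pairs), dtype=bool)
        factors: dict[str, np.ndarray] = {}
        thresholds: dict[str, float] = {}
        triples = []
        for r_i, label in enumerate(spec.relation_labels):
            r = _relation_factor(
                rng, d, gt.class_centers or {}, spec.subject_class,
                spec.object_class, symmetric=False,
                rho=gt.config.schema_bias if gt.class_centers else 0.0,
            )
            factors[label] = r
            scores = _planted_pair_scores(E, r, pairs)
            order = np.argsort(-scores, kind="stable")
            free = order[~taken[order]]
            top = free[: spec.n_per_relation]
            taken[top] = True
            thresholds[label] = float(scores[top].min())
            sel = pairs[top]
            triples.append(
                np.column_stack([sel[:, 0], np.full(len(sel), r_i), sel[:, 1]])
            )
        triples = np.vstack(triples)

        # no-interaction pool: admissible pairs below every task threshold
        # and absent from the pretraining KG's planted facts
        below_all = ~taken
        for label in spec.relation_labels:
            below_all &= (
                _planted_pair_scores(E, factors[label], pairs) < thresholds[label]
            )
        pretrain_facts: set[tuple[int, int]] = set()
        if gt.fact_pairs:
            for rspec in gt.config.relations:
                sel = gt.fact_pairs[rspec.name]
                pretrain_facts.update(map(tuple, sel.tolist()))
                if rspec.symmetric:
                    pretrain_facts.update(map(tuple, sel[:, ::-1].tolist()))
        if pretrain_facts:
            below_all &= np.fromiter(
                ((int(s), int(o)) not in pretrain_facts for s, o in pairs),
                count=len(pairs), dtype=bool,
            )
        pool = pairs[below_all]
        n_neg = int(round(spec.no_interaction_ratio * len(triples)))
        if n_neg > len(pool):
            raise ValueError(
                f"task {spec.name}: negative pool too small ({len(pool)} < {n_neg})"
            )
        neg = pool[rng.choice(len(pool), size=n_neg, replace=False)] if n_neg else (
            np.empty((0, 2), dtype=np.int64)
        )
        kg = KnowledgeGraph(entities, list(spec.relation_labels), triples)
        out.append(GeneratedTask(spec, kg, neg, factors, thresholds))
    return out


# ---------------------------------------------------------------------------


def summarize(kg: KnowledgeGraph) -> dict:
    """JSON-ready report of relation frequencies and degree statistics."""
    from kgelp.data import relation_stats

    stats = relation_stats(kg)
    counts = {kg.relations[r]: c for r, c in stats.counts.items()}
    vals = np.array(list(counts.values()), dtype=float)
    return {
        "n_entities": kg.n_entities,
        "n_relations": kg.n_relations,
        "n_triples": int(len(kg.triples)),
        "relation_counts": counts,
        "mean_out_degree": {kg.relations[r]: v for r, v in stats.mean_out_degree.items()},
        "mean_in_degree": {kg.relations[r]: v for r, v in stats.mean_in_degree.items()},
        "log10_count_range": float(np.log10(vals.max() / vals.min())),
    }
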