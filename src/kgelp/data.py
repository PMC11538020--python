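"""Multi-relational knowledge-graph containers and I/O.

A knowledge graph is a set of (subject, predicate, object) facts over dense
integer entity/relation vocabularies.  Triples travel as an ``(N, 3)`` int64
array throughout the package.  Symmetric relations such as drug-drug
interaction (DDI) and protein-protein interaction (PPI) are undirected facts;
:func:`add_reverses` makes both orientations explicit, which is only lawful
for relations whose subject and object entity classes coincide.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "KnowledgeGraph",
    "RelationSchema",
    "SplitKG",
    "RelationStats",
    "read_triples",
    "write_triples",
    "add_reverses",
    "split",
    "relation_stats",
]


@dataclass(frozen=True)
class RelationSchema:
    """Subject/object entity classes and symmetry flag for one relation."""

    subject_class: str
    object_class: str
    symmetric: bool = False


class KnowledgeGraph:
    """Integer-indexed triples plus bidirectional label vocabularies.

    Parameters
    ----------
    entities, relations:
        Label lists; index = position (dense, 0-based).
    triples:
        ``(N, 3)`` integer array of (subject, predicate, object) rows.
        Duplicate rows are collapsed (a warning records the count).
    schema:
        Optional map relation label -> :class:`RelationSchema`.
    entity_classes:
        Optional map entity label -> entity class name, required for schema
        validation and class-restricted sampling.
    """

    def __init__(
        self,
        entities: list[str],
        relations: list[str],
        triples: np.ndarray,
        schema: dict[str, RelationSchema] | None = None,
        entity_classes: dict[str, str] | None = None,
    ) -> None:
        self.entities = list(entities)
        self.relations = list(relations)
        self.entity_index = {e: i for i, e in enumerate(self.entities)}
        self.relation_index = {r: i for i, r in enumerate(self.relations)}
        if len(self.entity_index) != len(self.entities):
            raise ValueError("duplicate entity labels")
        if len(self.relation_index) != len(self.relations):
            raise ValueError("duplicate relation labels")

        triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
        uniq = np.unique(triples, axis=0) if len(triples) else triples
        self.duplicates_dropped = len(triples) - len(uniq)
        if self.duplicates_dropped:
            logger.warning("dropped %d duplicate triples", self.duplicates_dropped)
        self.triples = uniq
        self.schema = schema
        self.entity_classes = entity_classes
        self._validate()

    # -- basic protocol ----------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def __len__(self) -> int:
        return len(self.triples)

    def triple_set(self) -> set[tuple[int, int, int]]:
        return set(map(tuple, self.triples.tolist()))

    def _validate(self) -> None:
        t = self.triples
        if len(t):
            if t.min() < 0:
                raise ValueError("negative index in triples")
            if t[:, [0, 2]].max() >= self.n_entities:
                raise ValueError("entity index out of range")
            if t[:, 1].max() >= self.n_relations:
                raise ValueError("relation index out of range")
        if self.schema is not None and self.entity_classes is not None:
            classes = np.array(
                [self.entity_classes[e] for e in self.entities], dtype=object
            )
            for r, rs in self.schema.items():
                rows = t[t[:, 1] == self.relation_index[r]]
                if len(rows) == 0:
                    continue
                if not (classes[rows[:, 0]] == rs.subject_class).all():
                    raise ValueError(f"relation {r}: subject class violation")
                if not (classes[rows[:, 2]] == rs.object_class).all():
                    raise ValueError(f"relation {r}: object class violation")

    def replace_triples(self, triples: np.ndarray) -> "KnowledgeGraph":
        """New graph over the same vocabularies with a different triple set."""
        return KnowledgeGraph(
            self.entities, self.relations, triples, self.schema, self.entity_classes
        )


@dataclass
class SplitKG:
    """Disjoint train/valid/test partitions plus the known-true filter set.

    ``filter_set`` holds every triple known to be true (union of the three
    partitions, including any reverse-augmented training triples) and is the
    set consulted by filtered rank evaluation.
    """

    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    n_entities: int
    n_relations: int
    filter_set: set[tuple[int, int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.filter_set:
            self.filter_set = (
                set(map(tuple, self.train.tolist()))
                | set(map(tuple, self.valid.tolist()))
                | set(map(tuple, self.test.tolist()))
            )

    def with_train_reverses(self, kg: KnowledgeGraph, relations: set[int]) -> "SplitKG":
        """Add reverse orientations of symmetric relations to *train* only.

        Reverses of validation/test triples are deliberately not added to
        training: for a symmetric relation the reverse of a held-out fact is
        the same fact, and training on it would leak the label.  For the
        same reason an added reverse that coincides with a held-out triple
        (possible when the source KG stores both orientations) is dropped.
        """
        _check_same_class(kg, relations)
        extra = _reversed_rows(self.train, relations)
        held_out = set(map(tuple, self.valid.tolist())) | set(
            map(tuple, self.test.tolist())
        )
        if len(extra):
            keep = np.fromiter(
                (tuple(t) not in held_out for t in extra.tolist()),
                count=len(extra), dtype=bool,
            )
            extra = extra[keep]
        train = np.unique(np.vstack([self.train, extra]), axis=0)
        return SplitKG(
            train,
            self.valid,
            self.test,
            self.n_entities,
            self.n_relations,
            filter_set=set(map(tuple, train.tolist()))
            | set(map(tuple, self.valid.tolist()))
            | set(map(tuple, self.test.tolist())),
        )


@dataclass
class RelationStats:
    counts: dict[int, int]
    mean_out_degree: dict[int, float]
    mean_in_degree: dict[int, float]

    @property
    def total(self) -> int:
        return sum(self.counts.values())


# ---------------------------------------------------------------------------
# I/O: UTF-8 TSV, one "subject<TAB>predicate<TAB>object" per line.


def read_triples(path, dialect: str = "label-tsv") -> KnowledgeGraph:
    """Read a triple TSV into a :class:`KnowledgeGraph`.

    ``label-tsv`` builds vocabularies in first-appearance order of the file;
    ``index-tsv`` expects integer fields and synthesizes ``e{i}`` / ``r{i}``
    labels.  Blank lines are ignored; duplicate lines collapse with a logged
    count (exposed as ``kg.duplicates_dropped``).
    """
    if dialect not in ("label-tsv", "index-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    rows: list[tuple[str, str, str]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected 3 tab-separated fields, "
                    f"got {len(parts)}"
                )
            rows.append(tuple(parts))
    if not rows:
        raise ValueError(f"{path}: no triples")

    if dialect == "index-tsv":
        arr = np.array([[int(a), int(b), int(c)] for a, b, c in rows], dtype=np.int64)
        entities = [f"e{i}" for i in range(int(arr[:, [0, 2]].max()) + 1)]
        relations = [f"r{i}" for i in range(int(arr[:, 1].max()) + 1)]
        return KnowledgeGraph(entities, relations, arr)

    entities: list[str] = []
    relations: list[str] = []
    eidx: dict[str, int] = {}
    ridx: dict[str, int] = {}
    trip = np.empty((len(rows), 3), dtype=np.int64)
    for i, (s, p, o) in enumerate(rows):
        for lab in (s, o):
            if lab not in eidx:
                eidx[lab] = len(entities)
                entities.append(lab)
        if p not in ridx:
            ridx[p] = len(relations)
            relations.append(p)
        trip[i] = (eidx[s], ridx[p], eidx[o])
    return KnowledgeGraph(entities, relations, trip)


def write_triples(kg: KnowledgeGraph, path, dialect: str = "label-tsv") -> None:
    """Write triples sorted by (predicate, subject, object) — deterministic."""
    if dialect not in ("label-tsv", "index-tsv"):
        raise ValueError(f"unknown dialect {dialect!r}")
    t = kg.triples
    order = np.lexsort((t[:, 2], t[:, 0], t[:, 1])) if len(t) else []
    with open(path, "w", encoding="utf-8") as fh:
        for s, p, o in t[order]:
            if dialect == "label-tsv":
                fh.write(f"{kg.entities[s]}\t{kg.relations[p]}\t{kg.entities[o]}\n")
            else:
                fh.write(f"{s}\t{p}\t{o}\n")


def write_vocab(kg: KnowledgeGraph, entity_path, relation_path) -> None:
    """Sidecar vocabularies: lines of "index<TAB>label"."""
    with open(entity_path, "w", encoding="utf-8") as fh:
        for i, e in enumerate(kg.entities):
            fh.write(f"{i}\t{e}\n")
    with open(relation_path, "w", encoding="utf-8") as fh:
        for i, r in enumerate(kg.relations):
            fh.write(f"{i}\t{r}\n")


# ---------------------------------------------------------------------------


def _check_same_class(kg: KnowledgeGraph, relations: set[int]) -> None:
    if kg.schema is None:
        return
    for r in relations:
        rs = kg.schema.get(kg.relations[r])
        if rs is not None and rs.subject_class != rs.object_class:
            raise ValueError(
                f"relation {kg.relations[r]!r} joins distinct classes "
                f"({rs.subject_class} -> {rs.object_class}); reverses are only "
                "meaningful for same-class relations"
            )


def _reversed_rows(triples: np.ndarray, relations: set[int]) -> np.ndarray:
    mask = np.isin(triples[:, 1], list(relations))
    rev = triples[mask][:, [2, 1, 0]]
    return rev


def add_reverses(kg: KnowledgeGraph, relations: set[int]) -> KnowledgeGraph:
    """Make symmetric relations explicit: add (o, r, s) for each (s, r, o).

    Only same-class relations (DDI/PPI analogues) are accepted; the result is
    deduplicated, so the operation is idempotent.
    """
    _check_same_class(kg, relations)
    rev = _reversed_rows(kg.triples, relations)
    return kg.replace_triples(np.vstack([kg.triples, rev]))


def split(
    kg: KnowledgeGraph, ratios: tuple[float, float, float], seed: int
) -> SplitKG:
    """Seeded shuffle-and-partition into train/valid/test.

    Train gets ``floor(N * r_train)`` triples, valid ``floor(N * r_valid)``,
    test the remainder, matching the conventional 80/10/10 protocol.
    """
    r_train, r_valid, r_test = ratios
    if min(ratios) <= 0 or abs(sum(ratios) - 1.0) > 1e-9:
        raise ValueError("ratios must be positive and sum to 1")
    n = len(kg.triples)
    n_train = int(np.floor(n * r_train))
    n_valid = int(np.floor(n * r_valid))
    n_test = n - n_train - n_valid
    if min(n_train, n_valid, n_test) == 0:
        raise ValueError("empty split partition; evaluation undefined")
    perm = np.random.default_rng(seed).permutation(n)
    t = kg.triples[perm]
    return SplitKG(
        t[:n_train],
        t[n_train : n_train + n_valid],
        t[n_train + n_valid :],
        kg.n_entities,
        kg.n_relations,
    )


def relation_stats(kg: KnowledgeGraph) -> RelationStats:
    """Per-relation triple counts and mean in/out-degrees.

    Mean out-degree of relation r = #triples(r) / #distinct subjects(r);
    mean in-degree = #triples(r) / #distinct objects(r).
    """
    if len(kg.triples) == 0:
        raise ValueError("empty knowledge graph")
    counts: dict[int, int] = {}
    out_deg: dict[int, float] = {}
    in_deg: dict[int, float] = {}
    for r in np.unique(kg.triples[:, 1]):
        rows = kg.triples[kg.triples[:, 1] == r]
        counts[int(r)] = len(rows)
        out_deg[int(r)] = len(rows) / len(np.unique(rows[:, 0]))
        in_deg[int(r)] = len(rows) / len(np.unique(rows[:, 2]))
    return RelationStats(counts, out_deg, in_deg)
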