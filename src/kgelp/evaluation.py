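"""Filtered rank-based link-prediction evaluation: MRR and HITS@k.

For each test triple (s, p, o) the scorer ranks every entity as a
completion of (s, p, _) and of (_, p, o).  Candidates that would form a
*different* known-true triple (any member of the filter set) are removed
before ranking, so facts the model correctly considers plausible cannot
unfairly outrank the target.  The target itself is always kept.

Ties are resolved by the mean rank of the tied block by default, which
makes a constant scorer earn exactly its analytic expected rank (N+1)/2
rather than an inflated optimistic rank; ``optimistic`` and
``pessimistic`` policies are available for diagnosis.

Any object exposing ``score_all_objects(s, p)`` and
``score_all_subjects(p, o)`` (an embedding model, the rule-based
predictor, the planted-ground-truth oracle) can be evaluated — the
evaluation is scorer-agnostic.
"""

from __future__ import annotations

import difflib
import json
from dataclasses import dataclass

import numpy as np

__all__ = ["FilterIndex", "filtered_rank", "evaluate", "rank_query", "MetricReport"]

_TIE_POLICIES = ("mean", "optimistic", "pessimistic")


class FilterIndex:
    """Known-true triples indexed by (s, p) -> objects and (p, o) -> subjects."""

    def __init__(self, filter_set: set[tuple[int, int, int]]):
        self.sp: dict[tuple[int, int], list[int]] = {}
        self.po: dict[tuple[int, int], list[int]] = {}
        for s, p, o in filter_set:
            self.sp.setdefault((s, p), []).append(o)
            self.po.setdefault((p, o), []).append(s)

    def true_objects(self, s: int, p: int) -> list[int]:
        return self.sp.get((s, p), [])

    def true_subjects(self, p: int, o: int) -> list[int]:
        return self.po.get((p, o), [])


def _rank_from_scores(
    scores: np.ndarray, true_idx: int, filtered: np.ndarray, tie: str
) -> tuple[float, int]:
    """Rank of ``true_idx`` among unfiltered candidates by descending score.

    Returns (rank, number of candidates remaining after filtering).
    """
    s_true = scores[true_idx]
    keep = np.ones(len(scores), dtype=bool)
    keep[filtered] = False
    keep[true_idx] = True
    cand = scores[keep]
    greater = int((cand > s_true).sum())
    ties = int((cand == s_true).sum()) - 1  # excluding the target itself
    if tie == "mean":
        rank = greater + 1 + ties / 2.0
    elif tie == "optimistic":
        rank = greater + 1
    elif tie == "pessimistic":
        rank = greater + 1 + ties
    else:
        raise ValueError(f"tie policy must be one of {_TIE_POLICIES}")
    return float(rank), int(keep.sum())


def filtered_rank(
    scorer,
    triple: tuple[int, int, int],
    direction: str,
    filter_set: set | FilterIndex,
    tie: str = "mean",
) -> float:
    """Filtered rank of one triple's completion in the given direction."""
    index = filter_set if isinstance(filter_set, FilterIndex) else FilterIndex(filter_set)
    s, p, o = triple
    if direction == "tail":
        scores = np.asarray(scorer.score_all_objects(s, p), dtype=float)
        filtered = np.array(index.true_objects(s, p), dtype=np.int64)
        true_idx = o
    elif direction == "head":
        scores = np.asarray(scorer.score_all_subjects(p, o), dtype=float)
        filtered = np.array(index.true_subjects(p, o), dtype=np.int64)
        true_idx = s
    else:
        raise ValueError("direction must be 'head' or 'tail'")
    rank, _ = _rank_from_scores(scores, true_idx, filtered, tie)
    return rank


@dataclass
class MetricReport:
    mrr: float
    hits: dict[int, float]
    n_test: int
    per_direction: dict[str, dict[str, float]]

    def to_json(self) -> str:
        payload = {
            "mrr": self.mrr,
            **{f"hits@{k}": v for k, v in self.hits.items()},
            "n_test": self.n_test,
            "per_direction": self.per_direction,
        }
        return json.dumps(payload, indent=2)


def evaluate(
    scorer,
    test_triples: np.ndarray,
    filter_set: set | FilterIndex,
    ks: tuple[int, ...] = (1, 3, 10),
    tie: str = "mean",
    batch_size: int = 256,
) -> MetricReport:
    """Both-direction filtered evaluation over a test set.

    MRR pools all (triple, direction) pairs: with n test triples the mean
    reciprocal rank runs over 2n ranked queries.
    """
    test_triples = np.asarray(test_triples, dtype=np.int64).reshape(-1, 3)
    if len(test_triples) == 0:
        raise ValueError("empty test set")
    if tie not in _TIE_POLICIES:
        raise ValueError(f"tie policy must be one of {_TIE_POLICIES}")
    index = filter_set if isinstance(filter_set, FilterIndex) else FilterIndex(filter_set)

    ranks = {"tail": [], "head": []}
    for start in range(0, len(test_triples), batch_size):
        chunk = test_triples[start : start + batch_size]
        s, p, o = chunk[:, 0], chunk[:, 1], chunk[:, 2]
        tail_scores = np.asarray(scorer.score_all_objects(s, p), dtype=float)
        head_scores = np.asarray(scorer.score_all_subjects(p, o), dtype=float)
        for b in range(len(chunk)):
            filt = np.array(index.true_objects(s[b], p[b]), dtype=np.int64)
            r, _ = _rank_from_scores(tail_scores[b], o[b], filt, tie)
            ranks["tail"].append(r)
            filt = np.array(index.true_subjects(p[b], o[b]), dtype=np.int64)
            r, _ = _rank_from_scores(head_scores[b], s[b], filt, tie)
            ranks["head"].append(r)

    all_ranks = np.array(ranks["tail"] + ranks["head"])
    per_direction = {}
    for direction in ("tail", "head"):
        rr = np.array(ranks[direction])
        per_direction[direction] = {
            "mrr": float((1.0 / rr).mean()),
            **{f"hits@{k}": float((rr <= k).mean()) for k in ks},
        }
    return MetricReport(
        mrr=float((1.0 / all_ranks).mean()),
        hits={k: float((all_ranks <= k).mean()) for k in ks},
        n_test=len(test_triples),
        per_direction=per_direction,
    )


def rank_query(scorer, kg, subject: str | int, relation: str | int, top_n: int):
    """Top-n completions of (s, p, _) with labels and scores, unfiltered.

    Unknown labels raise with the nearest vocabulary matches, the
    drug-repurposing "fill in the blank" entry point.
    """

    def resolve(label, index, kind):
        if isinstance(label, (int, np.integer)):
            return int(label)
        if label not in index:
            near = difflib.get_close_matches(label, index, n=3)
            raise KeyError(f"unknown {kind} {label!r}; nearest: {near}")
        return index[label]

    s = resolve(subject, kg.entity_index, "entity")
    p = resolve(relation, kg.relation_index, "relation")
    scores = np.asarray(scorer.score_all_objects(s, p), dtype=float)
    order = np.argsort(-scores, kind="stable")[:top_n]
    return [(kg.entities[i], float(scores[i])) for i in order]
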