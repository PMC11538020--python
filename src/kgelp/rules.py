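"""Bottom-up rule learning: sample ground paths, generalize, score, predict.

The learner mines chain rules of the form

    body_1 ^ ... ^ body_L  ->  head

where each atom is r(term, term) and terms are either variables (X, Y,
A0, A1, ...) or entity constants.  Mining proceeds bottom-up: sample a
ground path (a connected sequence of facts) from the training KG, take
the first fact as the head and the remainder as the body, then enumerate
the lawful ways of replacing constants by variables.  Each candidate is
scored on the training KG:

    occurrences     = number of distinct head-argument groundings for
                      which the body is satisfiable,
    co-occurrences  = those groundings whose head fact is in the KG,
    confidence      = co-occurrences / occurrences.

A rule with 150 co-occurrences over 238 occurrences therefore carries a
confidence of 63%.  Rules below the support or confidence threshold are
dropped.  Prediction aggregates firing rules by maximum confidence and
every prediction carries the rules that produced it — the explanation.

Constants are only allowed in the head and the body atom adjacent to it;
deeper body atoms are fully variabilized, which bounds the enumeration
while still covering head-constant rules such as
(X, DrDiA, D013610) -> (X, DrDiA, D007022).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from kgelp.data import KnowledgeGraph

__all__ = [
    "Atom",
    "Rule",
    "RuleBase",
    "KGIndex",
    "sample_ground_path",
    "generalize",
    "score_rule",
    "mine",
    "predict",
    "RulePredictor",
]

# Terms: non-negative ints are entity constants, negative ints are
# variables (-1 = X, -2 = Y, -3 = A0, ...).
Term = int


def is_var(t: Term) -> bool:
    return t < 0


def term_str(t: Term, kg: KnowledgeGraph | None = None) -> str:
    if is_var(t):
        return {-1: "X", -2: "Y"}.get(t, f"A{-t - 3}")
    return kg.entities[t] if kg is not None else f"e{t}"


@dataclass(frozen=True)
class Atom:
    relation: int
    subject: Term
    object: Term

    def to_str(self, kg=None, relname=None) -> str:
        r = relname or (kg.relations[self.relation] if kg else f"r{self.relation}")
        return f"{r}({term_str(self.subject, kg)},{term_str(self.object, kg)})"


@dataclass
class Rule:
    head: Atom
    body: tuple[Atom, ...]
    occurrences: int = 0
    co_occurrences: int = 0

    @property
    def confidence(self) -> float:
        if self.occurrences == 0:
            raise ValueError("confidence undefined for zero occurrences")
        return self.co_occurrences / self.occurrences

    def canonical(self) -> tuple:
        """Syntactic identity up to variable renaming (order of appearance)."""
        mapping: dict[int, int] = {}

        def rename(t: Term) -> Term:
            if not is_var(t):
                return t
            if t not in mapping:
                mapping[t] = -(len(mapping) + 1)
            return mapping[t]

        atoms = [self.head, *self.body]
        return tuple((a.relation, rename(a.subject), rename(a.object)) for a in atoms)

    def to_str(self, kg=None) -> str:
        body = ";".join(a.to_str(kg) for a in self.body)
        return f"{self.head.to_str(kg)} <= {body}"


@dataclass
class RuleBase:
    """Retained rules indexed by head relation; no syntactic duplicates."""

    rules: list[Rule] = field(default_factory=list)
    by_head: dict[int, list[Rule]] = field(default_factory=dict)
    _seen: set = field(default_factory=set)

    def add(self, rule: Rule) -> bool:
        key = rule.canonical()
        if key in self._seen:
            return False
        self._seen.add(key)
        self.rules.append(rule)
        self.by_head.setdefault(rule.head.relation, []).append(rule)
        return True

    def __len__(self) -> int:
        return len(self.rules)

    def save(self, path, kg: KnowledgeGraph | None = None) -> None:
        """One rule per line: confidence, co-occurrences, occurrences,
        head, body atoms separated by ';'."""
        with open(path, "w", encoding="utf-8") as fh:
            for r in sorted(self.rules, key=lambda r: -r.confidence):
                body = ";".join(a.to_str(kg) for a in r.body)
                fh.write(
                    f"{r.confidence:.6f}\t{r.co_occurrences}\t{r.occurrences}\t"
                    f"{r.head.to_str(kg)}\t{body}\n"
                )


class KGIndex:
    """Adjacency indices over a triple array for grounding and walks."""

    def __init__(self, kg_or_triples, n_entities: int | None = None):
        if isinstance(kg_or_triples, KnowledgeGraph):
            triples = kg_or_triples.triples
            n_entities = kg_or_triples.n_entities
        else:
            triples = np.asarray(kg_or_triples, dtype=np.int64)
        self.triples = triples
        self.n_entities = n_entities
        self.triple_set = set(map(tuple, triples.tolist()))
        self.by_rel_s: dict[int, dict[int, list[int]]] = {}
        self.by_rel_o: dict[int, dict[int, list[int]]] = {}
        self.incident: dict[int, list[int]] = {}
        for i, (s, p, o) in enumerate(triples.tolist()):
            self.by_rel_s.setdefault(p, {}).setdefault(s, []).append(o)
            self.by_rel_o.setdefault(p, {}).setdefault(o, []).append(s)
            self.incident.setdefault(s, []).append(i)
            if o != s:
                self.incident.setdefault(o, []).append(i)

    def objects(self, p: int, s: int) -> list[int]:
        return self.by_rel_s.get(p, {}).get(s, [])

    def subjects(self, p: int, o: int) -> list[int]:
        return self.by_rel_o.get(p, {}).get(o, [])

    def sp_pairs(self, p: int):
        return self.by_rel_s.get(p, {})


def sample_ground_path(
    index: KGIndex, start: tuple[int, int, int], max_len: int, rng
) -> list[tuple[int, int, int]]:
    """Random connected fact sequence of at most ``max_len`` facts.

    The walk starts at a random endpoint of the start fact and repeatedly
    follows a random incident fact of the current frontier entity, so
    consecutive facts always share an entity; facts never repeat.  An
    isolated start fact yields a path of length 1.
    """
    path = [tuple(start)]
    used = {tuple(start)}
    frontier = int(rng.choice([start[0], start[2]]))
    while len(path) < max_len:
        candidates = index.incident.get(frontier, [])
        if not candidates:
            break
        order = rng.permutation(len(candidates))
        nxt = None
        for k in order:
            t = tuple(index.triples[candidates[k]].tolist())
            if t not in used:
                nxt = t
                break
        if nxt is None:
            break
        path.append(nxt)
        used.add(nxt)
        s, _, o = nxt
        frontier = o if s == frontier else s
    return path


def generalize(path: list[tuple[int, int, int]]) -> list[Rule]:
    """Candidate rules from a ground path: head = first fact, body = rest.

    Bodies are taken as every non-empty prefix of the remaining path (the
    chain is prefix-closed), and every subset of the involved entities may
    be lifted to variables, subject to: (i) constants appear only in the
    head or the body atom adjacent to it, (ii) each body atom connects to
    the atoms before it through a shared term, (iii) every head variable
    is bound by the body.  Paths shorter than two facts yield no rules (a
    rule needs a body).
    """
    if len(path) < 2:
        return []
    out: list[Rule] = []
    seen: set = set()
    for body_len in range(1, len(path)):
        out.extend(_generalize_fixed(path[0], path[1 : 1 + body_len], seen))
    return out


def _generalize_fixed(head_fact, body_facts, seen: set) -> list[Rule]:
    entities = []
    for s, _, o in [head_fact, *body_facts]:
        for e in (s, o):
            if e not in entities:
                entities.append(e)
    out: list[Rule] = []
    n = len(entities)
    for mask in range(1 << n):
        lifted = [e for b, e in enumerate(entities) if mask >> b & 1]
        varmap = {e: -(k + 1) for k, e in enumerate(lifted)}

        def lift(e: int) -> Term:
            return varmap.get(e, e)

        head = Atom(head_fact[1], lift(head_fact[0]), lift(head_fact[2]))
        body = tuple(Atom(p, lift(s), lift(o)) for s, p, o in body_facts)
        # constants only in head and the adjacent body atom
        if any(
            not is_var(t)
            for a in body[1:]
            for t in (a.subject, a.object)
        ):
            continue
        # connectivity: each body atom shares a term with what precedes it
        terms_so_far = {head.subject, head.object}
        connected = True
        for a in body:
            if a.subject not in terms_so_far and a.object not in terms_so_far:
                connected = False
                break
            terms_so_far |= {a.subject, a.object}
        if not connected:
            continue
        # safety: head variables must occur in the body
        body_terms = {t for a in body for t in (a.subject, a.object)}
        if any(is_var(t) and t not in body_terms for t in (head.subject, head.object)):
            continue
        rule = Rule(head, body)
        key = rule.canonical()
        if key not in seen:
            seen.add(key)
            out.append(rule)
    return out


def _groundings(index: KGIndex, atoms: list[Atom], binding: dict[int, int]):
    """Depth-first enumeration of variable bindings satisfying the atoms."""
    if not atoms:
        yield binding
        return
    atom, rest = atoms[0], atoms[1:]
    s = binding.get(atom.subject, atom.subject) if is_var(atom.subject) else atom.subject
    o = binding.get(atom.object, atom.object) if is_var(atom.object) else atom.object
    s_bound = not is_var(atom.subject) or atom.subject in binding
    o_bound = not is_var(atom.object) or atom.object in binding
    if s_bound and o_bound:
        if (s, atom.relation, o) in index.triple_set:
            yield from _groundings(index, rest, binding)
    elif s_bound:
        for obj in index.objects(atom.relation, s):
            nb = dict(binding)
            nb[atom.object] = obj
            yield from _groundings(index, rest, nb)
    elif o_bound:
        for sub in index.subjects(atom.relation, o):
            nb = dict(binding)
            nb[atom.subject] = sub
            yield from _groundings(index, rest, nb)
    else:
        same_var = atom.subject == atom.object  # r(X, X): reflexive only
        for sub, objs in index.sp_pairs(atom.relation).items():
            for obj in objs:
                if same_var and sub != obj:
                    continue
                nb = dict(binding)
                nb[atom.subject] = sub
                nb[atom.object] = obj
                yield from _groundings(index, rest, nb)


def score_rule(rule: Rule, index: KGIndex) -> tuple[int, int, float]:
    """Exact (occurrences, co-occurrences, confidence) by grounding.

    Occurrences count distinct head-argument instantiations whose body is
    satisfiable; rules whose body never grounds are rejected upstream
    (confidence undefined at zero occurrences).
    """
    head_vars = [t for t in (rule.head.subject, rule.head.object) if is_var(t)]
    seen_occ: set = set()
    seen_co: set = set()
    for binding in _groundings(index, list(rule.body), {}):
        key = tuple(binding.get(v) for v in head_vars)
        if None in key:
            continue  # unbound head var in this grounding branch
        if key in seen_occ:
            continue
        seen_occ.add(key)
        s = binding.get(rule.head.subject, rule.head.subject)
        o = binding.get(rule.head.object, rule.head.object)
        if (s, rule.head.relation, o) in index.triple_set:
            seen_co.add(key)
    occ, co = len(seen_occ), len(seen_co)
    conf = co / occ if occ else float("nan")
    return occ, co, conf


def mine(
    kg: KnowledgeGraph | np.ndarray,
    budget: int,
    max_len: int = 3,
    min_confidence: float = 0.1,
    min_support: int = 2,
    seed: int = 0,
    n_entities: int | None = None,
) -> RuleBase:
    """Repeat sample -> generalize -> score for ``budget`` iterations.

    ``max_len`` bounds the rule length (body atoms).  Thresholds follow
    the convention that values below 1 are confidence cutoffs and integer
    values >= 1 are minimum support (occurrence) counts.  Deterministic
    given the seed; the budget is an iteration count, not wall-clock.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    index = KGIndex(kg, n_entities)
    rng = np.random.default_rng(seed)
    base = RuleBase()
    scored: dict[tuple, tuple[int, int, float]] = {}
    n = len(index.triples)
    if n == 0:
        return base
    for _ in range(budget):
        start = index.triples[int(rng.integers(0, n))]
        path = sample_ground_path(index, tuple(start), max_len + 1, rng)
        for rule in generalize(path):
            key = rule.canonical()
            if key in scored:
                occ, co, conf = scored[key]
            else:
                occ, co, conf = score_rule(rule, index)
                scored[key] = (occ, co, conf)
            if occ == 0:
                continue
            if occ >= min_support and conf >= min_confidence:
                rule.occurrences, rule.co_occurrences = occ, co
                base.add(rule)
    return base


def predict(
    rulebase: RuleBase,
    query: tuple,
    index: KGIndex,
    filter_set: set | None = None,
) -> list[tuple[int, float, list[Rule]]]:
    """Ranked candidates for (s, p, None) or (None, p, o) with explanations.

    Candidate score = maximum confidence over firing rules; ties break by
    the sorted tail of firing confidences, then entity index.  Candidates
    forming known-true triples (other than themselves) are removed when a
    filter set is given.  Every reported rule actually grounds to its
    candidate.
    """
    s, p, o = query
    direction = "tail" if o is None else "head"
    fired: dict[int, list[Rule]] = {}
    for rule in rulebase.by_head.get(p, []):
        known = s if direction == "tail" else o
        known_term = rule.head.subject if direction == "tail" else rule.head.object
        pred_term = rule.head.object if direction == "tail" else rule.head.subject
        binding: dict[int, int] = {}
        if is_var(known_term):
            binding[known_term] = known
        elif known_term != known:
            continue
        for g in _groundings(index, list(rule.body), binding):
            cand = g.get(pred_term, pred_term)
            if is_var(cand):
                continue
            lst = fired.setdefault(int(cand), [])
            if rule not in lst:
                lst.append(rule)
    results = []
    for cand, rules in fired.items():
        if filter_set is not None:
            t = (s, p, cand) if direction == "tail" else (cand, p, o)
            if t in filter_set:
                continue  # already known true; predictions target new facts
        confs = sorted((r.confidence for r in rules), reverse=True)
        results.append((cand, confs, rules))
    results.sort(key=lambda x: (tuple(-c for c in x[1]), x[0]))
    return [(c, confs[0], rules) for c, confs, rules in results]


class RulePredictor:
    """Scorer-contract adapter: plugs a rule base into filtered evaluation.

    Entity scores are the maximum confidence of any firing rule (0 when no
    rule fires), so the evaluation module runs unmodified over rules.
    """

    def __init__(self, rulebase: RuleBase, index: KGIndex, n_entities: int):
        self.rulebase = rulebase
        self.index = index
        self.n_entities = n_entities

    def _scores(self, query) -> np.ndarray:
        out = np.zeros(self.n_entities)
        for cand, conf, _ in predict(self.rulebase, query, self.index):
            out[cand] = conf
        return out

    def score_all_objects(self, s, p):
        if np.isscalar(s):
            return self._scores((int(s), int(p), None))
        return np.stack([self._scores((int(a), int(b), None)) for a, b in zip(s, p)])

    def score_all_subjects(self, p, o):
        if np.isscalar(o):
            return self._scores((None, int(p), int(o)))
        return np.stack([self._scores((None, int(a), int(b))) for a, b in zip(p, o)])
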