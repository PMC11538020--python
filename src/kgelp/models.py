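"""Knowledge-graph embedding models under one scoring contract.

Six scoring functions f(e_s, r_p, e_o), higher = more plausible:

======== ======== =======================================================
Model    Domain   Score
======== ======== =======================================================
TransE   R^d      -|| e_s + r_p - e_o ||
TransH   R^d      -|| (e_s - w_p'e_s w_p) + r_p - (e_o - w_p'e_o w_p) ||
RotatE   C^d      -|| e_s o r_p - e_o ||,  |r_p,i| = 1
DistMult R^d      <e_s, r_p, e_o>           (tri-linear dot product)
ComplEx  C^d      Re(<e_s, r_p, conj(e_o)>)
ConvE    R^d      g(vec(g([e_s; r_p] * w)) W) . e_o
======== ======== =======================================================

ComplEx conjugates the object embedding: without the conjugation the score
is symmetric in (s, o) and the model loses the ability to represent
antisymmetric relations, collapsing onto DistMult-like behaviour.

Every model exposes ``score``, ``score_all_objects`` and
``score_all_subjects`` plus batched forward/backward hooks used by the
trainer.  Gradients are hand-derived; the test suite checks them against
central finite differences.  Complex parameters carry gradients as complex
arrays (real part = d/d Re, imaginary part = d/d Im).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["ModelConfig", "EmbeddingModel", "init_model", "MODEL_NAMES"]

MODEL_NAMES = ("TransE", "TransH", "RotatE", "DistMult", "ComplEx", "ConvE")

_EPS = 1e-12  # guards distance gradients at zero


@dataclass
class ModelConfig:
    name: str
    dim: int = 32
    init_scale: float = 0.1
    norm: int = 2  # translational distance norm: 1 or 2
    seed: int = 0
    reciprocal: bool = False  # reciprocal-relation modelling for head queries
    conve_filters: int = 32
    conve_kernel: int = 3
    conve_height: int | None = None  # reshape height; width = dim // height

    def __post_init__(self) -> None:
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model {self.name!r}; choose from {MODEL_NAMES}")
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.norm not in (1, 2):
            raise ValueError("norm must be 1 or 2")


def _reshape_hw(dim: int, height: int | None) -> tuple[int, int]:
    if height is not None:
        if dim % height:
            raise ValueError(f"conve_height {height} does not divide dim {dim}")
        return height, dim // height
    best = None
    for h in range(2, int(np.sqrt(dim)) + 1):
        if dim % h == 0:
            best = h
    if best is None:
        raise ValueError(
            f"dim {dim} has no 2D reshape (prime); pick a composite embedding size"
        )
    return best, dim // best


class EmbeddingModel:
    """Base class: parameter container plus the uniform scoring contract."""

    def __init__(self, config: ModelConfig, n_entities: int, n_relations: int):
        self.config = config
        self.n_entities = n_entities
        self.n_relations = n_relations
        self.dim = config.dim
        self.params: dict[str, np.ndarray] = {}
        self._init_params(np.random.default_rng(config.seed))

    # -- subclass hooks ----------------------------------------------------
    def _init_params(self, rng: np.random.Generator) -> None:
        raise NotImplementedError

    def _forward(self, e: np.ndarray, p: np.ndarray, direction: str):
        """Score all candidate completions.

        direction 'tail': e are subjects, scores[b, i] = f(e_b, p_b, i).
        direction 'head': e are objects,  scores[b, i] = f(i, p_b, e_b).
        Returns (scores (B, Ne), cache for :meth:`_backward`).
        """
        raise NotImplementedError

    def _backward(self, cache, dscores: np.ndarray) -> dict[str, np.ndarray]:
        raise NotImplementedError

    def project_constraints(self) -> None:
        """Re-establish parameter invariants after an optimizer step."""

    # -- uniform contract --------------------------------------------------
    @property
    def name(self) -> str:
        return self.config.name

    def forward_all(self, e, p, direction: str):
        """Batched scores plus backward cache (training entry point)."""
        e = np.atleast_1d(np.asarray(e, dtype=np.int64))
        p = np.atleast_1d(np.asarray(p, dtype=np.int64))
        if direction == "head" and self.config.reciprocal:
            return self._forward(e, p + self.n_relations, "tail")
        return self._forward(e, p, direction)

    def score_all_batch(self, e, p, direction: str) -> np.ndarray:
        return self.forward_all(e, p, direction)[0]

    def score_all_objects(self, s, p) -> np.ndarray:
        """Scores of (s, p, i) for every entity i. Scalar args -> (Ne,)."""
        self._check_finite()
        out = self.score_all_batch(s, p, "tail")
        return out[0] if np.isscalar(s) else out

    def score_all_subjects(self, p, o) -> np.ndarray:
        """Scores of (i, p, o) for every entity i. Scalar args -> (Ne,)."""
        self._check_finite()
        out = self.score_all_batch(o, p, "head")
        return out[0] if np.isscalar(o) else out

    def score_triples(self, s, p, o) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=np.int64))
        p = np.atleast_1d(np.asarray(p, dtype=np.int64))
        o = np.atleast_1d(np.asarray(o, dtype=np.int64))
        return self._pointwise(s, p, o)[0]

    # -- pointwise scoring (negative-sampling objectives) ------------------
    def _pointwise(self, s, p, o):
        """(values (B,), cache) without scoring the full vocabulary.

        Base implementation gathers from the all-objects rows; models
        override it with direct per-triple computation.
        """
        scores, cache = self._forward(s, p, "tail")
        cols = np.arange(len(s)), o
        return scores[cols], ("gather", cache, cols, scores.shape)

    def _pointwise_backward(self, cache, dvals):
        kind = cache[0]
        if kind != "gather":
            raise NotImplementedError
        _, inner, cols, shape = cache
        dscores = np.zeros(shape)
        dscores[cols] = dvals
        return self._backward(inner, dscores)

    def score(self, s: int, p: int, o: int) -> float:
        self._check_finite()
        return float(self.score_triples([s], [p], [o])[0])

    def _check_finite(self) -> None:
        for name, table in self.params.items():
            flat = table.view(np.float64) if np.iscomplexobj(table) else table
            if not np.all(np.isfinite(flat)):
                raise FloatingPointError(
                    f"non-finite values in parameter table {name!r}"
                )

    # -- persistence -------------------------------------------------------
    def save(self, prefix: str) -> None:
        """Checkpoint as <prefix>.npz plus <prefix>.json manifest."""
        np.savez(str(prefix) + ".npz", **self.params)
        manifest = {
            "config": asdict(self.config),
            "n_entities": self.n_entities,
            "n_relations": self.n_relations,
        }
        with open(str(prefix) + ".json", "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=2)

    @classmethod
    def load(cls, prefix: str) -> "EmbeddingModel":
        with open(str(prefix) + ".json", encoding="utf-8") as fh:
            manifest = json.load(fh)
        config = ModelConfig(**manifest["config"])
        model = init_model(config, manifest["n_entities"], manifest["n_relations"])
        with np.load(str(prefix) + ".npz") as data:
            for k in model.params:
                model.params[k] = data[k]
        return model

    def copy(self) -> "EmbeddingModel":
        clone = init_model(self.config, self.n_entities, self.n_relations)
        clone.params = {k: v.copy() for k, v in self.params.items()}
        return clone

    @property
    def n_relation_rows(self) -> int:
        return self.n_relations * (2 if self.config.reciprocal else 1)


# ---------------------------------------------------------------------------
# Factorization models


class DistMult(EmbeddingModel):
    def _init_params(self, rng) -> None:
        s = self.config.init_scale
        self.params["entity"] = rng.uniform(-s, s, (self.n_entities, self.dim))
        self.params["relation"] = rng.uniform(-s, s, (self.n_relation_rows, self.dim))

    def _forward(self, e, p, direction):
        # <e_s, r, e_o> is symmetric in (s, o): both directions share code.
        E = self.params["entity"]
        t = E[e] * self.params["relation"][p]  # (B, d)
        return t @ E.T, (e, p, t)

    def _backward(self, cache, dscores):
        e, p, t = cache
        E, R = self.params["entity"], self.params["relation"]
        dE = dscores.T @ t  # all-candidate side
        dt = dscores @ E
        np.add.at(dE, e, dt * R[p])
        dR = np.zeros_like(R)
        np.add.at(dR, p, dt * E[e])
        return {"entity": dE, "relation": dR}

    def _pointwise(self, s, p, o):
        E, R = self.params["entity"], self.params["relation"]
        vals = (E[s] * R[p] * E[o]).sum(axis=1)
        return vals, (s, p, o)

    def _pointwise_backward(self, cache, dvals):
        s, p, o = cache
        E, R = self.params["entity"], self.params["relation"]
        w = dvals[:, None]
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        np.add.at(dE, s, w * R[p] * E[o])
        np.add.at(dR, p, w * E[s] * E[o])
        np.add.at(dE, o, w * E[s] * R[p])
        return {"entity": dE, "relation": dR}


class ComplEx(EmbeddingModel):
    """Re(<e_s, r_p, conj(e_o)>) with complex entity and relation tables.

    Head queries use the identity
    Re(<e_i, r, conj(e_o)>) = Re(<e_o, conj(r), conj(e_i)>),
    i.e. a tail query with subject e_o under the conjugated relation.
    """

    def _init_params(self, rng) -> None:
        s = self.config.init_scale
        se = (self.n_entities, self.dim)
        sr = (self.n_relation_rows, self.dim)
        self.params["entity"] = rng.uniform(-s, s, se) + 1j * rng.uniform(-s, s, se)
        self.params["relation"] = rng.uniform(-s, s, sr) + 1j * rng.uniform(-s, s, sr)

    def _forward(self, e, p, direction):
        E, R = self.params["entity"], self.params["relation"]
        r = R[p] if direction == "tail" else np.conj(R[p])
        t = E[e] * r  # scores[b, i] = Re(sum_k t_bk conj(E_ik))
        scores = t.real @ E.real.T + t.imag @ E.imag.T
        return scores, (e, p, t, direction)

    def _backward(self, cache, dscores):
        e, p, t, direction = cache
        E, R = self.params["entity"], self.params["relation"]
        dE = dscores.T @ t  # candidate carrier is t
        dt = dscores @ E  # carrier: t_re pairs with E_re, t_im with E_im
        dR = np.zeros_like(R)
        if direction == "tail":
            np.add.at(dE, e, dt * np.conj(R[p]))
            np.add.at(dR, p, dt * np.conj(E[e]))
        else:
            np.add.at(dE, e, dt * R[p])  # t = e o conj(r)
            np.add.at(dR, p, np.conj(dt * np.conj(E[e])))
        return {"entity": dE, "relation": dR}

    def _pointwise(self, s, p, o):
        E, R = self.params["entity"], self.params["relation"]
        vals = (E[s] * R[p] * np.conj(E[o])).real.sum(axis=1)
        return vals, (s, p, o)

    def _pointwise_backward(self, cache, dvals):
        # f = Re(<a, b, conj(c)>): carriers g_a = conj(b) o c,
        # g_b = conj(a) o c, g_c = a o b
        s, p, o = cache
        E, R = self.params["entity"], self.params["relation"]
        w = dvals[:, None]
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        np.add.at(dE, s, w * np.conj(R[p]) * E[o])
        np.add.at(dR, p, w * np.conj(E[s]) * E[o])
        np.add.at(dE, o, w * E[s] * R[p])
        return {"entity": dE, "relation": dR}


# ---------------------------------------------------------------------------
# Translational models


def _distance_scores(diff: np.ndarray, norm: int) -> np.ndarray:
    """-||diff|| along the last axis; complex arrays use the modulus."""
    if np.iscomplexobj(diff):
        sq = diff.real**2 + diff.imag**2
    else:
        sq = diff**2
    if norm == 2:
        return -np.sqrt(sq.sum(axis=-1))
    return -np.sqrt(sq).sum(axis=-1)


def _distance_dgrad(diff: np.ndarray, scores: np.ndarray, dscores, norm: int):
    """Carrier d(score)/d(diff), scaled by upstream dscores."""
    if norm == 2:
        return -dscores[..., None] * diff / (-scores + _EPS)[..., None]
    mod = np.sqrt(diff.real**2 + diff.imag**2) if np.iscomplexobj(diff) else np.abs(diff)
    return -dscores[..., None] * diff / (mod + _EPS)


def _pairwise_l2(t: np.ndarray, E: np.ndarray) -> np.ndarray:
    """dist[b, i] = ||t_b - E_i||_2 without forming the (B, Ne, d) tensor.

    Uses ||t||^2 - 2 t.e + ||e||^2 (GEMM); cancellation can leave tiny
    negative values, clipped at zero, so an exact coincidence scores an
    O(1e-8) distance instead of exactly 0.
    """
    if np.iscomplexobj(t):
        t2 = (t.real**2 + t.imag**2).sum(axis=1)
        e2 = (E.real**2 + E.imag**2).sum(axis=1)
        cross = t.real @ E.real.T + t.imag @ E.imag.T
    else:
        t2 = (t**2).sum(axis=1)
        e2 = (E**2).sum(axis=1)
        cross = t @ E.T
    sq = t2[:, None] - 2.0 * cross + e2[None, :]
    return np.sqrt(np.maximum(sq, 0.0))


def _pairwise_l2_backward(t, E, dist, dscores):
    """(dt, dE) for scores = -dist under upstream dscores.

    dt_b  = sum_i W_bi (E_i - t_b),  dE_i = sum_b W_bi (t_b - E_i),
    with W = dscores / dist — three GEMMs, symmetric in both directions.
    """
    W = dscores / (dist + _EPS)
    row = W.sum(axis=1)
    col = W.sum(axis=0)
    if np.iscomplexobj(t):
        dt = (W @ E.real + 1j * (W @ E.imag)) - row[:, None] * t
        dE = (W.T @ t.real + 1j * (W.T @ t.imag)) - col[:, None] * E
    else:
        dt = W @ E - row[:, None] * t
        dE = W.T @ t - col[:, None] * E
    return dt, dE


class TransE(EmbeddingModel):
    def _init_params(self, rng) -> None:
        s = self.config.init_scale
        self.params["entity"] = rng.uniform(-s, s, (self.n_entities, self.dim))
        self.params["relation"] = rng.uniform(-s, s, (self.n_relation_rows, self.dim))

    def _forward(self, e, p, direction):
        E, R = self.params["entity"], self.params["relation"]
        sign = 1.0 if direction == "tail" else -1.0
        # tail: ||e_s + r - e_i||; head: ||e_i + r - e_o|| = ||(e_o - r) - e_i||
        t = E[e] + sign * R[p]
        if self.config.norm == 2:
            aux = _pairwise_l2(t, E)
            return -aux, (e, p, t, aux, sign)
        diff = t[:, None, :] - E[None, :, :]
        scores = _distance_scores(diff, 1)
        return scores, (e, p, t, scores, sign)

    def _backward(self, cache, dscores):
        e, p, t, aux, sign = cache
        E, R = self.params["entity"], self.params["relation"]
        if self.config.norm == 2:
            dt, dE = _pairwise_l2_backward(t, E, aux, dscores)
        else:
            diff = t[:, None, :] - E[None, :, :]
            dD = _distance_dgrad(diff, aux, dscores, 1)
            dt = dD.sum(axis=1)
            dE = -dD.sum(axis=0)
        np.add.at(dE, e, dt)
        dR = np.zeros_like(R)
        np.add.at(dR, p, sign * dt)
        return {"entity": dE, "relation": dR}

    def _pointwise(self, s, p, o):
        E, R = self.params["entity"], self.params["relation"]
        diff = E[s] + R[p] - E[o]
        vals = _distance_scores(diff, self.config.norm)
        return vals, (s, p, o, diff, vals)

    def _pointwise_backward(self, cache, dvals):
        s, p, o, diff, vals = cache
        g_diff = _distance_dgrad(diff, vals, dvals, self.config.norm)
        E, R = self.params["entity"], self.params["relation"]
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        np.add.at(dE, s, g_diff)
        np.add.at(dR, p, g_diff)
        np.add.at(dE, o, -g_diff)
        return {"entity": dE, "relation": dR}


class RotatE(EmbeddingModel):
    """Complex entities, phase-only relations stored as angles theta.

    Parameterizing r = exp(i theta) keeps |r_p,i| = 1 exactly through every
    optimizer step — the unit-modulus invariant cannot drift.
    """

    def _init_params(self, rng) -> None:
        s = self.config.init_scale
        se = (self.n_entities, self.dim)
        self.params["entity"] = rng.uniform(-s, s, se) + 1j * rng.uniform(-s, s, se)
        self.params["phase"] = rng.uniform(
            -np.pi, np.pi, (self.n_relation_rows, self.dim)
        )

    @property
    def relation_embedding(self) -> np.ndarray:
        """Unit-modulus complex relation table exp(i theta)."""
        return np.exp(1j * self.params["phase"])

    def _forward(self, e, p, direction):
        E = self.params["entity"]
        r = np.exp(1j * self.params["phase"][p])
        # tail: ||e_s o r - e_i||; head: ||e_i o r - e_o|| = ||e_i - e_o o
        # conj(r)|| (rotation by a unit phase is an isometry)
        t = E[e] * (r if direction == "tail" else np.conj(r))
        if self.config.norm == 2:
            aux = _pairwise_l2(t, E)
            return -aux, (e, p, t, r, aux, direction)
        diff = t[:, None, :] - E[None, :, :]  # |.| is symmetric in the sign
        scores = _distance_scores(diff, 1)
        return scores, (e, p, t, r, scores, direction)

    def _backward(self, cache, dscores):
        e, p, t, r, aux, direction = cache
        E = self.params["entity"]
        if self.config.norm == 2:
            dt, dE = _pairwise_l2_backward(t, E, aux, dscores)
        else:
            diff = t[:, None, :] - E[None, :, :]
            dD = _distance_dgrad(diff, aux, dscores, 1)
            dt = dD.sum(axis=1)
            dE = -dD.sum(axis=0)
        if direction == "tail":
            g_e = dt * np.conj(r)  # t = e o r
            g_r = dt * np.conj(E[e])
        else:
            g_e = dt * r  # t = e o conj(r)
            g_r = np.conj(dt * np.conj(E[e]))
        np.add.at(dE, e, g_e)
        dTheta = np.zeros_like(self.params["phase"])
        # r = exp(i theta): df/dtheta = Im(conj(r) g_r)
        np.add.at(dTheta, p, (np.conj(r) * g_r).imag)
        return {"entity": dE, "phase": dTheta}

    def _pointwise(self, s, p, o):
        E = self.params["entity"]
        r = np.exp(1j * self.params["phase"][p])
        diff = E[s] * r - E[o]
        vals = _distance_scores(diff, self.config.norm)
        return vals, (s, p, o, r, diff, vals)

    def _pointwise_backward(self, cache, dvals):
        s, p, o, r, diff, vals = cache
        E = self.params["entity"]
        g_diff = _distance_dgrad(diff, vals, dvals, self.config.norm)
        dE = np.zeros_like(E)
        dTheta = np.zeros_like(self.params["phase"])
        np.add.at(dE, s, g_diff * np.conj(r))
        np.add.at(dE, o, -g_diff)
        g_r = g_diff * np.conj(E[s])
        np.add.at(dTheta, p, (np.conj(r) * g_r).imag)
        return {"entity": dE, "phase": dTheta}


class TransH(EmbeddingModel):
    """TransE on a relation-specific hyperplane with unit normal w_p."""

    def _init_params(self, rng) -> None:
        s = self.config.init_scale
        self.params["entity"] = rng.uniform(-s, s, (self.n_entities, self.dim))
        self.params["relation"] = rng.uniform(-s, s, (self.n_relation_rows, self.dim))
        w = rng.normal(size=(self.n_relation_rows, self.dim))
        self.params["normal"] = w / np.linalg.norm(w, axis=1, keepdims=True)

    def project_constraints(self) -> None:
        w = self.params["normal"]
        self.params["normal"] = w / np.linalg.norm(w, axis=1, keepdims=True)

    def _forward(self, e, p, direction):
        E, R, W = self.params["entity"], self.params["relation"], self.params["normal"]
        scores = np.empty((len(e), self.n_entities))
        caches = []
        sign = 1.0 if direction == "tail" else -1.0
        for rel in np.unique(p):
            rows = np.where(p == rel)[0]
            w = W[rel]
            Eproj = E - np.outer(E @ w, w)
            t = Eproj[e[rows]] + sign * R[rel]
            if self.config.norm == 2:
                aux = _pairwise_l2(t, Eproj)
                scores[rows] = -aux
            else:
                diff = t[:, None, :] - Eproj[None, :, :]
                aux = _distance_scores(diff, 1)
                scores[rows] = aux
            caches.append((int(rel), rows, t, aux))
        return scores, (e, p, sign, caches)

    def _backward(self, cache, dscores):
        e, p, sign, caches = cache
        E, R, W = self.params["entity"], self.params["relation"], self.params["normal"]
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        dW = np.zeros_like(W)

        def proj_backward(X, G, w, rel, scatter_idx=None):
            # P(x) = x - (w.x) w:  dX = G - (G.w) w ;
            # dw = -sum_n [ (G_n.w) X_n + (w.X_n) G_n ]
            Gw = G @ w
            dX = G - np.outer(Gw, w)
            dW[rel] += -(X.T @ Gw + G.T @ (X @ w))
            if scatter_idx is None:
                return dX
            np.add.at(dE, scatter_idx, dX)
            return None

        for rel, rows, t, aux in caches:
            w = W[rel]
            Eproj = E - np.outer(E @ w, w)
            if self.config.norm == 2:
                dt, dEproj = _pairwise_l2_backward(t, Eproj, aux, dscores[rows])
            else:
                diff = t[:, None, :] - Eproj[None, :, :]
                dD = _distance_dgrad(diff, aux, dscores[rows], 1)
                dt = dD.sum(axis=1)
                dEproj = -dD.sum(axis=0)
            dR[rel] += sign * dt.sum(axis=0)
            dE += proj_backward(E, dEproj, w, rel)  # candidate side, dense
            proj_backward(E[e[rows]], dt, w, rel, scatter_idx=e[rows])
        return {"entity": dE, "relation": dR, "normal": dW}

    def _pointwise(self, s, p, o):
        E, R, W = self.params["entity"], self.params["relation"], self.params["normal"]
        w = W[p]  # (B, d)
        sproj = E[s] - (E[s] * w).sum(1, keepdims=True) * w
        oproj = E[o] - (E[o] * w).sum(1, keepdims=True) * w
        diff = sproj + R[p] - oproj
        vals = _distance_scores(diff, self.config.norm)
        return vals, (s, p, o, diff, vals)

    def _pointwise_backward(self, cache, dvals):
        s, p, o, diff, vals = cache
        E, R, W = self.params["entity"], self.params["relation"], self.params["normal"]
        g_diff = _distance_dgrad(diff, vals, dvals, self.config.norm)
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        dW = np.zeros_like(W)
        np.add.at(dR, p, g_diff)
        w = W[p]
        for idx, g in ((s, g_diff), (o, -g_diff)):
            x = E[idx]
            gw = (g * w).sum(1, keepdims=True)
            xw = (x * w).sum(1, keepdims=True)
            np.add.at(dE, idx, g - gw * w)
            np.add.at(dW, p, -(gw * x + xw * g))
        return {"entity": dE, "relation": dR, "normal": dW}


# ---------------------------------------------------------------------------
# ConvE


class ConvE(EmbeddingModel):
    """2D-convolution scorer over the stacked [e_s; r_p] reshape.

    Canonical choices: vertical stack of the reshaped subject and relation
    embeddings, 3x3 filters, valid convolution, rectifier nonlinearity g,
    linear projection back to d, dot product with the object embedding.
    Head queries run every candidate subject through the network, sharing
    the per-relation feature table within a batch.
    """

    def _init_params(self, rng) -> None:
        c = self.config
        s = c.init_scale
        self.h, self.w = _reshape_hw(self.dim, c.conve_height)
        k = c.conve_kernel
        if 2 * self.h < k or self.w < k:
            raise ValueError(f"reshape ({self.h}x{self.w}) too small for {k}x{k} filters")
        self.out_h = 2 * self.h - k + 1
        self.out_w = self.w - k + 1
        n_flat = c.conve_filters * self.out_h * self.out_w
        self.params["entity"] = rng.uniform(-s, s, (self.n_entities, self.dim))
        self.params["relation"] = rng.uniform(-s, s, (self.n_relation_rows, self.dim))
        self.params["filters"] = rng.uniform(-s, s, (c.conve_filters, k * k))
        self.params["proj"] = rng.uniform(-s, s, (n_flat, self.dim)) / np.sqrt(n_flat)

    def _im2col(self, x: np.ndarray) -> np.ndarray:
        """(B, 2h, w) -> (B, out_h*out_w, k*k) patch matrix."""
        k = self.config.conve_kernel
        B = x.shape[0]
        cols = np.empty((B, self.out_h, self.out_w, k, k))
        for i in range(k):
            for j in range(k):
                cols[:, :, :, i, j] = x[:, i : i + self.out_h, j : j + self.out_w]
        return cols.reshape(B, self.out_h * self.out_w, k * k)

    def _col2im(self, dcols: np.ndarray) -> np.ndarray:
        k = self.config.conve_kernel
        B = dcols.shape[0]
        dc = dcols.reshape(B, self.out_h, self.out_w, k, k)
        dx = np.zeros((B, 2 * self.h, self.w))
        for i in range(k):
            for j in range(k):
                dx[:, i : i + self.out_h, j : j + self.out_w] += dc[:, :, :, i, j]
        return dx

    def _features(self, es: np.ndarray, rp: np.ndarray):
        """v = g(vec(g([e_s; r_p] * w)) W) for aligned embedding rows."""
        B = es.shape[0]
        x = np.concatenate(
            [es.reshape(B, self.h, self.w), rp.reshape(B, self.h, self.w)], axis=1
        )
        cols = self._im2col(x)
        z1 = cols @ self.params["filters"].T  # (B, P, F)
        a1 = np.maximum(z1, 0.0)
        flat = a1.reshape(B, -1)
        z2 = flat @ self.params["proj"]
        v = np.maximum(z2, 0.0)
        return v, (cols, z1, flat, z2)

    def _features_backward(self, fcache, dv: np.ndarray):
        cols, z1, flat, z2 = fcache
        B = dv.shape[0]
        dz2 = dv * (z2 > 0)
        dproj = flat.T @ dz2
        dflat = dz2 @ self.params["proj"].T
        dz1 = dflat.reshape(z1.shape) * (z1 > 0)
        dfilters = np.einsum("bpf,bpk->fk", dz1, cols)
        dx = self._col2im(dz1 @ self.params["filters"])
        des = dx[:, : self.h, :].reshape(B, self.dim)
        drp = dx[:, self.h :, :].reshape(B, self.dim)
        return des, drp, dfilters, dproj

    def _forward(self, e, p, direction):
        E, R = self.params["entity"], self.params["relation"]
        if direction == "tail":
            v, fcache = self._features(E[e], R[p])
            return v @ E.T, ("tail", e, p, v, fcache)
        # head: scores[b, i] = v(i, p_b) . e_{o_b}
        scores = np.empty((len(e), self.n_entities))
        per_rel = []
        for rel in np.unique(p):
            rows = np.where(p == rel)[0]
            V, fcache = self._features(E, np.broadcast_to(R[rel], E.shape))
            scores[rows] = E[e[rows]] @ V.T
            per_rel.append((int(rel), rows, V, fcache))
        return scores, ("head", e, p, per_rel)

    def _backward(self, cache, dscores):
        E, R = self.params["entity"], self.params["relation"]
        dE = np.zeros_like(E)
        dR = np.zeros_like(R)
        dF = np.zeros_like(self.params["filters"])
        dP = np.zeros_like(self.params["proj"])
        if cache[0] == "tail":
            _, e, p, v, fcache = cache
            dE += dscores.T @ v
            dv = dscores @ E
            des, drp, dfilters, dproj = self._features_backward(fcache, dv)
            np.add.at(dE, e, des)
            np.add.at(dR, p, drp)
            dF += dfilters
            dP += dproj
        else:
            _, e, p, per_rel = cache
            for rel, rows, V, fcache in per_rel:
                ds = dscores[rows]
                np.add.at(dE, e[rows], ds @ V)
                dV = ds.T @ E[e[rows]]  # (Ne, d)
                des, drp, dfilters, dproj = self._features_backward(fcache, dV)
                dE += des
                dR[rel] += drp.sum(axis=0)
                dF += dfilters
                dP += dproj
        return {"entity": dE, "relation": dR, "filters": dF, "proj": dP}


# ---------------------------------------------------------------------------

_REGISTRY = {
    "TransE": TransE,
    "TransH": TransH,
    "RotatE": RotatE,
    "DistMult": DistMult,
    "ComplEx": ComplEx,
    "ConvE": ConvE,
}


def init_model(config: ModelConfig, n_entities: int, n_relations: int) -> EmbeddingModel:
    """Build a seeded model; all type invariants hold at initialization."""
    return _REGISTRY[config.name](config, n_entities, n_relations)
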