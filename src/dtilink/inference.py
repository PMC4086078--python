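"""Supervised bipartite link prediction over drug and protein kernels.

Three algorithms are provided, each trained on a drug kernel ``Kd``
(n_d x n_d), a protein kernel ``Kp`` (n_p x n_p) and a partially known
0/1 interaction matrix ``Y`` (n_d x n_p); unknown pairs are treated as
negatives (label 0).

**Pairwise kernel regression (PKR)** — kernel ridge regression over
drug-protein *pairs* with the Kronecker product pair kernel
``K_pair((d,p),(d',p')) = Kd(d,d') * Kp(p,p')``.  The dual system
``(Kd (x) Kp + lambda I) a = vec(Y)`` is never materialized: with
eigendecompositions ``Kd = Ud Dd Ud^T`` and ``Kp = Up Dp Up^T`` the dual
coefficient matrix is

    C = Ud [ G o (Ud^T Y Up) ] Up^T,     G_ij = 1 / (Dd_i Dp_j + lambda)

and fitted scores are ``F = Kd C Kp``.  Cost is O(n_d^3 + n_p^3) plus
matrix products — this is why it is the default algorithm.

**Bipartite local model (BLM)** — one kernel ridge model per training
drug (features = protein kernel, labels = that drug's row of Y) and one
per training protein, symmetric; a pair's score combines the two local
predictions (mean by default).  A node with no known edges contributes no
local model; the pair falls back to the other side, and to 0 when neither
side is modeled (so BLM cannot score new-drug x new-protein pairs).

**Bipartite graph embedding (BGE)** — training nodes are embedded in a
low-dimensional "interaction space" from a PSD kernel built on the
bipartite adjacency; kernel ridge regression then maps input similarities
onto the embedding coordinates, and a pair's score is the inner product
of its mapped coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_tables import InteractionNetwork, KernelMatrix

__all__ = [
    "ModelParams",
    "TrainedModel",
    "ScoredEdges",
    "EdgeRecord",
    "fit",
    "fit_pkr",
    "predict_pkr",
    "fit_blm",
    "fit_bge",
    "score_all_pairs",
    "threshold_edges",
    "ALGORITHMS",
]

ALGORITHMS = ("pairwise_kernel_regression", "bipartite_local_model", "bipartite_graph_embedding")

_ALIASES = {
    "pkr": "pairwise_kernel_regression",
    "blm": "bipartite_local_model",
    "bge": "bipartite_graph_embedding",
}


@dataclass
class ModelParams:
    """Hyperparameters shared by the three algorithms.

    ridge — the regularization strength lambda of every kernel ridge
        solve (default 1.0).
    embed_dim — embedding dimension for the graph-embedding algorithm;
        ``None`` defaults to ``min(10, min(n_d, n_p) - 1)`` at fit time.
    blm_combine — how the two local-model scores are merged per pair.
    """

    algorithm: str = "pairwise_kernel_regression"
    ridge: float = 1.0
    embed_dim: int | None = None
    blm_combine: str = "mean"

    def __post_init__(self) -> None:
        self.algorithm = _ALIASES.get(self.algorithm, self.algorithm)
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")
        if self.ridge <= 0:
            raise ValueError(f"ridge (lambda) must be positive, got {self.ridge}")
        if self.embed_dim is not None and self.embed_dim < 1:
            raise ValueError("embed_dim must be >= 1")
        if self.blm_combine not in ("mean", "max"):
            raise ValueError("blm_combine must be 'mean' or 'max'")


@dataclass
class TrainedModel:
    """A fitted link-prediction model, sufficient to score any pair.

    ``arrays`` holds the algorithm-specific payload (dual coefficients,
    local-model duals, embedding regression maps) plus the retained
    training kernels; ``F`` is the fitted training score matrix, which the
    generic predict path reproduces when handed the training kernels.
    """

    params: ModelParams
    drug_ids: list[str]
    protein_ids: list[str]
    arrays: dict[str, np.ndarray]

    @property
    def F(self) -> np.ndarray:
        return self.arrays["F"]

    def predict(
        self,
        Kd_cross: np.ndarray,
        Kp_cross: np.ndarray,
        drug_train_idx: Sequence[int] | None = None,
        protein_train_idx: Sequence[int] | None = None,
    ) -> np.ndarray:
        """Score every (row of Kd_cross) x (row of Kp_cross) pair.

        Cross-kernel columns must be ordered as the training ids.  For the
        bipartite local model, ``drug_train_idx[i]`` gives the training
        index of query drug ``i`` (or -1 for a new drug) so the local model
        belonging to that drug can be used; PKR and BGE ignore these.
        """
        Kd_cross = np.atleast_2d(np.asarray(Kd_cross, dtype=float))
        Kp_cross = np.atleast_2d(np.asarray(Kp_cross, dtype=float))
        n_d, n_p = len(self.drug_ids), len(self.protein_ids)
        if Kd_cross.shape[1] != n_d:
            raise ValueError(
                f"Kd_cross has {Kd_cross.shape[1]} columns, expected {n_d} training drugs"
            )
        if Kp_cross.shape[1] != n_p:
            raise ValueError(
                f"Kp_cross has {Kp_cross.shape[1]} columns, expected {n_p} training proteins"
            )
        algo = self.params.algorithm
        if algo == "pairwise_kernel_regression":
            return predict_pkr(self, Kd_cross, Kp_cross)
        if algo == "bipartite_local_model":
            return _predict_blm(self, Kd_cross, Kp_cross, drug_train_idx, protein_train_idx)
        return _predict_bge(self, Kd_cross, Kp_cross)

    # ------------------------------------------------------------------
    # serialization: a single documented JSON file (arrays as nested lists)

    def save(self, path: str | Path) -> None:
        payload = {
            "format": "dtilink-model-v1",
            "algorithm": self.params.algorithm,
            "params": {
                "ridge": self.params.ridge,
                "embed_dim": self.params.embed_dim,
                "blm_combine": self.params.blm_combine,
            },
            "drug_ids": self.drug_ids,
            "protein_ids": self.protein_ids,
            "arrays": {k: v.tolist() for k, v in self.arrays.items()},
        }
        Path(path).write_text(json.dumps(payload), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        payload = json.loads(Path(path).read_text(encoding="utf-8"))
        if payload.get("format") != "dtilink-model-v1":
            raise ValueError(f"{path}: not a dtilink model file")
        params = ModelParams(algorithm=payload["algorithm"], **payload["params"])
        arrays = {k: np.asarray(v, dtype=float) for k, v in payload["arrays"].items()}
        return cls(params, payload["drug_ids"], payload["protein_ids"], arrays)


def _check_aligned(Kd: KernelMatrix, Kp: KernelMatrix, net: InteractionNetwork) -> None:
    if Kd.side != "drug" or Kp.side != "protein":
        raise ValueError("Kd must be a drug kernel and Kp a protein kernel")
    if Kd.object_ids != net.drug_ids:
        raise ValueError("drug kernel ids do not match interaction network drug ids")
    if Kp.object_ids != net.protein_ids:
        raise ValueError("protein kernel ids do not match interaction network protein ids")


# ---------------------------------------------------------------------------
# pairwise kernel regression


def fit_pkr(
    Kd: KernelMatrix, Kp: KernelMatrix, net: InteractionNetwork, params: ModelParams | None = None
) -> TrainedModel:
    """Fit pairwise kernel ridge regression with the product pair kernel."""
    params = params or ModelParams("pairwise_kernel_regression")
    if params.algorithm != "pairwise_kernel_regression":
        raise ValueError(f"fit_pkr called with algorithm {params.algorithm!r}")
    _check_aligned(Kd, Kp, net)
    lam = params.ridge
    dd, Ud = np.linalg.eigh(Kd.values)
    dp, Up = np.linalg.eigh(Kp.values)
    G = 1.0 / (np.outer(dd, dp) + lam)
    C = Ud @ (G * (Ud.T @ net.Y @ Up)) @ Up.T
    F = Kd.values @ C @ Kp.values
    return TrainedModel(
        params,
        list(net.drug_ids),
        list(net.protein_ids),
        {"C": C, "F": F, "Kd_train": Kd.values, "Kp_train": Kp.values},
    )


def predict_pkr(model: TrainedModel, Kd_cross: np.ndarray, Kp_cross: np.ndarray) -> np.ndarray:
    """Score new pairs: ``F_new = Kd_cross C Kp_cross^T``."""
    C = model.arrays["C"]
    if Kd_cross.shape[1] != C.shape[0] or Kp_cross.shape[1] != C.shape[1]:
        raise ValueError("cross-kernel column counts do not match training sizes")
    return Kd_cross @ C @ Kp_cross.T


# ---------------------------------------------------------------------------
# bipartite local model


def fit_blm(
    Kd: KernelMatrix, Kp: KernelMatrix, net: InteractionNetwork, params: ModelParams | None = None
) -> TrainedModel:
    """Fit per-drug and per-protein local kernel ridge models.

    Drug d's dual vector is ``(Kp + lambda I)^-1 Y[d,:]`` (row d of
    ``Alpha``); protein p's is ``(Kd + lambda I)^-1 Y[:,p]`` (column p of
    ``Beta``).  Nodes with zero known edges are marked unmodeled.
    """
    params = params or ModelParams("bipartite_local_model")
    if params.algorithm != "bipartite_local_model":
        raise ValueError(f"fit_blm called with algorithm {params.algorithm!r}")
    _check_aligned(Kd, Kp, net)
    lam = params.ridge
    Y = net.Y
    n_d, n_p = Y.shape
    Alpha = np.linalg.solve(Kp.values + lam * np.eye(n_p), Y.T).T  # (n_d, n_p) duals per drug
    Beta = np.linalg.solve(Kd.values + lam * np.eye(n_d), Y)  # (n_d, n_p) duals per protein
    has_drug_model = Y.sum(axis=1) > 0
    has_prot_model = Y.sum(axis=0) > 0
    model = TrainedModel(
        params,
        list(net.drug_ids),
        list(net.protein_ids),
        {
            "Alpha": Alpha,
            "Beta": Beta,
            "has_drug_model": has_drug_model.astype(float),
            "has_prot_model": has_prot_model.astype(float),
            "Kd_train": Kd.values,
            "Kp_train": Kp.values,
        },
    )
    F = model.predict(
        Kd.values, Kp.values, drug_train_idx=range(n_d), protein_train_idx=range(n_p)
    )
    model.arrays["F"] = F
    return model


def _predict_blm(
    model: TrainedModel,
    Kd_cross: np.ndarray,
    Kp_cross: np.ndarray,
    drug_train_idx: Sequence[int] | None,
    protein_train_idx: Sequence[int] | None,
) -> np.ndarray:
    Alpha = model.arrays["Alpha"]
    Beta = model.arrays["Beta"]
    has_d = model.arrays["has_drug_model"].astype(bool)
    has_p = model.arrays["has_prot_model"].astype(bool)
    n_q_d, n_q_p = Kd_cross.shape[0], Kp_cross.shape[0]
    d_idx = np.full(n_q_d, -1, dtype=int) if drug_train_idx is None else np.asarray(list(drug_train_idx), dtype=int)
    p_idx = np.full(n_q_p, -1, dtype=int) if protein_train_idx is None else np.asarray(list(protein_train_idx), dtype=int)

    # drug-side predictions: local model of training drug t scores proteins via Kp_cross
    S_drug_side = Alpha @ Kp_cross.T  # (n_train_d, n_q_p)
    # protein-side predictions: local model of training protein s scores drugs via Kd_cross
    S_prot_side = Kd_cross @ Beta  # (n_q_d, n_train_p)

    D = np.full((n_q_d, n_q_p), np.nan)
    for i, t in enumerate(d_idx):
        if t >= 0 and has_d[t]:
            D[i, :] = S_drug_side[t, :]
    P = np.full((n_q_d, n_q_p), np.nan)
    for j, s in enumerate(p_idx):
        if s >= 0 and has_p[s]:
            P[:, j] = S_prot_side[:, s]

    d_ok, p_ok = ~np.isnan(D), ~np.isnan(P)
    Dz, Pz = np.where(d_ok, D, 0.0), np.where(p_ok, P, 0.0)
    if model.params.blm_combine == "mean":
        n_sides = d_ok.astype(float) + p_ok.astype(float)
        S = (Dz + Pz) / np.maximum(n_sides, 1.0)
    else:
        S = np.where(d_ok & p_ok, np.maximum(Dz, Pz), Dz + Pz)
    return S


# ---------------------------------------------------------------------------
# bipartite graph embedding


def _network_kernel(Y: np.ndarray, jitter: float = 1e-6) -> np.ndarray:
    """Joint PSD kernel on the n_d + n_p training nodes from the adjacency.

    Built from the bipartite incidence B as the block matrix
    ``[[B B^T, B], [B^T, B^T B]] + jitter*I`` followed by eigenvalue
    clipping at 0.  The off-diagonal blocks couple the two sides: with the
    SVD ``B = U S V^T`` the retained eigenvectors are ``[u_k; v_k]/sqrt(2)``
    with eigenvalues ``s_k(s_k + 1)``, so interacting drugs and proteins
    land close together in the embedding.
    """
    n_d, n_p = Y.shape
    M = np.empty((n_d + n_p, n_d + n_p))
    M[:n_d, :n_d] = Y @ Y.T
    M[:n_d, n_d:] = Y
    M[n_d:, :n_d] = Y.T
    M[n_d:, n_d:] = Y.T @ Y
    M += jitter * np.eye(n_d + n_p)
    w, U = np.linalg.eigh(M)
    w = np.maximum(w, 0.0)
    return (U * w) @ U.T


def fit_bge(
    Kd: KernelMatrix, Kp: KernelMatrix, net: InteractionNetwork, params: ModelParams | None = None
) -> TrainedModel:
    """Fit the graph-embedding model: embed training nodes, regress onto them."""
    params = params or ModelParams("bipartite_graph_embedding")
    if params.algorithm != "bipartite_graph_embedding":
        raise ValueError(f"fit_bge called with algorithm {params.algorithm!r}")
    _check_aligned(Kd, Kp, net)
    if net.n_edges == 0:
        raise ValueError("bipartite graph embedding requires at least one training edge")
    n_d, n_p = net.Y.shape
    bound = min(n_d, n_p) - 1
    embed_dim = params.embed_dim if params.embed_dim is not None else max(1, min(10, bound))
    if embed_dim > bound:
        raise ValueError(f"embed_dim {embed_dim} exceeds min(n_drugs, n_proteins) - 1 = {bound}")

    M = _network_kernel(net.Y)
    w, U = np.linalg.eigh(M)
    order = np.argsort(w)[::-1][:embed_dim]
    coords = U[:, order] * np.sqrt(np.maximum(w[order], 0.0))  # (n_d + n_p, embed_dim)
    Z_d, Z_p = coords[:n_d], coords[n_d:]

    lam = params.ridge
    A_d = np.linalg.solve(Kd.values + lam * np.eye(n_d), Z_d)  # maps Kd rows -> drug coords
    A_p = np.linalg.solve(Kp.values + lam * np.eye(n_p), Z_p)
    F = (Kd.values @ A_d) @ (Kp.values @ A_p).T
    return TrainedModel(
        params,
        list(net.drug_ids),
        list(net.protein_ids),
        {
            "A_d": A_d,
            "A_p": A_p,
            "Z_d": Z_d,
            "Z_p": Z_p,
            "F": F,
            "Kd_train": Kd.values,
            "Kp_train": Kp.values,
        },
    )


def _predict_bge(model: TrainedModel, Kd_cross: np.ndarray, Kp_cross: np.ndarray) -> np.ndarray:
    z_d = Kd_cross @ model.arrays["A_d"]
    z_p = Kp_cross @ model.arrays["A_p"]
    return z_d @ z_p.T


# ---------------------------------------------------------------------------
# front door


_FITTERS = {
    "pairwise_kernel_regression": fit_pkr,
    "bipartite_local_model": fit_blm,
    "bipartite_graph_embedding": fit_bge,
}


def fit(
    Kd: KernelMatrix, Kp: KernelMatrix, net: InteractionNetwork, params: ModelParams | None = None
) -> TrainedModel:
    """Dispatch to the fitter named by ``params.algorithm`` (default PKR)."""
    params = params or ModelParams()
    return _FITTERS[params.algorithm](Kd, Kp, net, params)


# ---------------------------------------------------------------------------
# scoring the full universe and thresholding


def score_all_pairs(
    model: TrainedModel,
    Kd_cross: np.ndarray,
    Kp_cross: np.ndarray,
    drug_ids: Sequence[str],
    protein_ids: Sequence[str],
    clip: bool = True,
) -> np.ndarray:
    """Score every drug x protein pair of a universe covering training + new.

    Rows of ``Kd_cross``/``Kp_cross`` follow ``drug_ids``/``protein_ids``;
    columns follow the model's training ids.  Ids matching training ids are
    routed to their local models where the algorithm has them.  With
    ``clip=True`` scores are clipped to [0, 1] for reporting ("closer to 1
    = more reliable"); ranking-based evaluation always uses raw scores.
    """
    d_train = {x: i for i, x in enumerate(model.drug_ids)}
    p_train = {x: i for i, x in enumerate(model.protein_ids)}
    d_idx = [d_train.get(x, -1) for x in drug_ids]
    p_idx = [p_train.get(x, -1) for x in protein_ids]
    S = model.predict(Kd_cross, Kp_cross, drug_train_idx=d_idx, protein_train_idx=p_idx)
    return np.clip(S, 0.0, 1.0) if clip else S


CATEGORIES = ("new-new", "training-new", "new-training", "training-training")


@dataclass
class EdgeRecord:
    drug_id: str
    protein_id: str
    score: float
    category: str
    known: bool = False


@dataclass
class ScoredEdges:
    """Thresholded predicted edges, categorized by endpoint training status."""

    records: list[EdgeRecord]
    threshold: float

    def count_by_category(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.records:
            out[r.category] = out.get(r.category, 0) + 1
        return out


def threshold_edges(
    scores: np.ndarray,
    threshold: float,
    drug_ids: Sequence[str],
    protein_ids: Sequence[str],
    training_drug_ids: Sequence[str],
    training_protein_ids: Sequence[str],
    known_edges: set[tuple[str, str]] | None = None,
    include_known: bool = False,
) -> ScoredEdges:
    """Edges whose score strictly exceeds ``threshold``, with categories.

    Each endpoint is 'training' if present in the training interaction data
    and 'new' otherwise; the category string is drug-status dash
    protein-status.  Known training edges are excluded from the predicted
    list unless ``include_known`` (the "all" view), in which case they are
    flagged ``known=True`` and always included regardless of score.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != (len(drug_ids), len(protein_ids)):
        raise ValueError("score matrix shape does not match id universes")
    td, tp = set(training_drug_ids), set(training_protein_ids)
    known = known_edges or set()
    records: list[EdgeRecord] = []
    for i, d in enumerate(drug_ids):
        d_stat = "training" if d in td else "new"
        for j, p in enumerate(protein_ids):
            cat = f"{d_stat}-{'training' if p in tp else 'new'}"
            is_known = (d, p) in known
            if is_known and not include_known:
                continue
            if scores[i, j] > threshold or (is_known and include_known):
                records.append(EdgeRecord(d, p, float(scores[i, j]), cat, is_known))
    records.sort(key=lambda r: (-r.score, r.drug_id, r.protein_id))
    return ScoredEdges(records, float(threshold))
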