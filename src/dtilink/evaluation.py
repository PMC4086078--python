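"""Cross-validation schemes and ranking metrics for link prediction.

Two validation schemes mirror two practical prediction situations:

* **pair-wise CV** — drug-protein *pairs* are split into folds; test
  pairs have their labels masked to 0 during training.  Measures recovery
  of missing edges among entities that keep other training edges.
* **block-wise CV** — *entities* (drugs, proteins, or both) are split
  into folds and every pair touching a test entity is held out.  Measures
  cold-start prediction for entities with no training edges at all; by
  construction test entities never overlap training entities.

Performance is summarized by AUC (Mann-Whitney formulation, ties counted
half) and AUPR (average precision with a fixed deterministic tie order),
reported as mean +/- SD over repetitions, where a repetition's value is
the unweighted mean of its fold values.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.stats import rankdata

from .inference import ModelParams, fit
from .io_tables import InteractionNetwork, KernelMatrix

__all__ = [
    "CVConfig",
    "CVReport",
    "redundancy_filter",
    "pairwise_split",
    "blockwise_split",
    "auc",
    "aupr",
    "run_cv",
    "SCHEMES",
]

SCHEMES = ("pairwise", "blockwise_drug", "blockwise_protein", "blockwise_both")


@dataclass
class CVConfig:
    scheme: str = "pairwise"
    k: int = 3
    repetitions: int = 3
    seed: int = 0
    params: ModelParams = field(default_factory=ModelParams)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.k < 2:
            raise ValueError("k must be >= 2")
        if self.repetitions < 1:
            raise ValueError("repetitions must be >= 1")


@dataclass
class CVReport:
    """Per-fold metrics plus mean +/- SD across repetitions."""

    config: CVConfig
    fold_auc: list[list[float]]  # [repetition][fold]
    fold_aupr: list[list[float]]
    rep_auc: list[float]
    rep_aupr: list[float]
    mean_auc: float
    sd_auc: float
    mean_aupr: float
    sd_aupr: float

    def summary(self) -> dict:
        return {
            "scheme": self.config.scheme,
            "k": self.config.k,
            "repetitions": self.config.repetitions,
            "seed": self.config.seed,
            "algorithm": self.config.params.algorithm,
            "ridge": self.config.params.ridge,
            "aupr_definition": "average precision, lexicographic tie order",
            "mean_auc": self.mean_auc,
            "sd_auc": self.sd_auc,
            "mean_aupr": self.mean_aupr,
            "sd_aupr": self.sd_aupr,
            "fold_auc": self.fold_auc,
            "fold_aupr": self.fold_aupr,
        }


def redundancy_filter(S: KernelMatrix, cutoff: float = 0.8) -> list[str]:
    """Greedy removal of near-duplicate objects from a similarity matrix.

    A single pass in input order keeps an id iff its similarity to every
    previously kept id is strictly below ``cutoff``.  Used for benchmark
    construction: near-duplicate drugs (or close protein homologs) inflate
    apparent accuracy, so objects with similarity >= cutoff (default 0.8)
    to an already-kept object are dropped.
    """
    kept: list[int] = []
    for i in range(S.n_objects):
        if all(S.values[i, j] < cutoff for j in kept):
            kept.append(i)
    return [S.object_ids[i] for i in kept]


def pairwise_split(net: InteractionNetwork, k: int, seed: int) -> list[np.ndarray]:
    """Partition all n_d * n_p pair indices into k near-equal random folds.

    Pair index = drug_index * n_proteins + protein_index (drug-major).
    Fold sizes differ by at most 1; the split is a deterministic function
    of the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(net.n_drugs * net.n_proteins)
    return [np.sort(f) for f in np.array_split(perm, k)]


def blockwise_split(
    net: InteractionNetwork, k: int, seed: int, scheme: str = "blockwise_drug"
) -> list[dict[str, np.ndarray]]:
    """Partition entities into k blocks for cold-start validation.

    Returns one dict per fold with keys ``test_drugs`` / ``test_proteins``
    (index arrays into the network's axes); an axis not split by the
    scheme gets an empty array.  Test entities of a round never appear in
    any of that round's training pairs.
    """
    if scheme not in ("blockwise_drug", "blockwise_protein", "blockwise_both"):
        raise ValueError(f"not a block-wise scheme: {scheme!r}")
    rng = np.random.default_rng(seed)
    folds: list[dict[str, np.ndarray]] = [
        {"test_drugs": np.array([], dtype=int), "test_proteins": np.array([], dtype=int)}
        for _ in range(k)
    ]
    if scheme in ("blockwise_drug", "blockwise_both"):
        if k > net.n_drugs:
            raise ValueError(f"k={k} exceeds number of drugs ({net.n_drugs})")
        for f, block in enumerate(np.array_split(rng.permutation(net.n_drugs), k)):
            folds[f]["test_drugs"] = np.sort(block)
    if scheme in ("blockwise_protein", "blockwise_both"):
        if k > net.n_proteins:
            raise ValueError(f"k={k} exceeds number of proteins ({net.n_proteins})")
        for f, block in enumerate(np.array_split(rng.permutation(net.n_proteins), k)):
            folds[f]["test_proteins"] = np.sort(block)
    return folds


def auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve, Mann-Whitney formulation.

    ``(concordant pairs + 0.5 * tied pairs) / (n_pos * n_neg)`` — computed
    through average ranks, so ties contribute exactly one half.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 1
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC undefined: needs at least one positive and one negative")
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def aupr(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the precision-recall curve as average precision.

    Mean, over the positives in descending-score order, of the precision
    at each positive's rank.  Ties are broken deterministically by input
    position (stable sort), so results are reproducible bit-for-bit.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    n_pos = int((labels == 1).sum())
    if n_pos == 0:
        raise ValueError("AUPR undefined: needs at least one positive")
    order = np.argsort(-scores, kind="stable")
    sorted_labels = (labels[order] == 1).astype(float)
    cum_pos = np.cumsum(sorted_labels)
    precision_at = cum_pos / np.arange(1, len(scores) + 1)
    return float(precision_at[sorted_labels == 1].mean())


# ---------------------------------------------------------------------------
# the CV driver


def _eval_fold(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float] | None:
    labels = labels.astype(int)
    if labels.min() == labels.max():
        return None
    return auc(scores, labels), aupr(scores, labels)


def _run_pairwise_round(Kd, Kp, net, fold_pairs, params):
    n_p = net.n_proteins
    Y_train = net.Y.copy()
    di, pi = fold_pairs // n_p, fold_pairs % n_p
    Y_train[di, pi] = 0.0
    masked = InteractionNetwork(net.drug_ids, net.protein_ids, Y_train)
    model = fit(Kd, Kp, masked, params)
    S = model.predict(
        Kd.values,
        Kp.values,
        drug_train_idx=range(net.n_drugs),
        protein_train_idx=range(net.n_proteins),
    )
    return S[di, pi], net.Y[di, pi]


def _run_blockwise_round(Kd, Kp, net, fold, params, scheme):
    test_d, test_p = fold["test_drugs"], fold["test_proteins"]
    train_d = np.setdiff1d(np.arange(net.n_drugs), test_d)
    train_p = np.setdiff1d(np.arange(net.n_proteins), test_p)
    Kd_t = KernelMatrix(
        [net.drug_ids[i] for i in train_d], Kd.values[np.ix_(train_d, train_d)], "drug"
    )
    Kp_t = KernelMatrix(
        [net.protein_ids[j] for j in train_p], Kp.values[np.ix_(train_p, train_p)], "protein"
    )
    sub = InteractionNetwork(
        Kd_t.object_ids, Kp_t.object_ids, net.Y[np.ix_(train_d, train_p)]
    )
    model = fit(Kd_t, Kp_t, sub, params)

    if scheme == "blockwise_drug":
        q_d, q_p = test_d, np.arange(net.n_proteins)
    elif scheme == "blockwise_protein":
        q_d, q_p = np.arange(net.n_drugs), test_p
    else:  # blockwise_both: the new-drug x new-protein block
        q_d, q_p = test_d, test_p
    if len(q_d) == 0 or len(q_p) == 0:
        return None
    Kd_cross = Kd.values[np.ix_(q_d, train_d)]
    Kp_cross = Kp.values[np.ix_(q_p, train_p)]
    d_map = {i: t for t, i in enumerate(train_d)}
    p_map = {j: s for s, j in enumerate(train_p)}
    d_idx = [d_map.get(int(i), -1) for i in q_d]
    p_idx = [p_map.get(int(j), -1) for j in q_p]
    S = model.predict(Kd_cross, Kp_cross, drug_train_idx=d_idx, protein_train_idx=p_idx)
    return S.ravel(), net.Y[np.ix_(q_d, q_p)].ravel()


def run_cv(
    Kd: KernelMatrix, Kp: KernelMatrix, net: InteractionNetwork, cfg: CVConfig
) -> CVReport:
    """Repeated k-fold cross-validation under the configured scheme.

    Every repetition reshuffles folds (derived deterministically from the
    seed), fits on the training portion only, scores held-out pairs with
    raw (unclipped) model outputs and evaluates AUC/AUPR on them.  A fold
    whose test labels are single-class is skipped with a warning and
    excluded from that repetition's mean.
    """
    if Kd.object_ids != net.drug_ids or Kp.object_ids != net.protein_ids:
        raise ValueError("kernels must be aligned with the interaction network")
    fold_auc: list[list[float]] = []
    fold_aupr: list[list[float]] = []
    for rep in range(cfg.repetitions):
        rep_seed = int(np.random.SeedSequence(cfg.seed, spawn_key=(rep,)).generate_state(1)[0] % (2**31))
        if cfg.scheme == "pairwise":
            rounds = [
                _run_pairwise_round(Kd, Kp, net, f, cfg.params)
                for f in pairwise_split(net, cfg.k, rep_seed)
            ]
        else:
            rounds = [
                _run_blockwise_round(Kd, Kp, net, f, cfg.params, cfg.scheme)
                for f in blockwise_split(net, cfg.k, rep_seed, cfg.scheme)
            ]
        aucs, auprs = [], []
        for r in rounds:
            metrics = _eval_fold(*r) if r is not None else None
            if metrics is None:
                warnings.warn(
                    "fold with single-class (or empty) test set skipped", stacklevel=2
                )
                continue
            aucs.append(metrics[0])
            auprs.append(metrics[1])
        fold_auc.append(aucs)
        fold_aupr.append(auprs)

    rep_auc = [float(np.mean(a)) for a in fold_auc if a]
    rep_aupr = [float(np.mean(a)) for a in fold_aupr if a]
    if not rep_auc:
        raise ValueError("no evaluable folds in any repetition")

    def _sd(xs: list[float]) -> float:
        return float(np.std(xs, ddof=1)) if len(xs) > 1 else 0.0

    return CVReport(
        config=cfg,
        fold_auc=fold_auc,
        fold_aupr=fold_aupr,
        rep_auc=rep_auc,
        rep_aupr=rep_aupr,
        mean_auc=float(np.mean(rep_auc)),
        sd_auc=_sd(rep_auc),
        mean_aupr=float(np.mean(rep_aupr)),
        sd_aupr=_sd(rep_aupr),
    )
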