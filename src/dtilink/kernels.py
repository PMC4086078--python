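"""Kernel construction, repair, normalization and multi-view integration.

Every heterogeneous data view (chemical fingerprints, side-effect
profiles, domain compositions, expression levels, ...) is reduced to a
symmetric positive-semidefinite object x object similarity matrix — a
kernel — and the kernels of one side are combined by a weighted linear
sum into a single integrated similarity matrix.  That integrated kernel
is the only representation the inference algorithms ever see, which is
what lets arbitrarily heterogeneous inputs coexist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io_tables import KernelMatrix, ProfileMatrix

__all__ = [
    "KernelSet",
    "linear_kernel",
    "gaussian_kernel",
    "tanimoto_kernel",
    "correlation_kernel",
    "normalize_kernel",
    "psd_repair",
    "integrate_kernels",
    "kernel_from_profile",
    "default_gamma",
    "KERNEL_FUNCTIONS",
]


def _symmetrize(K: np.ndarray) -> np.ndarray:
    return (K + K.T) / 2.0


def linear_kernel(X: ProfileMatrix) -> KernelMatrix:
    """Inner-product kernel: ``K[i,j] = <x_i, x_j>``. PSD by construction."""
    K = _symmetrize(X.values @ X.values.T)
    return KernelMatrix(X.object_ids, K, X.side, provenance="linear")


def default_gamma(X: ProfileMatrix) -> float:
    """Median heuristic: ``1 / median(squared pairwise distance)``.

    Falls back to 1.0 when the median distance is zero (e.g. all rows
    identical) so the kernel stays well defined.
    """
    if X.n_objects < 2:
        return 1.0
    d2 = pdist(X.values, metric="sqeuclidean")
    med = float(np.median(d2))
    return 1.0 / med if med > 0 else 1.0


def gaussian_kernel(X: ProfileMatrix, gamma: float | None = None) -> KernelMatrix:
    """RBF kernel ``K[i,j] = exp(-gamma * ||x_i - x_j||^2)``; unit diagonal.

    ``gamma=None`` uses the median heuristic of :func:`default_gamma`.
    """
    if gamma is None:
        gamma = default_gamma(X)
    if gamma <= 0:
        raise ValueError(f"gamma must be positive, got {gamma}")
    d2 = squareform(pdist(X.values, metric="sqeuclidean"))
    K = np.exp(-gamma * d2)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(X.object_ids, _symmetrize(K), X.side, provenance=f"gaussian(gamma={gamma:g})")


def tanimoto_kernel(X: ProfileMatrix) -> KernelMatrix:
    """Tanimoto (Jaccard) kernel for binary fingerprints.

    ``K[i,j] = |x_i AND x_j| / |x_i OR x_j|``.  All-zero fingerprints would
    give 0/0; they are assigned self-similarity 1 and cross-similarity 0
    (a valid kernel block) with a warning.
    """
    V = X.values
    if not np.isin(V, (0.0, 1.0)).all():
        bad = np.argwhere(~np.isin(V, (0.0, 1.0)))[0]
        raise ValueError(
            f"tanimoto_kernel requires binary entries; found {V[tuple(bad)]!r} at "
            f"row {X.object_ids[bad[0]]!r}, column {X.feature_ids[bad[1]]!r}"
        )
    inter = V @ V.T
    sizes = V.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    empty = sizes == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} all-zero fingerprint row(s): self-similarity set to 1, "
            "cross-similarity 0",
            stacklevel=2,
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        K = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(X.object_ids, _symmetrize(K), X.side, provenance="tanimoto")


def correlation_kernel(X: ProfileMatrix) -> KernelMatrix:
    """Pearson correlation of profile rows; unit diagonal.

    A zero-variance row has no defined correlation and is a hard error.
    """
    V = X.values
    sd = V.std(axis=1)
    if (sd == 0).any():
        bad = X.object_ids[int(np.argmax(sd == 0))]
        raise ValueError(f"zero-variance profile row: {bad!r}")
    K = np.corrcoef(V)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(X.object_ids, _symmetrize(K), X.side, provenance="correlation")


def normalize_kernel(K: KernelMatrix) -> KernelMatrix:
    """Cosine normalization ``K'[i,j] = K[i,j] / sqrt(K[i,i] K[j,j])``.

    Puts heterogeneous views on a common unit-diagonal scale before
    integration; idempotent.  Nonpositive diagonal entries are hard errors.
    """
    d = np.diag(K.values)
    if (d <= 0).any():
        bad = K.object_ids[int(np.argmax(d <= 0))]
        raise ValueError(f"nonpositive kernel diagonal for id {bad!r}")
    s = 1.0 / np.sqrt(d)
    V = _symmetrize(K.values * s[:, None] * s[None, :])
    np.fill_diagonal(V, 1.0)
    return KernelMatrix(K.object_ids, V, K.side, provenance=f"normalize({K.provenance})")


def psd_repair(K: KernelMatrix, floor: float = 0.0) -> KernelMatrix:
    """Clip eigenvalues below ``floor`` and reconstruct.

    User-supplied similarity matrices (sequence scores, structure
    similarities) need not be positive semidefinite; eigenvalue clipping is
    the closest-PSD projection in Frobenius norm.  A PSD input passes
    through unchanged up to 1e-10.
    """
    w, U = np.linalg.eigh(K.values)
    if w.min() >= floor:
        return K
    w = np.maximum(w, floor)
    V = _symmetrize((U * w) @ U.T)
    return KernelMatrix(K.object_ids, V, K.side, provenance=f"psd_repair({K.provenance})")


@dataclass
class KernelSet:
    """Ordered kernels of one side with non-negative combination weights."""

    kernels: list[KernelMatrix]
    weights: Sequence[float] | None = None

    def __post_init__(self) -> None:
        if not self.kernels:
            raise ValueError("KernelSet requires at least one kernel")
        if self.weights is None:
            self.weights = [1.0] * len(self.kernels)
        self.weights = [float(w) for w in self.weights]
        if len(self.weights) != len(self.kernels):
            raise ValueError(
                f"{len(self.weights)} weights for {len(self.kernels)} kernels"
            )
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if sum(self.weights) <= 0:
            raise ValueError("weights must not all be zero")
        ref = self.kernels[0]
        for k in self.kernels[1:]:
            if k.side != ref.side:
                raise ValueError("all kernels in a set must describe the same side")
            if k.object_ids != ref.object_ids:
                raise ValueError(
                    "kernels in a set must share identical object ids in the same "
                    "order; align them first (restrict_to_intersection/reorder)"
                )


def integrate_kernels(ks: KernelSet, normalize_weights: bool = True) -> KernelMatrix:
    """Weighted linear combination ``K* = sum_i w_i K_i`` of one side's views.

    By default weights are normalized to sum 1 (equal weights give the
    mean), which keeps a unit-diagonal scale through integration;
    ``normalize_weights=False`` gives the raw sum.
    """
    w = np.asarray(ks.weights, dtype=float)
    if normalize_weights:
        w = w / w.sum()
    ref = ks.kernels[0]
    V = np.zeros_like(ref.values)
    for wi, k in zip(w, ks.kernels):
        V += wi * k.values
    prov = " + ".join(f"{wi:g}*{k.provenance or 'kernel'}" for wi, k in zip(w, ks.kernels))
    return KernelMatrix(ref.object_ids, _symmetrize(V), ref.side, provenance=prov)


KERNEL_FUNCTIONS = {
    "linear": linear_kernel,
    "gaussian": gaussian_kernel,
    "tanimoto": tanimoto_kernel,
    "correlation": correlation_kernel,
}


def kernel_from_profile(
    X: ProfileMatrix,
    kernel_fn: str = "linear",
    normalize: bool = True,
    repair: bool = True,
    **kwargs,
) -> KernelMatrix:
    """Default profile-to-kernel pipeline: kernel -> normalize -> PSD repair.

    This is the pipeline applied to every profile view before integration;
    user-supplied similarity matrices instead get PSD repair only.
    """
    try:
        fn = KERNEL_FUNCTIONS[kernel_fn]
    except KeyError:
        raise ValueError(
            f"unknown kernel function {kernel_fn!r}; choose from {sorted(KERNEL_FUNCTIONS)}"
        ) from None
    K = fn(X, **kwargs)
    if normalize:
        K = normalize_kernel(K)
    if repair:
        K = psd_repair(K)
    return K
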