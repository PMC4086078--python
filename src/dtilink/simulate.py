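"""Synthetic drug-target benchmarks with a shared-latent-space ground truth.

The generator instantiates the core working assumption of similarity-based
interaction prediction — similar drugs tend to interact with similar
proteins — in its most direct form: drugs and proteins get latent
coordinates in a common low-dimensional space, a pair's interaction
propensity is the inner product of its coordinates, and the observed
network is the densest slice of those propensities.  Observable data
views are noisy random projections of the latent coordinates, so kernels
computed from the views approximate latent similarity and a kernel
method that exploits the assumption can recover held-out edges.

Randomness is organized as named substreams (latent coordinates, each
view's projection, each view's noise) derived from one seed, so changing
one view's noise level never perturbs any other artifact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .io_tables import InteractionNetwork, ProfileMatrix

__all__ = ["SynthConfig", "SynthData", "generate", "complementary_views"]


@dataclass
class SynthConfig:
    """Study conditions for one synthetic benchmark.

    Defaults describe a small but non-trivial screen: 60 drugs x 40
    proteins with a rank-4 latent structure, 8% interaction density, and
    one mildly noisy real-valued view per side with more features than
    latent dimensions (so the latent geometry is identifiable).
    """

    n_drugs: int = 60
    n_proteins: int = 40
    latent_dim: int = 4
    density: float = 0.08
    n_views_per_side: int = 1
    view_noise: Sequence[float] = (0.1,)
    view_feature_dims: Sequence[int] = (32,)
    binary_views: Sequence[bool] = (False,)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_drugs < 1 or self.n_proteins < 1:
            raise ValueError("need at least one drug and one protein")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not (0 < self.density < 1):
            raise ValueError("density must lie in (0, 1)")
        if self.density * self.n_drugs * self.n_proteins < 1:
            raise ValueError("density too low: would produce an empty network")
        self.view_noise = list(self.view_noise)
        self.view_feature_dims = list(self.view_feature_dims)
        self.binary_views = list(self.binary_views)
        for name, xs in (
            ("view_noise", self.view_noise),
            ("view_feature_dims", self.view_feature_dims),
            ("binary_views", self.binary_views),
        ):
            if len(xs) != self.n_views_per_side:
                raise ValueError(f"{name} must have n_views_per_side={self.n_views_per_side} entries")
        if any(s < 0 for s in self.view_noise):
            raise ValueError("view_noise entries must be non-negative")
        if any(d < 1 for d in self.view_feature_dims):
            raise ValueError("view_feature_dims entries must be >= 1")


@dataclass
class SynthData:
    drug_profiles: list[ProfileMatrix]
    protein_profiles: list[ProfileMatrix]
    network: InteractionNetwork
    latent_drugs: np.ndarray  # (n_drugs, latent_dim) ground truth
    latent_proteins: np.ndarray
    propensity: np.ndarray  # (n_drugs, n_proteins) raw scores Y was cut from


# named substream tags (stable across releases; part of the data contract)
_STREAM_LATENT = 0
_STREAM_PROJECTION = 1
_STREAM_NOISE = 2
_SIDE_DRUG = 0
_SIDE_PROTEIN = 1


def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def _top_k_network(propensity: np.ndarray, density: float, drug_ids, protein_ids) -> InteractionNetwork:
    """Mark the ``ceil(density * n_pairs)`` largest propensities as edges.

    Deterministic thresholding rather than Bernoulli sampling, so edge
    counts are exact; ties broken by drug-major pair index (stable sort).
    """
    n_d, n_p = propensity.shape
    n_edges = int(np.ceil(density * n_d * n_p))
    flat = propensity.ravel()
    order = np.argsort(-flat, kind="stable")
    Y = np.zeros(n_d * n_p)
    Y[order[:n_edges]] = 1.0
    return InteractionNetwork(drug_ids, protein_ids, Y.reshape(n_d, n_p))


def _make_view(
    Z: np.ndarray,
    feature_dim: int,
    noise: float,
    binary: bool,
    object_ids: list[str],
    side: str,
    seed: int,
    side_tag: int,
    view_idx: int,
    visible: slice = slice(None),
) -> ProfileMatrix:
    latent_dim = Z.shape[1]
    W = _rng(seed, _STREAM_PROJECTION, side_tag, view_idx).standard_normal((latent_dim, feature_dim))
    if feature_dim >= latent_dim:
        # orthonormal rows: the projection is an isometry of the latent space,
        # so at zero noise the view's Gram matrix equals the latent Gram matrix
        Q, _ = np.linalg.qr(W.T)
        W = Q[:, :latent_dim].T
    else:
        W = W / np.sqrt(latent_dim)
    Zv = np.zeros_like(Z)
    Zv[:, visible] = Z[:, visible]
    X = Zv @ W
    if noise > 0:
        X = X + noise * _rng(seed, _STREAM_NOISE, side_tag, view_idx).standard_normal(X.shape)
    if binary:
        X = (X > np.median(X)).astype(float)
    feats = [f"{side[0]}v{view_idx}_f{j}" for j in range(feature_dim)]
    return ProfileMatrix(object_ids, feats, X, side)


def generate(cfg: SynthConfig) -> SynthData:
    """Draw one synthetic benchmark: latent truth, network, noisy views.

    Latent coordinates are standard normal; propensity(d, p) = z_d . z_p;
    the top ``ceil(density * n_d * n_p)`` pairs by propensity are the
    interactions.  View v per side is ``Z W_v + noise_v * E`` with a random
    projection ``W_v`` (scaled 1/sqrt(latent_dim)) and standard-normal
    noise; binary views threshold at the view's median value.
    """
    drug_ids = [f"d{i + 1:03d}" for i in range(cfg.n_drugs)]
    protein_ids = [f"p{j + 1:03d}" for j in range(cfg.n_proteins)]

    Zd = _rng(cfg.seed, _STREAM_LATENT, _SIDE_DRUG).standard_normal((cfg.n_drugs, cfg.latent_dim))
    Zp = _rng(cfg.seed, _STREAM_LATENT, _SIDE_PROTEIN).standard_normal((cfg.n_proteins, cfg.latent_dim))
    propensity = Zd @ Zp.T
    net = _top_k_network(propensity, cfg.density, drug_ids, protein_ids)

    drug_profiles, protein_profiles = [], []
    for v in range(cfg.n_views_per_side):
        drug_profiles.append(
            _make_view(
                Zd, cfg.view_feature_dims[v], cfg.view_noise[v], cfg.binary_views[v],
                drug_ids, "drug", cfg.seed, _SIDE_DRUG, v,
            )
        )
        protein_profiles.append(
            _make_view(
                Zp, cfg.view_feature_dims[v], cfg.view_noise[v], cfg.binary_views[v],
                protein_ids, "protein", cfg.seed, _SIDE_PROTEIN, v,
            )
        )
    return SynthData(drug_profiles, protein_profiles, net, Zd, Zp, propensity)


def complementary_views(cfg: SynthConfig) -> SynthData:
    """Generate two views per side that are informative about disjoint halves
    of the latent space.

    View A projects only the first ``latent_dim/2`` coordinates (the rest
    contribute nothing but noise); view B only the second half.  Neither
    view alone determines the interaction propensity, so integrating both
    should beat either one — the setting where multi-view integration pays.
    Requires an even ``latent_dim``; view parameters of the config's first
    view (noise, feature dim, binarization) apply to both.
    """
    if cfg.latent_dim % 2 != 0:
        raise ValueError("complementary_views requires an even latent_dim")
    half = cfg.latent_dim // 2

    drug_ids = [f"d{i + 1:03d}" for i in range(cfg.n_drugs)]
    protein_ids = [f"p{j + 1:03d}" for j in range(cfg.n_proteins)]
    Zd = _rng(cfg.seed, _STREAM_LATENT, _SIDE_DRUG).standard_normal((cfg.n_drugs, cfg.latent_dim))
    Zp = _rng(cfg.seed, _STREAM_LATENT, _SIDE_PROTEIN).standard_normal((cfg.n_proteins, cfg.latent_dim))
    propensity = Zd @ Zp.T
    net = _top_k_network(propensity, cfg.density, drug_ids, protein_ids)

    noise = cfg.view_noise[0]
    fdim = cfg.view_feature_dims[0]
    binary = cfg.binary_views[0]
    halves = (slice(0, half), slice(half, cfg.latent_dim))
    drug_profiles = [
        _make_view(Zd, fdim, noise, binary, drug_ids, "drug", cfg.seed, _SIDE_DRUG, v, visible=h)
        for v, h in enumerate(halves)
    ]
    protein_profiles = [
        _make_view(Zp, fdim, noise, binary, protein_ids, "protein", cfg.seed, _SIDE_PROTEIN, v, visible=h)
        for v, h in enumerate(halves)
    ]
    return SynthData(drug_profiles, protein_profiles, net, Zd, Zp, propensity)
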