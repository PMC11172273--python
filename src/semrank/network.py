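"""Forward pass of the personalized retrieval network.

Each side (query / document) owns six scalar filter scores and a feature
matrix NQM.  A filter score is expanded to an n-vector (by masking with
the item's binary MDF vector, or broadcast constant), convolved against
the rows of NQM (one dot product per row), passed through ReLU, max-pooled
to a scalar, and the six pooled scalars go through a fully connected
layer.  With the default identity weights the network is a deterministic
feature aggregator — there is no training signal anywhere in the model,
so no loss or optimizer exists; a seeded random weight matrix is provided
for ablation experiments only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .semantics import FeatureMatrix

__all__ = [
    "N_FILTERS",
    "NetworkConfig",
    "Representation",
    "vectorize_filter",
    "convolve",
    "relu",
    "max_pool",
    "fully_connected",
    "represent",
]

N_FILTERS = 6


@dataclass(frozen=True)
class NetworkConfig:
    """Fully-connected layer parameters and filter vectorization mode."""

    fcl_weights: np.ndarray = field(
        default_factory=lambda: np.eye(N_FILTERS)
    )
    fcl_bias: np.ndarray = field(default_factory=lambda: np.zeros(N_FILTERS))
    vectorization_mode: str = "active_mask"  # or "constant"

    def __post_init__(self) -> None:
        W = np.asarray(self.fcl_weights, dtype=float)
        b = np.asarray(self.fcl_bias, dtype=float)
        if W.shape != (N_FILTERS, N_FILTERS):
            raise ValueError(f"fcl_weights must be {N_FILTERS}x{N_FILTERS}, got {W.shape}")
        if b.shape != (N_FILTERS,):
            raise ValueError(f"fcl_bias must have length {N_FILTERS}, got {b.shape}")
        if not (np.all(np.isfinite(W)) and np.all(np.isfinite(b))):
            raise ValueError("fully connected parameters must be finite")
        if self.vectorization_mode not in ("active_mask", "constant"):
            raise ValueError(f"unknown vectorization mode {self.vectorization_mode!r}")
        object.__setattr__(self, "fcl_weights", W)
        object.__setattr__(self, "fcl_bias", b)

    @classmethod
    def random(cls, seed: int, scale: float = 1.0, **kwargs) -> "NetworkConfig":
        """Seeded random weight matrix, for ablation only."""
        rng = np.random.default_rng(seed)
        return cls(
            fcl_weights=scale * rng.standard_normal((N_FILTERS, N_FILTERS)),
            **kwargs,
        )


@dataclass(frozen=True)
class Representation:
    """Fixed-length vector representation of one side of a matching pair."""

    vector: np.ndarray
    owner: str = "query"


def vectorize_filter(score: float, active: np.ndarray, mode: str = "active_mask") -> np.ndarray:
    """Expand a scalar filter score to an n-vector.

    ``active_mask`` places the score on the item's active MDF positions
    (F[k] = score * V[k]); ``constant`` broadcasts it everywhere.
    """
    active = np.asarray(active, dtype=float)
    if mode == "active_mask":
        return score * active
    if mode == "constant":
        return np.full(active.shape[0], float(score))
    raise ValueError(f"unknown vectorization mode {mode!r}")


def convolve(nqm: FeatureMatrix | np.ndarray, F: np.ndarray) -> np.ndarray:
    """Feature map C with C[i] = sum_k NQM[i][k] * F[k] (one value per row)."""
    values = nqm.values if isinstance(nqm, FeatureMatrix) else np.asarray(nqm, float)
    F = np.asarray(F, dtype=float)
    if values.ndim != 2 or values.shape[1] != F.shape[0]:
        raise ValueError(
            f"dimension mismatch: matrix {values.shape} vs filter {F.shape}"
        )
    return values @ F


def relu(C: np.ndarray) -> np.ndarray:
    """Elementwise max(0, c)."""
    return np.maximum(np.asarray(C, dtype=float), 0.0)


def max_pool(C: np.ndarray) -> float:
    """Maximum of a feature map."""
    C = np.asarray(C, dtype=float)
    if C.size == 0:
        raise ValueError("cannot max-pool an empty feature map")
    return float(C.max())


def fully_connected(
    p: np.ndarray, cfg: NetworkConfig, owner: str = "query"
) -> Representation:
    """W @ p + bias over the six pooled scalars."""
    p = np.asarray(p, dtype=float)
    if p.shape != (N_FILTERS,):
        raise ValueError(f"pooled vector must have length {N_FILTERS}, got {p.shape}")
    return Representation(vector=cfg.fcl_weights @ p + cfg.fcl_bias, owner=owner)


def represent(
    nqm: FeatureMatrix | np.ndarray,
    side_scores: Sequence[float],
    active: np.ndarray,
    cfg: NetworkConfig | None = None,
    owner: str = "query",
) -> Representation:
    """Full forward pass for one side: 6 x (vectorize -> convolve -> ReLU ->
    max-pool), then the fully connected layer."""
    if cfg is None:
        cfg = NetworkConfig()
    scores = np.asarray(side_scores, dtype=float)
    if scores.shape != (N_FILTERS,):
        raise ValueError(f"expected {N_FILTERS} filter scores, got {scores.shape}")
    pooled = np.empty(N_FILTERS)
    for t in range(N_FILTERS):
        F = vectorize_filter(scores[t], active, cfg.vectorization_mode)
        pooled[t] = max_pool(relu(convolve(nqm, F)))
    return fully_connected(pooled, cfg, owner=owner)
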