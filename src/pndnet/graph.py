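"""Symmetric-normalized graph convolution over the region-node graph.

The P spatial pyramid nodes form a complete graph: every region interacts
with every other, however far apart, so long-range feature interactions are
propagated in a single hop. With self-loops added (A~ = A + I) and
D~ the diagonal degree matrix of A~, the propagation operator is the
renormalized

    A_hat = D~^{-1/2} A~ D~^{-1/2},

which for the complete P-node graph equals the uniform matrix J/P. A GCN
layer maps node features G -> ReLU(A_hat G W + b); two such layers with the
channel width kept equal to the backbone width form the default module.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .nn import glorot_uniform

__all__ = ["NormalizedAdjacency", "GCNLayerParams", "build_adjacency",
           "normalize_adjacency", "init_gcn_params", "gcn_forward"]


@dataclass(frozen=True)
class NormalizedAdjacency:
    """Binary adjacency A, self-looped A~ = A + I, degree diagonal of A~,
    and the symmetric-normalized operator A_hat."""

    A: np.ndarray
    A_tilde: np.ndarray
    degrees: np.ndarray
    A_hat: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.A.shape[0]


@dataclass
class GCNLayerParams:
    """Per-layer weight matrices (and zero-initialized biases)."""

    weights: list[np.ndarray]
    biases: list[np.ndarray]

    @property
    def n_layers(self) -> int:
        return len(self.weights)


def normalize_adjacency(A: np.ndarray) -> NormalizedAdjacency:
    """Renormalization of an arbitrary binary adjacency (self-loops added)."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {A.shape}")
    if not np.array_equal(A, A.T):
        raise ValueError("adjacency must be symmetric (undirected graph)")
    P = A.shape[0]
    A_tilde = A + np.eye(P)
    degrees = A_tilde.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(degrees)
    A_hat = A_tilde * inv_sqrt[:, None] * inv_sqrt[None, :]
    return NormalizedAdjacency(A=A, A_tilde=A_tilde, degrees=degrees, A_hat=A_hat)


def build_adjacency(P: int, topology: str = "complete") -> NormalizedAdjacency:
    """Normalized adjacency for P nodes.

    ``complete`` (the model topology) yields A_hat = J/P exactly. ``path``
    and ``ring`` exist for testing alternative structures only.
    """
    if P < 1:
        raise ValueError(f"node count must be >= 1, got {P}")
    if topology == "complete":
        A = np.ones((P, P)) - np.eye(P)
    elif topology == "path":
        A = np.zeros((P, P))
        idx = np.arange(P - 1)
        A[idx, idx + 1] = A[idx + 1, idx] = 1.0
    elif topology == "ring":
        A = np.zeros((P, P))
        idx = np.arange(P)
        A[idx, (idx + 1) % P] = A[(idx + 1) % P, idx] = 1.0
        if P <= 2:
            A = np.minimum(A, 1.0)
    else:
        raise ValueError(f"unknown topology {topology!r}")
    return normalize_adjacency(A)


def init_gcn_params(c_in: int, widths: list[int] | tuple[int, ...],
                    rng: np.random.Generator | None = None) -> GCNLayerParams:
    """Glorot-uniform weights, zero biases, chaining c_in through widths."""
    rng = rng or np.random.default_rng(0)
    weights, biases = [], []
    prev = c_in
    for w in widths:
        weights.append(glorot_uniform(rng, prev, w, (prev, w)))
        biases.append(np.zeros(w))
        prev = w
    return GCNLayerParams(weights=weights, biases=biases)


def gcn_forward(G0: np.ndarray, params: GCNLayerParams,
                adj: NormalizedAdjacency) -> np.ndarray:
    """Apply G^{(l+1)} = ReLU(A_hat G^{(l)} W^{(l)} + b^{(l)}) for every layer."""
    G = np.asarray(G0, dtype=float)
    if G.ndim != 2:
        raise ValueError(f"node features must be P x C, got shape {G.shape}")
    if not np.all(np.isfinite(G)):
        raise ValueError("node features contain non-finite values")
    P = adj.n_nodes
    if G.shape[0] != P:
        raise ValueError(f"node count mismatch: features have {G.shape[0]} rows, "
                         f"adjacency has {P}")
    for W, b in zip(params.weights, params.biases):
        if W.shape[0] != G.shape[1]:
            raise ValueError(f"weight shape {W.shape} does not chain with "
                             f"features of width {G.shape[1]}")
        G = np.maximum(adj.A_hat @ G @ W + b, 0.0)
    return G
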