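"""Spectral graph convolution over the scalp-electrode graph.

Nodes are the 16 scalp electrodes; edges are binary and symmetric.  Layers
propagate as ``H(l+1) = act(A_norm @ H(l) @ W(l) + b(l))`` with the
renormalized adjacency ``A_norm = D_hat^{-1/2} (A + I) D_hat^{-1/2}``.
A mean-pool readout over nodes feeds a linear classifier.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .montage import SCALP_16, default_edges
from .nn import ACTIVATIONS, Linear, Module, Tensor, as_tensor, parameter


class GraphError(ValueError):
    """Invalid electrode-graph construction input."""


@dataclass(frozen=True)
class ElectrodeGraph:
    nodes: tuple[str, ...]
    A: np.ndarray        # binary adjacency, zero diagonal
    A_hat: np.ndarray    # A + I
    D_hat: np.ndarray    # diagonal degree matrix of A_hat
    A_norm: np.ndarray   # D_hat^{-1/2} A_hat D_hat^{-1/2}

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def permuted(self, order: np.ndarray) -> "ElectrodeGraph":
        """Graph with nodes (and matrix rows/cols) reordered by ``order``."""
        order = np.asarray(order)
        return build_graph(tuple(self.nodes[i] for i in order),
                           [(self.nodes[i], self.nodes[j])
                            for i, j in zip(*np.nonzero(np.triu(self.A)))])


def build_graph(montage, edges) -> ElectrodeGraph:
    """Build the electrode graph from a node list and name-pair edges."""
    nodes = tuple(montage)
    index = {name: i for i, name in enumerate(nodes)}
    if len(index) != len(nodes):
        raise GraphError("duplicate electrode names")
    n = len(nodes)
    A = np.zeros((n, n))
    for a, b in edges:
        if a not in index or b not in index:
            raise GraphError(f"edge ({a}, {b}) references unknown electrode")
        if a == b:
            raise GraphError(f"self-edge on {a} is not allowed")
        A[index[a], index[b]] = 1.0
        A[index[b], index[a]] = 1.0
    A_hat = A + np.eye(n)
    deg = A_hat.sum(axis=1)
    D_hat = np.diag(deg)
    d_inv_sqrt = 1.0 / np.sqrt(deg)
    A_norm = d_inv_sqrt[:, None] * A_hat * d_inv_sqrt[None, :]
    return ElectrodeGraph(nodes=nodes, A=A, A_hat=A_hat, D_hat=D_hat, A_norm=A_norm)


def default_electrode_graph(threshold_deg: float = 46.0) -> ElectrodeGraph:
    """16-node 10-20 scalp graph with geodesic-neighbour edges."""
    return build_graph(SCALP_16, default_edges(threshold_deg))


def gcn_layer(H, graph: ElectrodeGraph, W, bias=None,
              activation="relu") -> Tensor:
    """One spectral graph-convolution layer: ``act(A_norm @ H @ W + b)``.

    ``H`` is (n_nodes, d) or (batch, n_nodes, d); node order must match
    ``graph.nodes``.
    """
    H = as_tensor(H)
    W = as_tensor(W)
    if H.shape[-2] != graph.n_nodes:
        raise ValueError(f"H has {H.shape[-2]} rows, graph has {graph.n_nodes} nodes")
    if H.shape[-1] != W.shape[0]:
        raise ValueError("feature dim of H incompatible with W")
    act = ACTIVATIONS[activation] if isinstance(activation, str) else activation
    out = Tensor(graph.A_norm) @ H @ W
    if bias is not None:
        out = out + as_tensor(bias)
    return act(out)


@dataclass(frozen=True)
class SGCMConfig:
    n_layers: int = 2
    hidden_dim: int = 64
    n_classes: int = 3
    activation: str = "relu"

    def __post_init__(self):
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be positive")


class SGCM(Module):
    """Graph-convolution stack + mean-pool readout + linear classifier."""

    def __init__(self, cfg: SGCMConfig, in_dim: int,
                 rng: np.random.Generator | int = 0):
        if isinstance(rng, (int, np.integer)):
            rng = np.random.default_rng(rng)
        self.cfg = cfg
        dims = [in_dim] + [cfg.hidden_dim] * cfg.n_layers
        self.weights = []
        self.biases = []
        for d_in, d_out in zip(dims[:-1], dims[1:]):
            limit = np.sqrt(6.0 / (d_in + d_out))
            self.weights.append(parameter(rng.uniform(-limit, limit, (d_in, d_out))))
            self.biases.append(parameter(np.zeros(d_out)))
        self.head = Linear(dims[-1], cfg.n_classes, rng)

    def __call__(self, features, graph: ElectrodeGraph) -> Tensor:
        """``features``: (n_nodes, d) or (batch, n_nodes, d) -> logits."""
        H = as_tensor(features)
        squeeze = H.ndim == 2
        if H.shape[-2] != graph.n_nodes:
            raise ValueError("one feature vector per graph node is required")
        for W, b in zip(self.weights, self.biases):
            H = gcn_layer(H, graph, W, bias=b, activation=self.cfg.activation)
        pooled = H.mean(axis=-2)          # symmetric readout over nodes
        logits = self.head(pooled)
        return logits


def sgcm_forward(model: SGCM, features, graph: ElectrodeGraph) -> Tensor:
    """Classify a segment from its 16 per-channel feature vectors."""
    return model(features, graph)
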