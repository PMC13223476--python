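"""Feature-interaction graph reasoning (FIGR).

Channel features are projected onto a small fully connected graph
(``N_f = C * node_fraction`` nodes, ``S_f = C/2`` states per node), mixed by
Laplacian-smoothed graph convolution

    V~ = sigma((I + A^T) V W)

realized as two kernel-1 Conv1D mixings (node dimension, then state/channel
dimension) with the identity term as a residual add, and re-projected back to
the feature grid with a residual join.  With all learned weights zero the
block is exactly the identity map.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .autodiff import (
    Conv3d,
    GroupNorm,
    Module,
    Parameter,
    Tensor,
    default_groups,
)

_ACTIVATIONS: dict[str, Callable[[Tensor], Tensor]] = {
    "relu": lambda t: t.relu(),
    "identity": lambda t: t,
    "sigmoid": lambda t: t.sigmoid(),
}


@dataclass
class GraphState:
    """Node-feature matrix, nodes x states, optionally batched (B, N_f, S_f)."""

    node_features: Tensor

    @property
    def n_nodes(self) -> int:
        return self.node_features.shape[-2]

    @property
    def n_states(self) -> int:
        return self.node_features.shape[-1]


@dataclass
class GraphReasonParams:
    """Explicit weights for the functional form of the graph mixing step."""

    adjacency: Tensor      # (N_f, N_f)
    state_weight: Tensor   # (S_f, S_f)
    activation: str = "relu"


def graph_reason(v: GraphState, params: GraphReasonParams) -> GraphState:
    """sigma((I + A^T) V W): node mixing + residual, then state mixing, then sigma."""
    vf = v.node_features
    a, w = params.adjacency, params.state_weight
    if a.shape != (v.n_nodes, v.n_nodes):
        raise ValueError(f"adjacency shape {a.shape} incompatible with {v.n_nodes} nodes")
    if w.shape != (v.n_states, v.n_states):
        raise ValueError(f"state weight shape {w.shape} incompatible with {v.n_states} states")
    propagated = vf + a.T @ vf          # Conv1D over the node dimension + identity
    weighted = propagated @ w           # Conv1D over the state dimension
    act = _ACTIVATIONS[params.activation]
    return GraphState(act(weighted))


class FIGR(Module):
    """The full projection / reasoning / reprojection block on (N, C, H, W, D)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 node_fraction: float = 0.25, activation: str = "relu"):
        super().__init__()
        if activation not in _ACTIVATIONS:
            raise ValueError(f"unknown activation {activation!r}")
        n_nodes = channels * node_fraction
        if abs(n_nodes - round(n_nodes)) > 1e-9 or channels % 2:
            raise ValueError(
                f"channels={channels} incompatible with node fraction {node_fraction}"
            )
        self.channels = channels
        self.n_nodes = int(round(n_nodes))
        self.n_states = channels // 2
        self.activation = activation
        self.conv_theta = Conv3d(channels, self.n_nodes, 1, rng)
        self.norm_theta = GroupNorm(default_groups(self.n_nodes), self.n_nodes)
        self.conv_phi = Conv3d(channels, self.n_states, 1, rng)
        self.norm_phi = GroupNorm(default_groups(self.n_states), self.n_states)
        scale = 1.0 / np.sqrt(self.n_nodes)
        self.adjacency = Parameter(rng.normal(0.0, scale, (self.n_nodes, self.n_nodes)))
        self.state_weight = Parameter(
            rng.normal(0.0, 1.0 / np.sqrt(self.n_states), (self.n_states, self.n_states))
        )
        self.conv_restore = Conv3d(self.n_states, channels, 1, rng)
        self.norm_restore = GroupNorm(default_groups(channels), channels)

    # -- the three stages ----------------------------------------------------
    def graph_project(self, x: Tensor) -> tuple[Tensor, Tensor, GraphState]:
        """theta: (B, N_f, V); phi: (B, S_f, V); V_f = theta phi^T: (B, N_f, S_f)."""
        b, c = x.shape[0], x.shape[1]
        if c != self.channels:
            raise ValueError(f"expected {self.channels} channels, got {c}")
        v = int(np.prod(x.shape[2:]))
        theta = self.norm_theta(self.conv_theta(x)).reshape(b, self.n_nodes, v)
        phi = self.norm_phi(self.conv_phi(x)).reshape(b, self.n_states, v)
        vf = theta @ phi.transpose((0, 2, 1))
        return theta, phi, GraphState(vf)

    def graph_reason(self, v: GraphState) -> GraphState:
        params = GraphReasonParams(self.adjacency, self.state_weight, self.activation)
        return graph_reason(v, params)

    def graph_reproject(self, v_tilde: GraphState, theta: Tensor, x: Tensor) -> Tensor:
        b, c = x.shape[0], x.shape[1]
        spatial = x.shape[2:]
        fused = v_tilde.node_features.transpose((0, 2, 1)) @ theta  # (B, S_f, V)
        grid = fused.reshape(b, self.n_states, *spatial)
        restored = self.norm_restore(self.conv_restore(grid))
        return x + restored

    def forward(self, x: Tensor) -> Tensor:
        theta, _phi, vf = self.graph_project(x)
        v_tilde = self.graph_reason(vf)
        return self.graph_reproject(v_tilde, theta, x)


def figr_forward(x: Tensor, block: FIGR) -> Tensor:
    """Functional alias: projection -> reasoning -> reprojection with residual."""
    return block(x)
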