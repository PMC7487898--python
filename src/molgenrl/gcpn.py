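"""Graph-convolutional policy network, value head and discriminator.

Node embeddings are produced by edge-type-sliced graph convolutions: for each
bond-order slice E_i of the dense state, with Ê_i = E_i + I and D̂_i its
degree diagonal, the next embedding is the mean over slices of
ReLU(D̂_i^{-1/2} Ê_i D̂_i^{-1/2} H W_i). The state is augmented with c
edgeless "scaffold" nodes, one per addable atom type, so the second-atom head
can point at them to grow the molecule. Four MLP heads define the factorized
action distribution (first atom | existing atoms; second atom | all n+c
nodes; bond type | 3; stop | 2) and are sampled ancestrally; the composite
log-probability is the sum of the four head terms. A value MLP and a
GCN+MLP discriminator (for adversarial rewards) share the same convolution
mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem

from . import nn
from .nn import Tensor
from .molgraph import (ATOM_FDIM, DEFAULT_ATOM_TYPES, DenseState,
                       mol_to_dense)
from .mol_env import ActionVector, EnvState

__all__ = ["GCPNConfig", "normalized_slices", "gcn_layer", "PolicyNetwork",
           "Discriminator", "candidate_features"]

_PT = Chem.GetPeriodicTable()
_NEG = -1e9  # additive mask for invalid logits


@dataclass
class GCPNConfig:
    embed_dim: int = 128
    layers: int = 3
    atom_types: tuple[str, ...] = DEFAULT_ATOM_TYPES
    input_dim: int = ATOM_FDIM


def candidate_features(atom_types: tuple[str, ...], dim: int = ATOM_FDIM) -> np.ndarray:
    """One-hot element identity per addable type, padded to atom-feature width."""
    F = np.zeros((len(atom_types), dim))
    for i, sym in enumerate(atom_types):
        z = _PT.GetAtomicNumber(sym)
        F[i, z - 1 if 1 <= z <= 100 else 100] = 1.0
    return F


def normalized_slices(E: np.ndarray, n_total: int) -> list[np.ndarray]:
    """Symmetric-normalized (Ê = E_i + I) propagation matrices, zero-padded
    to ``n_total`` nodes (appended nodes are edgeless, self-loop only)."""
    n = E.shape[1]
    out = []
    for i in range(E.shape[0]):
        Et = np.eye(n_total)
        Et[:n, :n] += E[i]
        d = Et.sum(axis=1)
        dinv = 1.0 / np.sqrt(d)
        out.append(Et * dinv[:, None] * dinv[None, :])
    return out


def gcn_layer(H: Tensor, norm_slices: list[np.ndarray],
              weights: list[Tensor]) -> Tensor:
    """Mean over edge types of ReLU(M_i H W_i)."""
    parts = [nn.relu(nn.Tensor(M) @ H @ W) for M, W in zip(norm_slices, weights)]
    acc = parts[0]
    for p in parts[1:]:
        acc = acc + p
    return acc * (1.0 / len(parts))


def _mlp_params(dims: list[int], rng: np.random.Generator, prefix: str
                ) -> dict[str, Tensor]:
    p = {}
    for i, (a, b) in enumerate(zip(dims[:-1], dims[1:])):
        p[f"{prefix}W{i}"] = nn.xavier_uniform((a, b), rng)
        p[f"{prefix}b{i}"] = Tensor(np.zeros(b), requires_grad=True)
    return p


def _mlp(params: dict[str, Tensor], prefix: str, x: Tensor, n_layers: int) -> Tensor:
    for i in range(n_layers):
        x = x @ params[f"{prefix}W{i}"] + params[f"{prefix}b{i}"]
        if i < n_layers - 1:
            x = nn.relu(x)
    return x


class _GCNStack:
    """Shared convolution-stack mechanics for policy and discriminator."""

    def __init__(self, cfg: GCPNConfig, rng: np.random.Generator):
        self.cfg = cfg
        d = cfg.embed_dim
        self.params: dict[str, Tensor] = {}
        for l in range(cfg.layers):
            din = cfg.input_dim if l == 0 else d
            for i in range(3):
                self.params[f"W_conv{l}_{i}"] = nn.xavier_uniform((din, d), rng)

    def convolve(self, F: np.ndarray, E: np.ndarray, n_total: int) -> Tensor:
        slices = normalized_slices(E, n_total)
        H = Tensor(F)
        for l in range(self.cfg.layers):
            ws = [self.params[f"W_conv{l}_{i}"] for i in range(3)]
            H = gcn_layer(H, slices, ws)
        return H


class PolicyNetwork(_GCNStack):
    """Policy over graph-building actions, with a value head."""

    def __init__(self, cfg: GCPNConfig | None = None, seed: int = 0):
        cfg = cfg or GCPNConfig()
        rng = np.random.default_rng(seed)
        super().__init__(cfg, rng)
        d = cfg.embed_dim
        self.params.update(_mlp_params([d, d, 1], rng, "f_"))       # first atom
        self.params.update(_mlp_params([2 * d, d, 1], rng, "s_"))   # second atom
        self.params.update(_mlp_params([2 * d, d, 3], rng, "e_"))   # bond type
        self.params.update(_mlp_params([d, d, 2], rng, "t_"))       # stop
        self.params.update(_mlp_params([d, d, 1], rng, "v_"))       # value
        self._cand = candidate_features(cfg.atom_types, cfg.input_dim)

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    # -- embeddings --------------------------------------------------------
    def embed_state(self, state: EnvState | DenseState) -> tuple[Tensor, int]:
        """Node embeddings of the state plus the c candidate scaffold nodes.

        Returns (X, n) with X of shape (n + c, d).
        """
        dense = state.to_dense() if isinstance(state, EnvState) else state
        n = dense.n
        F = np.concatenate([dense.F, self._cand], axis=0)
        X = self.convolve(F, dense.E, n + len(self._cand))
        return X, n

    # -- heads --------------------------------------------------------------
    def head_logits(self, X: Tensor, n: int, first: int | None = None,
                    second: int | None = None):
        """Logits of the four heads (first-head masked to existing atoms)."""
        total = X.shape[0]
        mask_f = np.where(np.arange(total) < n, 0.0, _NEG)
        logits_f = _mlp(self.params, "f_", X, 2).reshape(-1) + Tensor(mask_f)
        out = {"first": logits_f}
        if first is not None:
            xf = X[np.full(total, first)]
            logits_s = _mlp(self.params, "s_", nn.concat([xf, X], axis=1), 2).reshape(-1)
            out["second"] = logits_s
            if second is not None:
                pair = nn.concat([X[[first]], X[[second]]], axis=1)
                out["edge"] = _mlp(self.params, "e_", pair, 2).reshape(-1)
        out["stop"] = _mlp(self.params, "t_", X.mean(axis=0, keepdims=True), 2).reshape(-1)
        return out

    def action_distribution(self, state: EnvState, first: int, second: int
                            ) -> dict[str, np.ndarray]:
        """The four categorical distributions for a given (first, second)."""
        X, n = self.embed_state(state)
        logits = self.head_logits(X, n, first, second)
        return {k: np.exp(nn.log_softmax(v).data) for k, v in logits.items()}

    def action_log_prob(self, state: EnvState | DenseState,
                        action: ActionVector) -> Tensor:
        """Differentiable composite log-probability (sum of the four heads)."""
        X, n = self.embed_state(state)
        logits = self.head_logits(X, n, action.first, action.second)
        lp = (nn.log_softmax(logits["first"])[[action.first]]
              + nn.log_softmax(logits["second"])[[action.second]]
              + nn.log_softmax(logits["edge"])[[action.edge]]
              + nn.log_softmax(logits["stop"])[[action.stop]])
        return lp.reshape(())

    def sample_action(self, state: EnvState, rng: np.random.Generator,
                      max_resample: int = 10) -> tuple[ActionVector, float]:
        """Ancestral sample; degenerate second==first draws are rejected and
        resampled (after ``max_resample`` tries the duplicate stands and the
        environment treats it as an invalid action)."""
        X, n = self.embed_state(state)
        logits = self.head_logits(X, n)
        p_first = np.exp(nn.log_softmax(logits["first"]).data)
        first = int(rng.choice(len(p_first), p=p_first))
        total = X.shape[0]
        xf = X.data[first]
        sec_in = Tensor(np.concatenate([np.tile(xf, (total, 1)), X.data], axis=1))
        p_second = np.exp(nn.log_softmax(
            _mlp(self.params, "s_", sec_in, 2).reshape(-1)).data)
        second = first
        for _ in range(max_resample):
            second = int(rng.choice(total, p=p_second))
            if second != first:
                break
        pair = Tensor(np.concatenate([X.data[first], X.data[second]])[None, :])
        p_edge = np.exp(nn.log_softmax(
            _mlp(self.params, "e_", pair, 2).reshape(-1)).data)
        edge = int(rng.choice(3, p=p_edge))
        p_stop = np.exp(nn.log_softmax(logits["stop"]).data)
        stop = int(rng.choice(2, p=p_stop))
        action = ActionVector(first=first, second=second, edge=edge, stop=stop)
        logp = (np.log(p_first[first]) + np.log(p_second[second])
                + np.log(p_edge[edge]) + np.log(p_stop[stop]))
        return action, float(logp)

    # -- value ---------------------------------------------------------------
    def value(self, state: EnvState | DenseState) -> Tensor:
        X, _ = self.embed_state(state)
        return _mlp(self.params, "v_", X.mean(axis=0, keepdims=True), 2).reshape(())

    # -- persistence ----------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.params.items()}

    def load_state_dict(self, d) -> None:
        for k, v in self.params.items():
            v.data = np.array(d[k], dtype=np.float64)


class Discriminator(_GCNStack):
    """GCN + feed-forward network scoring P(graph is from the expert data)."""

    def __init__(self, cfg: GCPNConfig | None = None, seed: int = 0):
        cfg = cfg or GCPNConfig()
        rng = np.random.default_rng(seed)
        super().__init__(cfg, rng)
        self.params.update(_mlp_params([cfg.embed_dim, cfg.embed_dim, 1], rng, "d_"))

    def parameters(self) -> list[Tensor]:
        return list(self.params.values())

    def score(self, graph: DenseState) -> Tensor:
        """Differentiable probability in (0, 1) that the graph is real."""
        X = self.convolve(graph.F, graph.E, graph.n)
        logit = _mlp(self.params, "d_", X.mean(axis=0, keepdims=True), 2)
        return nn.sigmoid(logit.reshape(()))

    def __call__(self, mol_or_state) -> float:
        if isinstance(mol_or_state, DenseState):
            return self.score(mol_or_state).item()
        return self.score(mol_to_dense(mol_or_state)).item()
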