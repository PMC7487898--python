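"""Directed message-passing property model.

The encoder follows the directed-MPNN convention: each directed bond (u->v)
carries a message initialized from the 147-d concatenation of the source
atom's features and the bond features, passed through a linear layer + ReLU
(depth-0). At each further depth the messages of the neighbouring incoming
bonds of u — excluding the reverse twin (v->u), configurable — are summed and
passed through a linear layer, ReLU and dropout. After depth N-1 the messages
incoming to each atom are summed, concatenated with the atom's raw features,
and transformed once more; the molecule embedding is the mean over atoms.
A feed-forward network regresses the property score (pKi scale) from the
embedding.

Training minimizes the adaptive robust negative log-likelihood over the
residuals with the shape and scale parameters trained jointly with the
weights; an ordinary L2 objective is available as a baseline twin.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import scipy.sparse as sp

from . import nn
from .nn import Tensor
from .molgraph import (ATOM_FDIM, BOND_INPUT_DIM, DirectedMolGraph,
                       smiles_to_graph)
from .robust_loss import RobustLossParams, robust_nll_op

__all__ = ["MPNNConfig", "TrainConfig", "PropertyModel", "train", "hyperopt",
           "encode", "predict"]


@dataclass
class MPNNConfig:
    depth: int = 3                 # number of message-passing depths N
    hidden_dim: int = 64           # message vector size
    ffn_layers: int = 2            # linear layers in the regressor
    dropout: float = 0.0
    include_reverse: bool = False  # include the reverse twin in aggregation

    def __post_init__(self):
        if self.depth < 1 or self.hidden_dim < 1 or self.ffn_layers < 1:
            raise ValueError("depth, hidden_dim and ffn_layers must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


@dataclass
class TrainConfig:
    batch_size: int = 50
    epochs: int = 100
    warmup_epochs: int = 2
    lr_init: float = 1e-4
    lr_max: float = 1e-3
    lr_final: float = 1e-4
    split: tuple[float, float, float] = (0.8, 0.1, 0.1)
    seed: int = 0
    loss: str = "robust"           # "robust" or "l2"

    def __post_init__(self):
        if abs(sum(self.split) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if not self.lr_init < self.lr_max:
            raise ValueError("lr_init must be below lr_max")

    def lr_at(self, epoch: int) -> float:
        """Linear warmup to lr_max, then exponential decay to lr_final."""
        if epoch < self.warmup_epochs:
            t = (epoch + 1) / self.warmup_epochs
            return self.lr_init + t * (self.lr_max - self.lr_init)
        rest = max(self.epochs - self.warmup_epochs, 1)
        r = (self.lr_final / self.lr_max) ** (1.0 / rest)
        return self.lr_max * r ** (epoch + 1 - self.warmup_epochs)


# ---------------------------------------------------------------------------
# Batched sparse graph assembly
# ---------------------------------------------------------------------------

class _Batch:
    """Concatenated graphs with sparse aggregation operators."""

    def __init__(self, graphs: list[DirectedMolGraph], include_reverse: bool):
        bond_inputs, atom_feats = [], []
        b2b_r, b2b_c = [], []
        b2a_r, b2a_c = [], []
        a2m_r, a2m_c, a2m_v = [], [], []
        a_off = b_off = 0
        for gi, g in enumerate(graphs):
            bond_inputs.append(g.bond_inputs)
            atom_feats.append(g.atom_features)
            for k in range(g.n_bonds):
                u = g.bond_src[k]
                for j in g.incoming[u]:
                    if not include_reverse and j == (k ^ 1):
                        continue
                    b2b_r.append(b_off + k)
                    b2b_c.append(b_off + j)
            for a in range(g.n_atoms):
                for j in g.incoming[a]:
                    b2a_r.append(a_off + a)
                    b2a_c.append(b_off + j)
                a2m_r.append(gi)
                a2m_c.append(a_off + a)
                a2m_v.append(1.0 / g.n_atoms)
            a_off += g.n_atoms
            b_off += g.n_bonds
        self.n_mols = len(graphs)
        self.bond_inputs = Tensor(np.concatenate(bond_inputs)
                                  if b_off else np.zeros((0, BOND_INPUT_DIM)))
        self.atom_feats = Tensor(np.concatenate(atom_feats))
        ones = np.ones(len(b2b_r))
        self.S_b2b = sp.csr_matrix((ones, (b2b_r, b2b_c)), shape=(b_off, b_off))
        self.S_b2a = sp.csr_matrix((np.ones(len(b2a_r)), (b2a_r, b2a_c)),
                                   shape=(a_off, b_off))
        self.S_a2m = sp.csr_matrix((a2m_v, (a2m_r, a2m_c)),
                                   shape=(self.n_mols, a_off))


class PropertyModel:
    """Encoder + regressor weights, robust-loss parameters and config."""

    def __init__(self, cfg: MPNNConfig, seed: int = 0, loss: str = "robust"):
        self.cfg = cfg
        self.loss_kind = loss
        self.loss_params = RobustLossParams()
        rng = np.random.default_rng(seed)
        h = cfg.hidden_dim
        p: dict[str, Tensor] = {}
        p["W_in"] = nn.xavier_uniform((BOND_INPUT_DIM, h), rng)
        p["b_in"] = Tensor(np.zeros(h), requires_grad=True)
        for l in range(cfg.depth - 1):
            p[f"W_h{l}"] = nn.xavier_uniform((h, h), rng)
            p[f"b_h{l}"] = Tensor(np.zeros(h), requires_grad=True)
        p["W_a"] = nn.xavier_uniform((ATOM_FDIM + h, h), rng)
        p["b_a"] = Tensor(np.zeros(h), requires_grad=True)
        for l in range(cfg.ffn_layers - 1):
            p[f"W_f{l}"] = nn.xavier_uniform((h, h), rng)
            p[f"b_f{l}"] = Tensor(np.zeros(h), requires_grad=True)
        p["W_out"] = nn.xavier_uniform((h, 1), rng)
        p["b_out"] = Tensor(np.zeros(1), requires_grad=True)
        self.params = p

    def parameters(self) -> list[Tensor]:
        ps = list(self.params.values())
        if self.loss_kind == "robust":
            ps += self.loss_params.parameters()
        return ps

    # -- forward ---------------------------------------------------------
    def encode_batch(self, batch: _Batch, rng: np.random.Generator | None = None
                     ) -> Tensor:
        cfg, p = self.cfg, self.params
        h = nn.relu(batch.bond_inputs @ p["W_in"] + p["b_in"])
        for l in range(cfg.depth - 1):
            m = nn.spmm(batch.S_b2b, h)
            h = nn.dropout(nn.relu(m @ p[f"W_h{l}"] + p[f"b_h{l}"]), cfg.dropout, rng)
        a_in = nn.concat([batch.atom_feats, nn.spmm(batch.S_b2a, h)], axis=1)
        a = nn.dropout(nn.relu(a_in @ p["W_a"] + p["b_a"]), cfg.dropout, rng)
        return nn.spmm(batch.S_a2m, a)

    def predict_batch(self, emb: Tensor, rng: np.random.Generator | None = None
                      ) -> Tensor:
        cfg, p = self.cfg, self.params
        z = emb
        for l in range(cfg.ffn_layers - 1):
            z = nn.dropout(nn.relu(z @ p[f"W_f{l}"] + p[f"b_f{l}"]), cfg.dropout, rng)
        return (z @ p["W_out"] + p["b_out"]).reshape(-1)

    def forward_graphs(self, graphs: list[DirectedMolGraph],
                       rng: np.random.Generator | None = None) -> Tensor:
        batch = _Batch(graphs, self.cfg.include_reverse)
        return self.predict_batch(self.encode_batch(batch, rng), rng)

    def predict_smiles(self, smiles: str | list[str]) -> float | np.ndarray:
        single = isinstance(smiles, str)
        graphs = [smiles_to_graph(s) for s in ([smiles] if single else smiles)]
        out = self.forward_graphs(graphs).data
        return float(out[0]) if single else out

    def predict_mol(self, mol) -> float:
        from .molgraph import mol_to_graph
        return float(self.forward_graphs([mol_to_graph(mol)]).data[0])

    def __call__(self, mol_or_smiles) -> float:
        if isinstance(mol_or_smiles, str):
            return self.predict_smiles(mol_or_smiles)
        return self.predict_mol(mol_or_smiles)

    # -- persistence -------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        d = {k: v.data.copy() for k, v in self.params.items()}
        d["alpha_latent"] = self.loss_params.alpha_latent.data.copy()
        d["scale_latent"] = self.loss_params.scale_latent.data.copy()
        return d

    def load_state_dict(self, d: dict[str, np.ndarray]) -> None:
        for k, v in self.params.items():
            v.data = np.array(d[k], dtype=np.float64)
        self.loss_params.alpha_latent.data = np.array(d["alpha_latent"])
        self.loss_params.scale_latent.data = np.array(d["scale_latent"])

    def save(self, path: str) -> None:
        meta = {"format": "molgenrl-propmodel-v1", "loss": self.loss_kind,
                "config": asdict(self.cfg)}
        np.savez(path, __meta__=np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8), **self.state_dict())

    @classmethod
    def load(cls, path: str) -> "PropertyModel":
        with np.load(path if str(path).endswith(".npz") else str(path) + ".npz") as z:
            meta = json.loads(bytes(z["__meta__"]).decode())
            model = cls(MPNNConfig(**meta["config"]), loss=meta["loss"])
            model.load_state_dict({k: z[k] for k in z.files if k != "__meta__"})
        return model


def encode(graph: DirectedMolGraph, model: PropertyModel) -> np.ndarray:
    """Molecule embedding of one graph (evaluation mode)."""
    return model.encode_batch(_Batch([graph], model.cfg.include_reverse)).data[0]


def predict(embedding: np.ndarray, model: PropertyModel) -> float:
    """Property score from an embedding (evaluation mode)."""
    return float(model.predict_batch(Tensor(np.atleast_2d(embedding))).data[0])


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

def _rmse(model: PropertyModel, graphs, targets) -> float:
    if not graphs:
        return float("nan")
    preds = model.forward_graphs(graphs).data
    return float(np.sqrt(np.mean((preds - targets) ** 2)))


def _split_indices(n: int, fractions, rng: np.random.Generator):
    idx = rng.permutation(n)
    n_train = int(round(fractions[0] * n))
    n_val = int(round(fractions[1] * n))
    return idx[:n_train], idx[n_train:n_train + n_val], idx[n_train + n_val:]


def train(dataset: pd.DataFrame, mpnn_cfg: MPNNConfig | None = None,
          train_cfg: TrainConfig | None = None,
          splits: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
          ) -> tuple[PropertyModel, pd.DataFrame]:
    """Train a property model; returns the best-validation checkpoint.

    ``dataset`` needs ``smiles`` and ``target`` columns (>= 10 rows). The
    data is split 80/10/10 by the config seed unless explicit index
    ``splits`` are given. The learning rate warms up linearly then decays
    exponentially to its final value at the last epoch; the model is
    checkpointed whenever the validation RMSE improves and the returned
    weights are the best-validation ones. Per-epoch train/val/test RMSE (and
    the current alpha and c for the robust loss) are returned as a frame.
    """
    mpnn_cfg = mpnn_cfg or MPNNConfig()
    cfg = train_cfg or TrainConfig()
    if len(dataset) < 10:
        raise ValueError("dataset must contain at least 10 molecules")
    targets = dataset["target"].to_numpy(dtype=float)
    if not np.all(np.isfinite(targets)):
        raise ValueError("labels must be finite")
    graphs = [smiles_to_graph(s) for s in dataset["smiles"]]
    rng = np.random.default_rng(cfg.seed)
    if splits is None:
        tr, va, te = _split_indices(len(graphs), cfg.split, rng)
    else:
        tr, va, te = (np.asarray(s) for s in splits)
    if len(tr) == 0 or len(va) == 0:
        raise ValueError("empty train or validation split")

    model = PropertyModel(mpnn_cfg, seed=cfg.seed, loss=cfg.loss)
    opt = nn.Adam(model.parameters(), lr=cfg.lr_init)
    drop_rng = np.random.default_rng(cfg.seed + 1)

    g_tr = [graphs[i] for i in tr]
    y_tr = targets[tr]
    g_va, y_va = [graphs[i] for i in va], targets[va]
    g_te, y_te = [graphs[i] for i in te], targets[te]

    best_val = math.inf
    best_state = model.state_dict()
    rows = []
    for epoch in range(cfg.epochs):
        opt.lr = cfg.lr_at(epoch)
        order = rng.permutation(len(g_tr))
        epoch_loss = 0.0
        for start in range(0, len(order), cfg.batch_size):
            bidx = order[start:start + cfg.batch_size]
            preds = model.forward_graphs([g_tr[i] for i in bidx], rng=drop_rng)
            res = preds - Tensor(y_tr[bidx])
            if cfg.loss == "robust":
                loss = robust_nll_op(res, model.loss_params.alpha(),
                                     model.loss_params.c()).sum()
            else:
                loss = ((res * res) * 0.5).sum()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += loss.item()
        alpha, c = model.loss_params.values()
        row = {"epoch": epoch, "loss": epoch_loss, "lr": opt.lr,
               "train_rmse": _rmse(model, g_tr, y_tr),
               "val_rmse": _rmse(model, g_va, y_va),
               "test_rmse": _rmse(model, g_te, y_te),
               "alpha": alpha, "c": c}
        rows.append(row)
        if row["val_rmse"] < best_val:
            best_val = row["val_rmse"]
            best_state = model.state_dict()
    model.load_state_dict(best_state)
    return model, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Bayesian hyperparameter optimization (10-fold CV)
# ---------------------------------------------------------------------------

def _cv_score(dataset: pd.DataFrame, cfg_dict: dict, base_cfg: TrainConfig,
              n_folds: int, seed: int) -> float:
    from sklearn.model_selection import KFold

    mp = MPNNConfig(**cfg_dict)
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = []
    idx = np.arange(len(dataset))
    for tr, va in kf.split(idx):
        cfg = TrainConfig(**{**asdict(base_cfg), "seed": seed})
        # fold's validation set doubles as the checkpoint-selection split
        model, hist = train(dataset, mp, cfg, splits=(tr, va, np.array([], int)))
        graphs = [smiles_to_graph(s) for s in dataset["smiles"].iloc[va]]
        scores.append(_rmse(model, graphs, dataset["target"].to_numpy()[va]))
    return float(np.mean(scores))


def hyperopt(dataset: pd.DataFrame, search_space: dict[str, list],
             budget: int, base_cfg: TrainConfig | None = None,
             n_folds: int = 10, seed: int = 0,
             test_fraction: float = 0.1):
    """Sequential model-based (Bayesian) search over MPNN hyperparameters.

    A test fraction is held out before cross-validation; the model score is
    the mean validation RMSE over ``n_folds`` folds of the remainder. A
    Gaussian-process surrogate (Matern kernel) with an expected-improvement
    acquisition proposes configurations after an initial random design.
    Returns ``(best_config, best_score, history)``.
    """
    from itertools import product

    from sklearn.gaussian_process import GaussianProcessRegressor
    from sklearn.gaussian_process.kernels import Matern

    if budget < 2:
        raise ValueError("hyperopt budget must be at least 2 evaluations")
    base_cfg = base_cfg or TrainConfig(epochs=20)
    rng = np.random.default_rng(seed)

    n = len(dataset)
    test_idx = rng.choice(n, size=int(round(test_fraction * n)), replace=False)
    cv_mask = np.ones(n, dtype=bool)
    cv_mask[test_idx] = False
    cv_data = dataset[cv_mask].reset_index(drop=True)

    keys = sorted(search_space)
    candidates = [dict(zip(keys, vals)) for vals in product(*(search_space[k] for k in keys))]
    if not candidates:
        raise ValueError("empty search space")

    def to_vec(c):
        return np.array([
            (candidates_vals[k].index(c[k])) / max(len(candidates_vals[k]) - 1, 1)
            for k in keys])

    candidates_vals = {k: list(search_space[k]) for k in keys}
    X_all = np.array([to_vec(c) for c in candidates])

    evaluated: dict[int, float] = {}
    history = []
    order = rng.permutation(len(candidates))
    n_init = min(max(2, budget // 3), budget, len(candidates))
    queue = list(order[:n_init])
    while len(evaluated) < min(budget, len(candidates)):
        if queue:
            i = queue.pop(0)
        else:
            gp = GaussianProcessRegressor(kernel=Matern(nu=2.5),
                                          normalize_y=True, alpha=1e-6)
            done = sorted(evaluated)
            gp.fit(X_all[done], np.array([evaluated[j] for j in done]))
            todo = [j for j in range(len(candidates)) if j not in evaluated]
            mu, sd = gp.predict(X_all[todo], return_std=True)
            best = min(evaluated.values())
            sd = np.maximum(sd, 1e-12)
            from scipy.stats import norm
            z = (best - mu) / sd
            ei = (best - mu) * norm.cdf(z) + sd * norm.pdf(z)
            i = todo[int(np.argmax(ei))]
        if i in evaluated:
            continue
        score = _cv_score(cv_data, candidates[i], base_cfg, n_folds,
                          seed=int(rng.integers(2 ** 31)))
        evaluated[i] = score
        history.append({**candidates[i], "score": score})
    best_i = min(evaluated, key=evaluated.get)
    return candidates[best_i], evaluated[best_i], pd.DataFrame(history)
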