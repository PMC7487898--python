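"""Policy-gradient training of the molecule generator.

Proximal policy optimization with a clipped probability-ratio surrogate,
advantages from generalized advantage estimation, a value-regression head,
an adversarial reward derived from a discriminator trained to separate
expert molecules from generated ones, and expert imitation on randomly
grown subgraph/action pairs. The trainer is correct and monotonically
improving at desk scale; large-scale runs only change the configured sizes.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from rdkit import Chem

from . import nn
from .nn import Tensor
from .gcpn import Discriminator, PolicyNetwork
from .mol_env import ActionVector, EnvState, MoleculeEnv
from .molgraph import DEFAULT_ATOM_TYPES, mol_to_dense, smiles_to_mol

logger = logging.getLogger(__name__)

__all__ = ["PPOConfig", "Trajectory", "ExpertPair", "gae", "ppo_objective",
           "adversarial_term", "discriminator_loss", "sample_expert_pair",
           "expert_loss", "pretrain_expert", "train"]

_BOND_ORDERS = (Chem.BondType.SINGLE, Chem.BondType.DOUBLE, Chem.BondType.TRIPLE)


@dataclass
class PPOConfig:
    clip_eps: float = 0.2
    gamma: float = 0.99
    gae_lambda: float = 0.95
    lr: float = 1e-3
    lr_final: float = 0.0
    iterations: int = 30
    episodes_per_iter: int = 16
    ppo_epochs: int = 4
    value_coef: float = 0.5
    expert_weight: float = 0.0
    expert_decay_iters: int = 0   # linear decay horizon for expert_weight
    expert_pairs_per_update: int = 8
    advantage_bound: float = 1e3  # divergence guard on mean |advantage|
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.clip_eps < 1.0:
            raise ValueError("clip epsilon must be in (0, 1)")
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must be in (0, 1]")
        if not 0.0 <= self.gae_lambda <= 1.0:
            raise ValueError("lambda must be in [0, 1]")


@dataclass
class Trajectory:
    states: list[EnvState] = field(default_factory=list)
    actions: list[ActionVector] = field(default_factory=list)
    log_probs: list[float] = field(default_factory=list)
    rewards: list[float] = field(default_factory=list)
    values: list[float] = field(default_factory=list)
    terminal: bool = False
    final_state: EnvState | None = None
    final_breakdown: object = None

    def __len__(self) -> int:
        return len(self.actions)


@dataclass
class ExpertPair:
    """A subgraph state and the single growth action toward the parent graph."""

    state: EnvState
    action: ActionVector


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

def gae(rewards, values, gamma: float, lam: float) -> np.ndarray:
    """Generalized advantage estimates.

    ``values`` must have one more entry than ``rewards`` (the bootstrap value
    of the state after the last step; 0 for terminal states). Computes
    delta_t = r_t + gamma*V(s_{t+1}) - V(s_t) and the exponentially weighted
    sum A_t = sum_k (gamma*lam)^k delta_{t+k}.
    """
    rewards = np.asarray(rewards, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape[0] != rewards.shape[0] + 1:
        raise ValueError("values must be one longer than rewards (bootstrap)")
    deltas = rewards + gamma * values[1:] - values[:-1]
    adv = np.empty_like(deltas)
    acc = 0.0
    for t in range(len(deltas) - 1, -1, -1):
        acc = deltas[t] + gamma * lam * acc
        adv[t] = acc
    return adv


def ppo_objective(logp_new, logp_old, advantages, clip_eps: float = 0.2):
    """Per-step clipped surrogate min(r*A, clip(r, 1-eps, 1+eps)*A), to be
    maximized; ``logp_new`` may be a Tensor (differentiable) or an array."""
    lp_new = logp_new if isinstance(logp_new, Tensor) else Tensor(np.asarray(logp_new, float))
    lp_old = np.asarray(logp_old.data if isinstance(logp_old, Tensor) else logp_old, float)
    adv = np.asarray(advantages, dtype=float)
    ratio = nn.exp(lp_new - Tensor(lp_old))
    unclipped = ratio * adv
    clipped = nn.clip(ratio, 1.0 - clip_eps, 1.0 + clip_eps) * adv
    return nn.minimum(unclipped, clipped)


def adversarial_term(d_prob: float, clamp: float = 1e-6) -> float:
    """Generator-side adversarial reward -log(1 - D(x)); monotone in D."""
    d = min(max(d_prob, clamp), 1.0 - clamp)
    return -math.log(1.0 - d)


def discriminator_loss(disc: Discriminator, real_states, fake_states) -> Tensor:
    """Mean binary cross-entropy of expert (real) vs generated (fake) graphs."""
    eps = 1e-6
    terms = []
    for s in real_states:
        d = nn.clip(disc.score(s), eps, 1 - eps)
        terms.append(-nn.log(d))
    for s in fake_states:
        d = nn.clip(disc.score(s), eps, 1 - eps)
        terms.append(-nn.log(1.0 - d))
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return acc * (1.0 / len(terms))


# ---------------------------------------------------------------------------
# Expert imitation
# ---------------------------------------------------------------------------

def _induced_submol(mol: Chem.Mol, atoms: list[int]) -> Chem.Mol:
    amap = {a: i for i, a in enumerate(atoms)}
    rw = Chem.RWMol()
    for a in atoms:
        src = mol.GetAtomWithIdx(a)
        at = Chem.Atom(src.GetSymbol())
        at.SetFormalCharge(src.GetFormalCharge())
        rw.AddAtom(at)
    for b in mol.GetBonds():
        u, v = b.GetBeginAtomIdx(), b.GetEndAtomIdx()
        if u in amap and v in amap:
            rw.AddBond(amap[u], amap[v], b.GetBondType())
    sub = rw.GetMol()
    Chem.SanitizeMol(sub)
    Chem.Kekulize(sub, clearAromaticFlags=True)
    return sub


def sample_expert_pair(mol: Chem.Mol, rng: np.random.Generator,
                       atom_types: tuple[str, ...] = DEFAULT_ATOM_TYPES
                       ) -> ExpertPair:
    """Random connected subgraph of an expert molecule plus one frontier
    growth action (applying the action keeps the result a subgraph of the
    parent). Single-atom molecules yield a stop-action pair."""
    mol = Chem.Mol(mol)
    Chem.Kekulize(mol, clearAromaticFlags=True)
    n = mol.GetNumAtoms()
    if n < 2:
        state = EnvState(mol=mol, steps=0, done=False)
        return ExpertPair(state=state, action=ActionVector(0, 0, 0, stop=1))
    size = int(rng.integers(1, n))
    start = int(rng.integers(n))
    chosen = [start]
    chosen_set = {start}
    while len(chosen) < size:
        frontier = [nb.GetIdx()
                    for a in chosen
                    for nb in mol.GetAtomWithIdx(a).GetNeighbors()
                    if nb.GetIdx() not in chosen_set]
        if not frontier:
            break
        nxt = frontier[int(rng.integers(len(frontier)))]
        chosen.append(nxt)
        chosen_set.add(nxt)
    amap = {a: i for i, a in enumerate(chosen)}
    # frontier bonds: one endpoint inside the subgraph, one outside
    fbonds = [b for b in mol.GetBonds()
              if (b.GetBeginAtomIdx() in chosen_set) != (b.GetEndAtomIdx() in chosen_set)]
    bond = fbonds[int(rng.integers(len(fbonds)))]
    u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
    if u not in chosen_set:
        u, v = v, u
    sym = mol.GetAtomWithIdx(v).GetSymbol()
    if sym not in atom_types:
        raise ValueError(f"expert molecule uses element {sym!r} outside the atom menu")
    sub = _induced_submol(mol, chosen)
    action = ActionVector(first=amap[u],
                          second=len(chosen) + atom_types.index(sym),
                          edge=_BOND_ORDERS.index(bond.GetBondType()),
                          stop=0)
    state = EnvState(mol=sub, steps=0, done=False)
    return ExpertPair(state=state, action=action)


def expert_loss(policy: PolicyNetwork, pairs: list[ExpertPair]) -> Tensor:
    """Mean negative composite log-probability of the expert actions."""
    if not pairs:
        raise ValueError("expert pairs must be non-empty")
    terms = []
    for pair in pairs:
        lp = policy.action_log_prob(pair.state, pair.action)
        if lp.item() < -40:
            logger.warning("near-zero expert action probability (logp=%.1f)", lp.item())
        terms.append(-lp)
    acc = terms[0]
    for t in terms[1:]:
        acc = acc + t
    return acc * (1.0 / len(terms))


def pretrain_expert(policy: PolicyNetwork, expert_smiles: list[str],
                    updates: int, seed: int = 0, lr: float = 1e-3,
                    pairs_per_update: int = 8) -> list[float]:
    """Imitation-only pretraining; returns the per-update expert loss."""
    rng = np.random.default_rng(seed)
    mols = [smiles_to_mol(s) for s in expert_smiles]
    opt = nn.Adam(policy.parameters(), lr=lr)
    losses = []
    for _ in range(updates):
        pairs = [sample_expert_pair(mols[int(rng.integers(len(mols)))], rng,
                                    policy.cfg.atom_types)
                 for _ in range(pairs_per_update)]
        loss = expert_loss(policy, pairs)
        opt.zero_grad()
        loss.backward()
        opt.step()
        losses.append(loss.item())
    return losses


# ---------------------------------------------------------------------------
# Episode collection & the training loop
# ---------------------------------------------------------------------------

def collect_episode(env: MoleculeEnv, policy: PolicyNetwork,
                    rng: np.random.Generator, init: str = "C") -> Trajectory:
    traj = Trajectory()
    state = env.reset(init)
    while not state.done:
        action, logp = policy.sample_action(state, rng)
        value = policy.value(state).item()
        nxt, reward, done, info = env.step(state, action)
        traj.states.append(state)
        traj.actions.append(action)
        traj.log_probs.append(logp)
        traj.rewards.append(reward)
        traj.values.append(value)
        if done:
            traj.final_breakdown = info.get("breakdown")
        state = nxt
    traj.terminal = True
    traj.final_state = state
    return traj


def train(env: MoleculeEnv, policy: PolicyNetwork,
          discriminator: Discriminator | None = None,
          expert_smiles: list[str] | None = None,
          cfg: PPOConfig | None = None,
          init: str = "C",
          log_path: str | None = None):
    """Alternating PPO / discriminator training loop.

    Per iteration: collect episodes, estimate advantages with GAE, run
    several PPO epochs on the clipped surrogate plus value regression plus
    (optionally decaying) expert-imitation loss, then update the
    discriminator on expert-vs-generated batches. The learning rate decays
    linearly across iterations. Returns (policy, log frame) where the log
    carries mean episode reward and the validity rate per iteration.
    """
    import pandas as pd

    cfg = cfg or PPOConfig()
    rng = np.random.default_rng(cfg.seed)
    use_adversarial = (discriminator is not None
                       and env.cfg.adversarial_weight != 0.0)
    if use_adversarial:
        env.discriminator = discriminator
    use_expert = cfg.expert_weight > 0.0 and expert_smiles
    expert_mols = [smiles_to_mol(s) for s in (expert_smiles or [])]

    opt = nn.Adam(policy.parameters(), lr=cfg.lr)
    d_opt = nn.Adam(discriminator.parameters(), lr=cfg.lr) if use_adversarial else None

    logs = []
    episode_records = []
    for it in range(cfg.iterations):
        frac = it / max(cfg.iterations - 1, 1)
        opt.lr = cfg.lr + frac * (cfg.lr_final - cfg.lr)
        if cfg.expert_decay_iters > 0:
            ew = cfg.expert_weight * max(0.0, 1.0 - it / cfg.expert_decay_iters)
        else:
            ew = cfg.expert_weight

        trajs = [collect_episode(env, policy, rng, init=init)
                 for _ in range(cfg.episodes_per_iter)]

        steps, advs, rets = [], [], []
        for tr in trajs:
            values = np.array(tr.values + [0.0])  # terminal bootstrap
            a = gae(tr.rewards, values, cfg.gamma, cfg.gae_lambda)
            advs.append(a)
            rets.append(a + values[:-1])
            steps += list(zip(tr.states, tr.actions, tr.log_probs))
        adv = np.concatenate(advs)
        ret = np.concatenate(rets)
        if np.mean(np.abs(adv)) > cfg.advantage_bound:
            raise RuntimeError("advantage estimates diverged; aborting training")
        adv_n = (adv - adv.mean()) / (adv.std() + 1e-8)

        for _ in range(cfg.ppo_epochs):
            lps = [policy.action_log_prob(s, a) for s, a, _ in steps]
            lp_new = nn.concat([lp.reshape(1) for lp in lps])
            lp_old = np.array([lp for _, _, lp in steps])
            surrogate = ppo_objective(lp_new, lp_old, adv_n, cfg.clip_eps).mean()
            vals = nn.concat([policy.value(s).reshape(1) for s, _, _ in steps])
            v_loss = ((vals - Tensor(ret)) ** 2).mean() * cfg.value_coef
            loss = -surrogate + v_loss
            if use_expert and ew > 0:
                pairs = [sample_expert_pair(
                    expert_mols[int(rng.integers(len(expert_mols)))], rng,
                    policy.cfg.atom_types)
                    for _ in range(cfg.expert_pairs_per_update)]
                loss = loss + ew * expert_loss(policy, pairs)
            opt.zero_grad()
            loss.backward()
            opt.step()

        if use_adversarial:
            k = min(len(trajs), len(expert_mols)) or len(trajs)
            real = [mol_to_dense(expert_mols[int(rng.integers(len(expert_mols)))])
                    for _ in range(k)] if expert_mols else []
            fake = [tr.final_state.to_dense() for tr in trajs[:k]]
            if real and fake:
                d_loss = discriminator_loss(discriminator, real, fake)
                d_opt.zero_grad()
                d_loss.backward()
                d_opt.step()

        totals, n_valid = [], 0
        for tr in trajs:
            totals.append(float(np.sum(tr.rewards)))
            smi = tr.final_state.smiles()
            mol = Chem.MolFromSmiles(smi)
            valid = mol is not None
            n_valid += valid
            bd = tr.final_breakdown
            rec = {
                "iteration": it, "smiles": smi, "reward": totals[-1],
                "steps": len(tr), "valid": bool(valid),
                "breakdown": dict(bd.parts) if bd is not None else {},
            }
            if valid:
                from rdkit.Chem import QED
                from .mol_env import sa_norm as _sa
                rec["qed"] = float(QED.qed(mol))
                rec["sa_norm"] = float(_sa(mol))
            episode_records.append(rec)
        logs.append({"iteration": it, "mean_reward": float(np.mean(totals)),
                     "validity": n_valid / len(trajs), "lr": opt.lr,
                     "expert_weight": ew})

    if log_path is not None:
        with open(log_path, "w") as fh:
            for rec in episode_records:
                fh.write(json.dumps(rec) + "\n")
    return policy, pd.DataFrame(logs), episode_records
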