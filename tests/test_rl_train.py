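"""PPO/GAE estimators, adversarial terms, expert imitation, training loop."""

import math

import numpy as np
import pytest
from rdkit import Chem

from molgenrl import nn
from molgenrl.gcpn import Discriminator, GCPNConfig, PolicyNetwork
from molgenrl.mol_env import ActionVector, MoleculeEnv, RewardConfig
from molgenrl.molgraph import canonical, smiles_to_dense, smiles_to_mol
from molgenrl.rl_train import (PPOConfig, adversarial_term, collect_episode,
                               discriminator_loss, expert_loss, gae,
                               ppo_objective, pretrain_expert,
                               sample_expert_pair, train)


def _gae_double_sum(rewards, values, gamma, lam):
    """Independent brute-force O(T^2) evaluation of the weighted delta sum."""
    T = len(rewards)
    deltas = [rewards[t] + gamma * values[t + 1] - values[t] for t in range(T)]
    return np.array([sum((gamma * lam) ** k * deltas[t + k]
                         for k in range(T - t)) for t in range(T)])


def test_gae_lambda_zero_is_td_error():
    r = np.array([1.0, 2.0, 3.0])
    v = np.array([0.5, 1.0, 0.2, 0.0])
    adv = gae(r, v, gamma=0.9, lam=0.0)
    deltas = r + 0.9 * v[1:] - v[:-1]
    assert np.allclose(adv, deltas)


def test_gae_lambda_one_gamma_one_telescopes_to_return_minus_value():
    r = np.array([1.0, -2.0, 0.5, 4.0])
    v = np.array([0.3, 0.1, -0.2, 0.7, 0.0])
    adv = gae(r, v, gamma=1.0, lam=1.0)
    returns = np.cumsum(r[::-1])[::-1]
    assert np.allclose(adv, returns - v[:-1])


def test_gae_hand_case():
    adv = gae([1.0, 1.0], [0.0, 0.0, 0.0], gamma=0.5, lam=0.5)
    # deltas = [1, 1]; A_0 = 1 + 0.25*1, A_1 = 1
    assert np.allclose(adv, [1.25, 1.0])


def test_gae_matches_double_sum_on_random_trajectories(rng):
    for _ in range(20):
        T = 10
        r = rng.normal(size=T)
        v = np.concatenate([rng.normal(size=T), [0.0]])
        g, l = rng.uniform(0.5, 1.0), rng.uniform(0.0, 1.0)
        assert np.allclose(gae(r, v, g, l), _gae_double_sum(r, v, g, l),
                           atol=1e-10)


def test_gae_length_mismatch():
    with pytest.raises(ValueError):
        gae([1.0], [0.0], 0.9, 0.9)


def test_ppo_ratio_one_returns_advantage():
    out = ppo_objective(np.log(0.3), np.log(0.3), 2.5, clip_eps=0.2)
    assert out.item() == pytest.approx(2.5)


@pytest.mark.parametrize("adv,ratio,expected", [
    (2.0, 1.4, (1 + 0.2) * 2.0),    # positive advantage, ratio above clip
    (-2.0, 0.6, (1 - 0.2) * -2.0),  # negative advantage, ratio below clip
])
def test_ppo_clip_branches(adv, ratio, expected):
    out = ppo_objective(math.log(ratio), 0.0, adv, clip_eps=0.2)
    assert out.item() == pytest.approx(expected)


def test_ppo_gradient_zero_in_clipped_region():
    lp = nn.Tensor(np.array([math.log(1.5)]), requires_grad=True)
    ppo_objective(lp, np.array([0.0]), np.array([1.0]), clip_eps=0.2).sum().backward()
    assert lp.grad[0] == 0.0
    lp2 = nn.Tensor(np.array([0.0]), requires_grad=True)
    ppo_objective(lp2, np.array([0.0]), np.array([1.0]), clip_eps=0.2).sum().backward()
    assert lp2.grad[0] != 0.0


def test_adversarial_term_values():
    assert adversarial_term(0.5) == pytest.approx(math.log(2), abs=1e-9)
    assert adversarial_term(0.999999) > adversarial_term(0.9) > adversarial_term(0.5)


def test_discriminator_loss_at_half_is_log4_per_pair():
    disc = Discriminator(GCPNConfig(embed_dim=6, layers=1), seed=0)
    for k, p in disc.params.items():
        if k.startswith("d_"):
            p.data[:] = 0.0  # forces D = 0.5 everywhere
    real = [smiles_to_dense("CCO")]
    fake = [smiles_to_dense("CCC")]
    loss = discriminator_loss(disc, real, fake)
    assert loss.item() == pytest.approx(math.log(4) / 2)  # mean over 2 terms


def test_expert_pair_ethane_only_choice(rng):
    pair = sample_expert_pair(smiles_to_mol("CC"), rng)
    assert pair.state.n == 1
    assert pair.action.stop == 0
    assert pair.action.first == 0
    assert pair.action.second == 1 + 0  # new atom, menu type C
    assert pair.action.edge == 0


def test_expert_action_applied_yields_subgraph_of_parent(rng):
    """Applying the expert action must produce a substructure of the parent."""
    env = MoleculeEnv(RewardConfig(max_heavy_atoms=25,
                                   strain_threshold=float("inf")))
    for smiles in ("CCO", "c1ccccc1", "CC(=O)Nc1ccccc1", "CN1CCC(O)CC1"):
        parent = smiles_to_mol(smiles)
        for _ in range(10):
            pair = sample_expert_pair(parent, rng)
            nxt, _, _, _ = env.step(pair.state, pair.action)
            assert nxt.n == pair.state.n + 1
            kek = Chem.Mol(parent)
            Chem.Kekulize(kek, clearAromaticFlags=True)
            assert kek.HasSubstructMatch(nxt.mol)


def test_expert_pairs_cover_every_frontier_of_path_graph(rng):
    """On a path graph every frontier bond is reachable over many draws."""
    seen = set()
    mol = smiles_to_mol("CCCCC")
    for _ in range(1000):
        pair = sample_expert_pair(mol, rng)
        seen.add((pair.state.n, pair.action.first))
    # for sub-path of size k, growth can happen at either end (or one if at
    # the boundary); sizes 1..4 are all reachable
    assert {n for n, _ in seen} == {1, 2, 3, 4}
    assert (4, 0) in seen and (4, 3) in seen


def test_single_atom_expert_molecule_gives_stop_pair(rng):
    pair = sample_expert_pair(smiles_to_mol("C"), rng)
    assert pair.action.stop == 1


def test_expert_loss_uniform_policy_bound(rng):
    """Uniform heads: composite logp is the sum of the four uniform terms."""
    pol = PolicyNetwork(GCPNConfig(embed_dim=8, layers=1), seed=0)
    for k, p in pol.params.items():
        if k[:2] in ("f_", "s_", "e_", "t_"):
            p.data[:] = 0.0
    pair = sample_expert_pair(smiles_to_mol("CC"), rng)
    loss = expert_loss(pol, [pair])
    want = math.log(1) + math.log(10) + math.log(3) + math.log(2)  # n=1, c=9
    assert loss.item() == pytest.approx(want, rel=1e-9)
    assert loss.item() >= 0.0


def test_expert_loss_requires_pairs():
    pol = PolicyNetwork(GCPNConfig(embed_dim=8, layers=1), seed=0)
    with pytest.raises(ValueError):
        expert_loss(pol, [])


def test_expert_pretraining_halves_loss():
    """200 imitation updates reduce the expert loss by at least 50%."""
    from molgenrl.synthetic import make_expert_set
    expert = make_expert_set(20, seed=7)
    pol = PolicyNetwork(GCPNConfig(embed_dim=16, layers=2), seed=0)
    losses = pretrain_expert(pol, expert, updates=200, seed=0, lr=1e-3)
    start = np.mean(losses[:10])
    end = np.mean(losses[-10:])
    assert end <= 0.5 * start


def test_collect_episode_terminates_and_aligns(rng):
    env = MoleculeEnv(RewardConfig(max_heavy_atoms=6,
                                   strain_threshold=float("inf")))
    pol = PolicyNetwork(GCPNConfig(embed_dim=8, layers=1), seed=0)
    tr = collect_episode(env, pol, rng)
    assert tr.terminal
    assert len(tr.actions) == len(tr.rewards) == len(tr.values) == len(tr.states)
    assert tr.final_state.done


def test_adversarial_off_equals_no_discriminator():
    """With adversarial weight 0 the reward reduces to plain PPO rewards."""
    cfg = RewardConfig(max_heavy_atoms=6, adversarial_weight=0.0,
                       strain_threshold=float("inf"))
    env_plain = MoleculeEnv(cfg)
    env_disc = MoleculeEnv(cfg, discriminator=Discriminator(
        GCPNConfig(embed_dim=8, layers=1), seed=0))
    mol = smiles_to_mol("CCO")
    bd1, bd2 = env_plain.final_reward(mol), env_disc.final_reward(mol)
    assert bd1.parts == bd2.parts
    assert "adversarial" not in bd1.parts


def test_training_loop_runs_and_logs_valid_molecules():
    env = MoleculeEnv(RewardConfig(max_heavy_atoms=6,
                                   strain_threshold=float("inf")))
    pol = PolicyNetwork(GCPNConfig(embed_dim=12, layers=2), seed=0)
    disc = Discriminator(GCPNConfig(embed_dim=12, layers=2), seed=1)
    from molgenrl.synthetic import make_expert_set
    _, logs, records = train(
        env, pol, discriminator=disc, expert_smiles=make_expert_set(10, seed=1),
        cfg=PPOConfig(iterations=3, episodes_per_iter=4, ppo_epochs=2,
                      expert_weight=0.1, seed=0))
    assert len(logs) == 3
    assert all(r["valid"] for r in records)
    assert all(canonical(r["smiles"]) for r in records)
    assert (logs["validity"] == 1.0).all()
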