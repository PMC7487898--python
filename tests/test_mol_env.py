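"""Molecule-building environment: dynamics, chemistry checks, rewards."""

import math

import numpy as np
import pytest
from rdkit import Chem

from molgenrl.mol_env import (ActionVector, MoleculeEnv, RewardConfig,
                              load_filter_catalog, sa_norm, strain_ok,
                              valence_ok, zinc_filter_ok)
from molgenrl.molgraph import smiles_to_dense, smiles_to_mol
from molgenrl.synthetic import toy_oracle


@pytest.fixture()
def env():
    return MoleculeEnv(RewardConfig(max_heavy_atoms=10,
                                    strain_threshold=float("inf")))


def test_reset_single_carbon(env):
    s = env.reset("C")
    assert s.n == 1 and s.steps == 0 and not s.done


def test_reset_seed_molecule_kekulized(env):
    s = env.reset("c1ccccc1")
    assert s.n == 6
    dense = s.to_dense()
    dense.validate()
    # kekulized benzene: three single + three double bonds
    assert dense.E[0].sum() == 6 and dense.E[1].sum() == 6


def test_reset_oversized_seed_rejected(env):
    with pytest.raises(ValueError, match="cap"):
        env.reset("C" * 20)  # 20 heavy atoms > cap 10


def test_reset_invalid_seed(env):
    with pytest.raises(ValueError):
        env.reset("xyz")


def test_growth_step_adds_atom_and_bonus(env):
    s = env.reset("C")
    nxt, r, done, _ = env.step(s, ActionVector(first=0, second=s.n, edge=0, stop=0))
    assert nxt.smiles() == "CC"
    assert r == env.cfg.step_valid_bonus
    assert not done
    assert s.n == 1  # original state untouched


def test_overvalent_action_leaves_state_unchanged(env):
    s = env.reset("C(C)(C)(C)C")  # neopentane: central carbon saturated
    before = s.smiles()
    nxt, r, done, _ = env.step(s, ActionVector(first=0, second=s.n, edge=0, stop=0))
    assert nxt.smiles() == before and r == 0.0


def test_stop_action_triggers_final_reward(env):
    s = env.reset("CCO")
    nxt, r, done, info = env.step(s, ActionVector(first=0, second=1, edge=0, stop=1))
    assert done and nxt.done
    assert "breakdown" in info
    assert r == pytest.approx(info["breakdown"].total)


def test_step_on_done_state_is_usage_error(env):
    s = env.reset("C")
    nxt, *_ = env.step(s, ActionVector(0, 0, 0, stop=1))
    with pytest.raises(RuntimeError):
        env.step(nxt, ActionVector(0, 1, 0, 0))


def test_atom_cap_terminates_and_respects_limit():
    env = MoleculeEnv(RewardConfig(max_heavy_atoms=4,
                                   strain_threshold=float("inf")))
    s = env.reset("C")
    grown = 0
    while not s.done:
        s, _, done, _ = env.step(s, ActionVector(first=s.n - 1, second=s.n,
                                                 edge=0, stop=0))
        grown += 1
        assert s.n <= 4
    assert s.n == 4 and grown == 3


@pytest.mark.parametrize("smiles,ok", [
    ("CC", True),
    ("N(C)(C)C", True),       # trivalent nitrogen
    ("O=C=O", True),
    ("S(F)(F)(F)(F)(F)F", True),  # hexavalent sulfur
])
def test_valence_ok_table_cases(smiles, ok):
    assert valence_ok(smiles_to_dense(smiles)) is ok


def test_valence_violation_detected():
    st = smiles_to_dense("CC")
    # forge a pentavalent carbon: 4 extra single bonds onto atom 0
    import numpy as np
    A = np.zeros((6, 6), int)
    E = np.zeros((3, 6, 6), int)
    for j in range(1, 6):
        A[0, j] = A[j, 0] = 1
        E[0, 0, j] = E[0, j, 0] = 1
    from molgenrl.molgraph import DenseState
    bad = DenseState(A=A, E=E, F=np.zeros((6, 1)), elements=["C"] * 6)
    assert not valence_ok(bad)


def test_strain_check_accepts_relaxed_and_rejects_fused_cage():
    assert strain_ok(smiles_to_mol("CCO"))
    # spiro-fused bicyclic cyclopropanes: severe angle strain
    cage = smiles_to_mol("C1CC12CC2")
    assert not strain_ok(cage)
    assert strain_ok(cage, threshold=float("inf"))


def test_zinc_filter_catalog_and_matches():
    catalog = load_filter_catalog()
    assert len(catalog) > 10
    assert zinc_filter_ok(smiles_to_mol("CC"))
    assert not zinc_filter_ok(smiles_to_mol("CC(=O)Cl"))   # acyl halide
    assert zinc_filter_ok(smiles_to_mol("CC(=O)Cl"), catalog=[])


def test_malformed_pattern_raises(tmp_path):
    p = tmp_path / "bad.smarts"
    p.write_text("broken\t[[[\n")
    with pytest.raises(ValueError, match="broken"):
        load_filter_catalog(str(p))


def test_final_reward_zero_weights_identity():
    """With no property weights the total is QED + 2*SA_norm + strain + filter."""
    env = MoleculeEnv(RewardConfig(strain_threshold=float("inf")))
    from rdkit.Chem import QED
    mol = smiles_to_mol("CCO")
    bd = env.final_reward(mol)
    expected = QED.qed(mol) + 2.0 * sa_norm(mol) + 1.0 + 1.0
    assert bd.total == pytest.approx(expected)


def test_reward_breakdown_parts_sum_exactly():
    env = MoleculeEnv(
        RewardConfig(property_weights={"oracle": 1.0},
                     strain_threshold=float("inf")),
        property_models={"oracle": toy_oracle})
    for smiles in ("c1ccccc1", "CCO", "CC(=O)Nc1ccccc1"):
        bd = env.final_reward(smiles_to_mol(smiles))
        assert bd.total == sum(bd.parts.values())
        assert bd.parts["property:oracle"] == pytest.approx(toy_oracle(smiles))


def test_missing_property_model_is_configuration_error():
    with pytest.raises(ValueError, match="dat"):
        MoleculeEnv(RewardConfig(property_weights={"dat": 2.0}))


def test_sa_norm_bounds(fixture_smiles):
    for s in fixture_smiles[:20]:
        assert 0.0 <= sa_norm(smiles_to_mol(s)) <= 1.0


def test_random_action_sequences_always_sanitizable(env, rng):
    """Safety invariant: any action sequence yields a sanitizable molecule."""
    for ep in range(20):
        s = env.reset("C")
        while not s.done and s.steps < 30:
            a = ActionVector(first=int(rng.integers(s.n)),
                             second=int(rng.integers(s.n + env.n_atom_types)),
                             edge=int(rng.integers(3)),
                             stop=int(rng.random() < 0.05))
            s, _, _, _ = env.step(s, a)
        assert Chem.MolFromSmiles(s.smiles()) is not None


def test_markov_step_is_pure_function(env):
    s = env.reset("CC")
    a = ActionVector(first=1, second=2, edge=0, stop=0)
    out1 = env.step(s, a)[0].smiles()
    out2 = env.step(s, a)[0].smiles()
    assert out1 == out2


def test_reward_config_validation():
    with pytest.raises(ValueError):
        RewardConfig(max_heavy_atoms=0)
    with pytest.raises(ValueError):
        RewardConfig(qed_weight=math.nan)


def test_reward_config_yaml_roundtrip(tmp_path):
    p = tmp_path / "reward.yaml"
    p.write_text("max_heavy_atoms: 15\nsa_weight: 2.0\n"
                 "property_weights:\n  dat: 2.0\n  net: -1.0\n")
    cfg = RewardConfig.from_yaml(str(p))
    assert cfg.max_heavy_atoms == 15
    assert cfg.property_weights == {"dat": 2.0, "net": -1.0}
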