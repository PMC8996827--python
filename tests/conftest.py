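"""Shared fixtures: synthetic corpora, encoded matrices, small-molecule panels."""

import numpy as np
import pytest

import drfp_kit as dk
from drfp_kit import fixtures as fx

# panel of small molecules (<= 8 heavy atoms) covering linear, branched,
# aromatic, charged and chiral chemistry, with unambiguous ring bases
SMALL_MOLECULE_PANEL = [
    "C",            # methane
    "CC",           # ethane
    "CCC",
    "CCCC",
    "CC(C)C",
    "CC(C)(C)C",
    "CCO",
    "CC=O",
    "CC(=O)O",
    "CC(=O)OC",
    "C=C",
    "C#N",
    "CC#N",
    "C=O",
    "CO",
    "CN",
    "CCN",
    "CNC",
    "CN(C)C",
    "CS",
    "CCS",
    "c1ccccc1",     # benzene
    "c1ccncc1",     # pyridine
    "c1cc[nH]c1",   # pyrrole
    "c1ccsc1",      # thiophene
    "C1CC1",        # cyclopropane
    "C1CCC1",
    "C1CCCC1",
    "C1CCOC1",
    "C1CCNC1",
    "C[C@H](N)C(=O)O",   # L-alanine (chiral)
    "C[C@@H](O)C",       # chiral alcohol
    "F[C@H](Cl)Br",      # chiral halomethane
    "C/C=C/C",           # trans-butene
    "C/C=C\\C",          # cis-butene
    "[NH4+]",
    "CC(=O)[O-]",
    "C[N+](C)(C)C",
    "[O-]S(=O)(=O)O",
    "CCl",
    "CBr",
    "OCC(O)CO",
]


@pytest.fixture(scope="session")
def molecule_panel():
    return list(SMALL_MOLECULE_PANEL)


@pytest.fixture(scope="session")
def class_data():
    """5 template classes x 30 reactions."""
    return fx.generate_template_reactions(n_classes=5, per_class=30, seed=11)


@pytest.fixture(scope="session")
def class_matrix(class_data):
    X, bit_maps, failed = dk.encode_many(class_data.reactions)
    assert not failed
    return X


@pytest.fixture(scope="session")
def yield_data(class_data):
    effects = fx.default_effect_map(class_data.reactions, class_data.classes)
    return fx.generate_synthetic_yields(class_data, effects, noise_sd=5.0, seed=11)


def random_renderings(smiles: str, n: int, seed: int) -> list[str]:
    """n distinct-atom-order SMILES renderings of one molecule."""
    from rdkit import Chem

    mol = Chem.MolFromSmiles(smiles)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        perm = [int(i) for i in rng.permutation(mol.GetNumAtoms())]
        out.append(Chem.MolToSmiles(Chem.RenumberAtoms(mol, perm), canonical=False))
    return out
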