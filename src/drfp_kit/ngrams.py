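"""Molecular n-grams: circular substructures and SSSR rings as SMILES.

For every heavy atom of a molecule and every bond radius 0..r, the
circular neighbourhood (all bonds within the radius of the root atom,
plus their atoms; radius 0 is the bare atom) is rendered as a canonical
fragment SMILES. The SSSR ring fragments (ring atoms and ring bonds
only, no exocyclic substituents) are added on top. The result is a plain
set of strings — duplicate environments collapse, which also absorbs
radii that exceed the molecule's extent.

Stereo descriptors and aromaticity are inherited from the parent
molecule. To make the fragment strings independent of the atom order of
the input SMILES, the parent is canonically renumbered before
extraction; RDKit's fragment writer is otherwise sensitive to parent
atom order.
"""

from __future__ import annotations

from dataclasses import dataclass

from rdkit import Chem

from .errors import UnparsableMolecule

__all__ = ["NGramConfig", "extract_molecule_ngrams", "extract_side_ngrams"]


@dataclass(frozen=True)
class NGramConfig:
    """Extraction settings: maximum bond radius and ring inclusion.

    ``radius`` 3 with rings included is the benchmark default; radii
    2-4 are the commonly evaluated range.
    """

    radius: int = 3
    include_rings: bool = True

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError(f"radius must be >= 0, got {self.radius}")


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparsableMolecule(smiles)
    # Canonical atom numbering: fragment SMILES become input-order free.
    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    return Chem.RenumberAtoms(mol, order)


def _environment_fragment(mol: Chem.Mol, root: int, radius: int) -> str:
    """Canonical SMILES of the bond-radius environment rooted at ``root``."""
    if radius == 0:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[root])
    bonds = Chem.FindAtomEnvironmentOfRadiusN(
        mol, radius, root, False, False  # useHs, enforceSize
    )
    if not bonds:
        return Chem.MolFragmentToSmiles(mol, atomsToUse=[root])
    atoms = {root}
    for b in bonds:
        bond = mol.GetBondWithIdx(b)
        atoms.update((bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()))
    return Chem.MolFragmentToSmiles(
        mol, atomsToUse=sorted(atoms), bondsToUse=list(bonds)
    )


def _ring_fragments(mol: Chem.Mol) -> set[str]:
    out: set[str] = set()
    for ring in Chem.GetSymmSSSR(mol):
        atoms = list(ring)
        bonds = []
        for i, a in enumerate(atoms):
            bond = mol.GetBondBetweenAtoms(a, atoms[(i + 1) % len(atoms)])
            if bond is not None:
                bonds.append(bond.GetIdx())
        out.add(
            Chem.MolFragmentToSmiles(mol, atomsToUse=atoms, bondsToUse=bonds)
        )
    return out


def extract_molecule_ngrams(
    smiles: str, cfg: NGramConfig | None = None
) -> set[str]:
    """All circular fragments (radii 0..r) plus SSSR rings, as a set.

    Raises :class:`UnparsableMolecule` if RDKit rejects the input.
    """
    cfg = cfg or NGramConfig()
    mol = _mol_from_smiles(smiles)
    fragments: set[str] = set()
    for atom in range(mol.GetNumAtoms()):
        for radius in range(cfg.radius + 1):
            fragments.add(_environment_fragment(mol, atom, radius))
    if cfg.include_rings:
        fragments |= _ring_fragments(mol)
    return fragments


def extract_side_ngrams(
    mols: list[str], cfg: NGramConfig | None = None
) -> set[str]:
    """Union of per-molecule n-gram sets over one reaction side."""
    cfg = cfg or NGramConfig()
    fragments: set[str] = set()
    for i, smiles in enumerate(mols):
        try:
            fragments |= extract_molecule_ngrams(smiles, cfg)
        except UnparsableMolecule as exc:
            raise UnparsableMolecule(smiles, detail=f"molecule index {i}") from exc
    return fragments
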