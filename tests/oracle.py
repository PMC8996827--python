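"""Brute-force n-gram oracle, independent of the package's extraction path.

Enumerates circular environments by hand-rolled breadth-first search on
the bond graph (a bond belongs to the radius-rho environment of a root
atom iff its nearer endpoint lies within rho-1 steps of the root) and
ring fragments via networkx's minimum cycle basis. Only the final
canonical-SMILES rendering is shared with the implementation, since
RDKit is the only canonical SMILES writer available.
"""

from collections import deque

import networkx as nx
from rdkit import Chem


def _canonical_parent(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    ranks = list(Chem.CanonicalRankAtoms(mol))
    order = sorted(range(len(ranks)), key=ranks.__getitem__)
    return Chem.RenumberAtoms(mol, order)


def _bfs_distances(adjacency: dict[int, list[int]], root: int) -> dict[int, int]:
    dist = {root: 0}
    queue = deque([root])
    while queue:
        u = queue.popleft()
        for v in adjacency[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def brute_force_ngrams(smiles: str, radius: int, include_rings: bool = True) -> set[str]:
    """Expected fragment set by exhaustive (atom, rho) enumeration."""
    mol = _canonical_parent(smiles)
    adjacency: dict[int, list[int]] = {a.GetIdx(): [] for a in mol.GetAtoms()}
    bond_of = {}
    for bond in mol.GetBonds():
        u, v = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        adjacency[u].append(v)
        adjacency[v].append(u)
        bond_of[frozenset((u, v))] = bond.GetIdx()

    fragments: set[str] = set()
    for root in adjacency:
        dist = _bfs_distances(adjacency, root)
        for rho in range(radius + 1):
            bonds = [
                idx
                for pair, idx in bond_of.items()
                if min(dist.get(a, 10**9) for a in pair) <= rho - 1
            ]
            atoms = {root}
            for pair, idx in bond_of.items():
                if idx in bonds:
                    atoms |= pair
            if bonds:
                frag = Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(atoms), bondsToUse=bonds
                )
            else:
                frag = Chem.MolFragmentToSmiles(mol, atomsToUse=[root])
            fragments.add(frag)

    if include_rings:
        graph = nx.Graph(
            (b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()
        )
        for cycle in nx.minimum_cycle_basis(graph):
            ring_atoms = set(cycle)
            ring_bonds = [
                idx for pair, idx in bond_of.items() if pair <= ring_atoms
            ]
            fragments.add(
                Chem.MolFragmentToSmiles(
                    mol, atomsToUse=sorted(ring_atoms), bondsToUse=ring_bonds
                )
            )
    return fragments
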