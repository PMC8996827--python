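"""Reaction SMILES parsing and fingerprint serialization.

A reaction SMILES is the three-field line notation
``REACTANTS>REAGENTS>PRODUCTS`` in which every field is a dot-separated
list of molecule SMILES and the reagent field may be empty (``A>>B``).
Parsing strips atom-map annotations, validates each component with RDKit
and returns a :class:`ReactionRecord`; tables of reactions with optional
class labels or yield values load into a :class:`LabeledReactionSet`.

Fingerprint matrices serialize to three formats: ``dense`` (CSV of 0/1),
``sparse`` (one row of sorted set-bit indices per reaction) and ``packed``
(bit-packed NumPy archive). All three round-trip bit-for-bit.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem, RDLogger

from .errors import (
    EmptySide,
    IOFailure,
    MalformedReaction,
    MissingColumn,
    UnknownFormat,
    UnparsableMolecule,
)

RDLogger.DisableLog("rdApp.*")

logger = logging.getLogger(__name__)

FORMATS = ("dense", "sparse", "packed")


@dataclass(frozen=True)
class ReactionRecord:
    """One parsed reaction: reactant, reagent and product molecule lists.

    Components are stored atom-map-free but otherwise as written; ``raw``
    keeps the original input string.
    """

    reactants: tuple[str, ...]
    reagents: tuple[str, ...]
    products: tuple[str, ...]
    raw: str

    def to_smiles(self) -> str:
        """Render back to three-field reaction SMILES."""
        return ">".join(
            ".".join(side)
            for side in (self.reactants, self.reagents, self.products)
        )


@dataclass
class LabeledReactionSet:
    """Reactions paired with class labels or yield values.

    Exactly one of ``classes`` / ``yields`` is set. ``fingerprints`` and
    ``splits`` are optional and attached by downstream steps.
    """

    reactions: list[str]
    classes: np.ndarray | None = None
    yields: np.ndarray | None = None
    fingerprints: np.ndarray | None = None
    splits: np.ndarray | None = None
    records: list[ReactionRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.classes is not None and self.yields is not None:
            raise ValueError("exactly one label kind may be present")
        n = len(self.reactions)
        for name in ("classes", "yields", "fingerprints", "splits"):
            arr = getattr(self, name)
            if arr is not None and len(arr) != n:
                raise ValueError(f"{name} has {len(arr)} entries for {n} reactions")

    @property
    def labels(self) -> np.ndarray | None:
        return self.classes if self.classes is not None else self.yields

    def __len__(self) -> int:
        return len(self.reactions)


def _strip_atom_maps(mol: Chem.Mol) -> Chem.Mol:
    for atom in mol.GetAtoms():
        atom.SetAtomMapNum(0)
    return mol


def _parse_component(smiles: str, line: int | None = None) -> str:
    """Validate one molecule SMILES, strip atom maps, return it map-free."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise UnparsableMolecule(smiles, line)
    if any(a.GetAtomMapNum() for a in mol.GetAtoms()):
        return Chem.MolToSmiles(_strip_atom_maps(mol))
    return smiles


def parse_reaction(s: str, line: int | None = None) -> ReactionRecord:
    """Parse a ``REACTANTS>REAGENTS>PRODUCTS`` string into a record.

    Atom-map numbers are stripped from every component. Raises
    :class:`MalformedReaction` on a wrong number of ``>`` separators,
    :class:`EmptySide` when the left side (reactants plus reagents) or the
    product side is empty, and :class:`UnparsableMolecule` for a component
    RDKit rejects.
    """
    fields = s.strip().split(">")
    if len(fields) != 3:
        raise MalformedReaction(
            f"expected 2 '>' separators, found {len(fields) - 1}"
            + (f" (line {line})" if line is not None else "")
        )
    sides = [[m for m in f.split(".") if m] for f in fields]
    reactants, reagents, products = sides
    if not (reactants or reagents) or not products:
        raise EmptySide(
            "reaction needs at least one reactant/reagent and one product"
            + (f" (line {line})" if line is not None else "")
        )
    return ReactionRecord(
        reactants=tuple(_parse_component(m, line) for m in reactants),
        reagents=tuple(_parse_component(m, line) for m in reagents),
        products=tuple(_parse_component(m, line) for m in products),
        raw=s,
    )


def merge_sides(rec: ReactionRecord) -> tuple[list[str], list[str]]:
    """Fold reagents into the reactants: left = reactants ++ reagents.

    The fingerprint deliberately does not distinguish reactants from
    reagents; no deduplication happens here.
    """
    return list(rec.reactants) + list(rec.reagents), list(rec.products)


def read_reaction_table(
    path: str | Path,
    smiles_column: str | None = None,
    label_column: str | None = None,
    label_kind: str = "auto",
    lenient: bool = False,
) -> LabeledReactionSet:
    """Load reactions (one per line, or a delimited table) with labels.

    Plain-text mode (``smiles_column=None``): one reaction SMILES per
    line. Table mode: CSV/TSV with a header row naming ``smiles_column``
    and optionally ``label_column``. ``label_kind`` is ``"class"``,
    ``"yield"`` or ``"auto"`` (numeric columns become yields).

    In strict mode (default) the first invalid row aborts with its 1-based
    row number; in lenient mode invalid rows are skipped with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    if smiles_column is None:
        lines = path.read_text().splitlines()
        rows = [(i + 1, ln.strip()) for i, ln in enumerate(lines) if ln.strip()]
        labels = None
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
        df = pd.read_csv(path, sep=sep)
        if smiles_column not in df.columns:
            raise MissingColumn(f"column {smiles_column!r} not in {list(df.columns)}")
        if label_column is not None and label_column not in df.columns:
            raise MissingColumn(f"column {label_column!r} not in {list(df.columns)}")
        rows = [(i + 2, s) for i, s in enumerate(df[smiles_column])]  # +2: header is row 1
        labels = df[label_column].to_numpy() if label_column else None

    reactions: list[str] = []
    records: list[ReactionRecord] = []
    kept: list[int] = []
    for pos, (line_no, smi) in enumerate(rows):
        try:
            rec = parse_reaction(str(smi), line=line_no)
        except (MalformedReaction, EmptySide, UnparsableMolecule):
            if not lenient:
                raise
            logger.warning("skipping invalid reaction at row %d: %r", line_no, smi)
            continue
        reactions.append(str(smi).strip())
        records.append(rec)
        kept.append(pos)

    classes = yields = None
    if labels is not None:
        labels = labels[kept]
        numeric = pd.api.types.is_numeric_dtype(np.asarray(labels).dtype)
        if label_kind == "yield" or (label_kind == "auto" and numeric):
            yields = np.asarray(labels, dtype=float)
        else:
            classes = np.asarray(labels)
    return LabeledReactionSet(
        reactions=reactions, classes=classes, yields=yields, records=records
    )


def _check_matrix(matrix: np.ndarray) -> np.ndarray:
    matrix = np.asarray(matrix)
    if matrix.ndim != 2:
        raise ValueError(f"expected 2-D binary matrix, got shape {matrix.shape}")
    if matrix.size and not np.isin(matrix, (0, 1)).all():
        raise ValueError("fingerprint matrix must be binary")
    return matrix.astype(np.uint8)


def write_fingerprints(
    matrix: np.ndarray,
    path: str | Path,
    format: str = "dense",
    bit_maps: list[dict[int, list[str]]] | None = None,
) -> None:
    """Write an n x d binary matrix; optionally a bit-map JSON sidecar.

    ``dense``: CSV of 0/1. ``sparse``: per row, comma-separated sorted
    set-bit indices, with a ``# d=<d>`` header. ``packed``: np.packbits
    archive. Bit maps go to ``<path>.bitmap.json``.
    """
    matrix = _check_matrix(matrix)
    path = Path(path)
    if format == "dense":
        np.savetxt(path, matrix, fmt="%d", delimiter=",")
    elif format == "sparse":
        with open(path, "w") as fh:
            fh.write(f"# d={matrix.shape[1]}\n")
            for row in matrix:
                fh.write(",".join(map(str, np.flatnonzero(row))) + "\n")
    elif format == "packed":
        np.savez(path, packed=np.packbits(matrix, axis=1), shape=matrix.shape)
    else:
        raise UnknownFormat(f"format must be one of {FORMATS}, got {format!r}")
    if bit_maps is not None:
        sidecar = path.with_suffix(path.suffix + ".bitmap.json")
        payload = [
            {str(i): frags for i, frags in sorted(bm.items())} for bm in bit_maps
        ]
        sidecar.write_text(json.dumps(payload, indent=1))


def read_fingerprints(path: str | Path, format: str = "dense") -> np.ndarray:
    """Read a fingerprint matrix written by :func:`write_fingerprints`."""
    path = Path(path)
    if not path.exists():
        raise IOFailure(f"no such file: {path}")
    if format == "dense":
        mat = np.loadtxt(path, delimiter=",", dtype=np.uint8, ndmin=2)
        return mat if mat.size else mat.reshape(0, 0)
    if format == "sparse":
        lines = path.read_text().splitlines()
        header = lines[0]
        if not header.startswith("# d="):
            raise IOFailure(f"missing sparse header in {path}")
        d = int(header[4:])
        rows = []
        for ln in lines[1:]:
            row = np.zeros(d, dtype=np.uint8)
            if ln.strip():
                row[[int(x) for x in ln.split(",")]] = 1
            rows.append(row)
        return np.array(rows, dtype=np.uint8).reshape(len(rows), d)
    if format == "packed":
        with np.load(Path(str(path))) as data:
            n, d = data["shape"]
            return np.unpackbits(data["packed"], axis=1, count=int(d))[: int(n)]
    raise UnknownFormat(f"format must be one of {FORMATS}, got {format!r}")
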