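"""The differential reaction fingerprint: hash and fold the changed set.

Pipeline for one reaction SMILES ``REACTANTS>REAGENTS>PRODUCTS``:

1. reagents are merged into the reactants (left side vs products);
2. each side becomes a set of molecular n-grams (circular fragments and
   SSSR rings rendered as canonical SMILES);
3. the symmetric difference S of the two sets — the substructures the
   reaction changes — is hashed fragment-by-fragment to unsigned 32-bit
   integers and folded into a d-bit binary vector via ``k mod d``.

Because S is a symmetric difference of sets, the encoding is invariant
to molecule order, to reactant/reagent placement, and to SMILES
rendering; it maps a reaction and its reverse to the same vector and an
identity reaction to the zero vector. Every set bit carries provenance:
the fragment strings whose hashes landed on it.

The fragment hash is the first 4 bytes of the SHA-256 digest of the
UTF-8 fragment string, read big-endian — stable across processes and
platforms, unlike Python's salted ``hash``.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import io as rio
from .errors import DrfpError, IndexOutOfRange
from .ngrams import NGramConfig, extract_side_ngrams

__all__ = [
    "FingerprintConfig",
    "HashedSet",
    "Fingerprint",
    "DrfpEncoder",
    "symmetric_difference",
    "hash_ngrams",
    "fold",
    "encode",
    "encode_many",
    "explain_bit",
]


@dataclass(frozen=True)
class FingerprintConfig:
    """N-gram settings plus output dimensionality d (default 2048)."""

    ngram: NGramConfig = field(default_factory=NGramConfig)
    dimension: int = 2048

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError(f"dimension must be >= 1, got {self.dimension}")


@dataclass(frozen=True)
class HashedSet:
    """32-bit fragment hashes with hash -> fragments provenance."""

    hashes: frozenset[int]
    provenance: dict[int, list[str]]


@dataclass(frozen=True)
class Fingerprint:
    """d-bit binary vector with bit -> fragments provenance."""

    bits: np.ndarray
    bit_map: dict[int, list[str]]

    @property
    def dimension(self) -> int:
        return self.bits.shape[0]

    def on_bits(self) -> np.ndarray:
        return np.flatnonzero(self.bits)


def symmetric_difference(left: set[str], right: set[str]) -> set[str]:
    """Fragments present on exactly one side: S = R Δ P."""
    return set(left) ^ set(right)


def hash_fragment(fragment: str) -> int:
    """Stable unsigned 32-bit hash of one fragment SMILES."""
    return int.from_bytes(
        hashlib.sha256(fragment.encode("utf-8")).digest()[:4], "big"
    )


def hash_ngrams(fragments: set[str]) -> HashedSet:
    """Hash every fragment; 32-bit collisions merge under one key."""
    provenance: dict[int, list[str]] = {}
    for frag in sorted(fragments):
        provenance.setdefault(hash_fragment(frag), []).append(frag)
    return HashedSet(hashes=frozenset(provenance), provenance=provenance)


def fold(hashed: HashedSet, dimension: int) -> Fingerprint:
    """Fold 32-bit hashes into a d-bit vector: bit i <=> some k = i (mod d)."""
    if dimension < 1:
        raise ValueError(f"dimension must be >= 1, got {dimension}")
    bits = np.zeros(dimension, dtype=np.uint8)
    bit_map: dict[int, list[str]] = {}
    for k in hashed.hashes:
        i = k % dimension
        bits[i] = 1
        bit_map.setdefault(i, []).extend(hashed.provenance[k])
    return Fingerprint(bits=bits, bit_map={i: sorted(f) for i, f in bit_map.items()})


def encode(reaction: str, cfg: FingerprintConfig | None = None) -> Fingerprint:
    """Encode one reaction SMILES to its differential fingerprint."""
    cfg = cfg or FingerprintConfig()
    rec = rio.parse_reaction(reaction)
    left, right = rio.merge_sides(rec)
    changed = symmetric_difference(
        extract_side_ngrams(left, cfg.ngram),
        extract_side_ngrams(right, cfg.ngram),
    )
    return fold(hash_ngrams(changed), cfg.dimension)


def encode_many(
    reactions: list[str],
    cfg: FingerprintConfig | None = None,
    lenient: bool = False,
) -> tuple[np.ndarray, list[dict[int, list[str]]], list[int]]:
    """Encode a batch: (n x d matrix, bit maps, failed row indices).

    Strict mode re-raises the first failure; lenient mode zero-fills
    failed rows and reports their indices.
    """
    cfg = cfg or FingerprintConfig()
    matrix = np.zeros((len(reactions), cfg.dimension), dtype=np.uint8)
    bit_maps: list[dict[int, list[str]]] = []
    failed: list[int] = []
    for i, rxn in enumerate(reactions):
        try:
            fp = encode(rxn, cfg)
        except DrfpError:
            if not lenient:
                raise
            failed.append(i)
            bit_maps.append({})
            continue
        matrix[i] = fp.bits
        bit_maps.append(fp.bit_map)
    return matrix, bit_maps, failed


def explain_bit(fp: Fingerprint, i: int) -> list[str]:
    """Fragments responsible for bit ``i`` (empty if the bit is unset)."""
    if not 0 <= i < fp.dimension:
        raise IndexOutOfRange(f"bit {i} outside [0, {fp.dimension})")
    return list(fp.bit_map.get(i, []))


class DrfpEncoder(TransformerMixin, BaseEstimator):
    """Stateless sklearn transformer: reaction SMILES -> binary DRFP rows.

    Parameters
    ----------
    radius : int, default 3
        Maximum bond radius of the circular fragments.
    dimension : int, default 2048
        Length d of the output bit vector.
    include_rings : bool, default True
        Whether SSSR ring fragments are added to the n-gram sets.
    lenient : bool, default False
        Zero-fill unencodable inputs instead of raising.

    The encoder learns nothing from data; ``fit`` only validates the
    configuration so the class composes with sklearn pipelines.

    Examples
    --------
    >>> enc = DrfpEncoder(dimension=128)
    >>> X = enc.fit_transform(["CCO.CC(=O)O>[H+]>CCOC(=O)C"])
    >>> X.shape
    (1, 128)
    """

    def __init__(
        self,
        radius: int = 3,
        dimension: int = 2048,
        include_rings: bool = True,
        lenient: bool = False,
    ):
        self.radius = radius
        self.dimension = dimension
        self.include_rings = include_rings
        self.lenient = lenient

    def _config(self) -> FingerprintConfig:
        return FingerprintConfig(
            ngram=NGramConfig(radius=self.radius, include_rings=self.include_rings),
            dimension=self.dimension,
        )

    def fit(self, X=None, y=None) -> "DrfpEncoder":
        self._config()  # validates radius/dimension
        self.n_features_out_ = self.dimension
        return self

    def transform(self, X: list[str]) -> np.ndarray:
        """Encode a sequence of reaction SMILES into an (n, d) uint8 matrix."""
        matrix, self.bit_maps_, self.failed_ = encode_many(
            list(X), self._config(), lenient=self.lenient
        )
        return matrix

    def get_feature_names_out(self, input_features=None) -> np.ndarray:
        return np.array([f"drfp_{i}" for i in range(self.dimension)])
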