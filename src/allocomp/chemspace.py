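"""Fingerprints, Tanimoto similarity, and cross-set chemical-overlap counts.

Molecules are encoded as hashed circular fingerprints of diameter 6 (radius
3), 2048 bits, without counts or chirality bits — the closest open analogue of
the ECFP6 class of fingerprints.  Similarity between two molecules is the
Tanimoto coefficient over the on-bit sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

__all__ = [
    "Fingerprint",
    "ecfp6",
    "tanimoto",
    "similarity_matrix",
    "cross_set_neighbor_count",
    "DEFAULT_N_BITS",
]

DEFAULT_N_BITS = 2048

_GENERATORS: dict[int, rdFingerprintGenerator.FingerprintGenerator64] = {}


def _generator(n_bits: int):
    if n_bits not in _GENERATORS:
        _GENERATORS[n_bits] = rdFingerprintGenerator.GetMorganGenerator(
            radius=3, fpSize=n_bits
        )
    return _GENERATORS[n_bits]


@dataclass(frozen=True)
class Fingerprint:
    """Fixed-length binary fingerprint of one ligand.

    ``bits`` is the frozen set of on-bit indices; ``bv`` keeps the RDKit bit
    vector for fast bulk Tanimoto computations (excluded from equality).
    """

    ligand_id: str
    n_bits: int
    bits: frozenset[int]
    bv: DataStructs.ExplicitBitVect = field(compare=False, repr=False, hash=False)

    def __len__(self) -> int:
        return self.n_bits


def ecfp6(smiles: str, n_bits: int = DEFAULT_N_BITS, ligand_id: str | None = None) -> Fingerprint:
    """Hashed circular fingerprint (diameter 6) of a molecule.

    Deterministic: any SMILES writing of the same molecule gives the same
    bits.  Raises ``ValueError`` on an invalid SMILES.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    bv = _generator(n_bits).GetFingerprint(mol)
    return Fingerprint(
        ligand_id=ligand_id if ligand_id is not None else smiles,
        n_bits=n_bits,
        bits=frozenset(bv.GetOnBits()),
        bv=bv,
    )


def tanimoto(a: Fingerprint, b: Fingerprint) -> float:
    """Tc = |A∩B| / (|A| + |B| − |A∩B|); 1.0 for two empty bit sets."""
    if a.n_bits != b.n_bits:
        raise ValueError(f"fingerprint length mismatch: {a.n_bits} vs {b.n_bits}")
    inter = len(a.bits & b.bits)
    union = len(a.bits) + len(b.bits) - inter
    return 1.0 if union == 0 else inter / union


def similarity_matrix(fps: Sequence[Fingerprint]) -> np.ndarray:
    """Dense symmetric all-pairs Tanimoto matrix (diagonal 1)."""
    n = len(fps)
    sims = np.ones((n, n))
    bvs = [fp.bv for fp in fps]
    for i in range(1, n):
        row = DataStructs.BulkTanimotoSimilarity(bvs[i], bvs[:i])
        sims[i, :i] = row
        sims[:i, i] = row
    return sims


def _max_sims(queries: Sequence[Fingerprint], pool: Sequence[Fingerprint]) -> np.ndarray:
    pool_bvs = [fp.bv for fp in pool]
    return np.array(
        [max(DataStructs.BulkTanimotoSimilarity(q.bv, pool_bvs)) for q in queries]
    )


def cross_set_neighbor_count(
    set_a: Sequence[Fingerprint],
    set_b: Sequence[Fingerprint],
    tc_threshold: float,
) -> tuple[int, int]:
    """How many ligands of each set have a close neighbor in the other set.

    Returns ``(count_a, count_b)`` where ``count_a`` is the number of ligands
    in ``set_a`` whose nearest ligand in ``set_b`` has Tc >= ``tc_threshold``
    (each unique ligand counted once), and vice versa.  Monotone non-increasing
    in the threshold.
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    count_a = int((_max_sims(set_a, set_b) >= tc_threshold).sum())
    count_b = int((_max_sims(set_b, set_a) >= tc_threshold).sum())
    return count_a, count_b
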