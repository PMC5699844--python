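"""Two-level redundancy clustering: protein families, then ligand clusters.

Heavily studied targets contribute thousands of near-duplicate ligands; left
uncorrected they dominate any set-level statistic.  Redundancy is removed in
two steps:

1. proteins are grouped into families by greedy clustering on bidirectional
   sequence identity (a joins a family iff identity is above the threshold in
   both directions against the family representative);
2. within each family, the pooled ligands of all member proteins are clustered
   by maximum-dissimilarity (sphere-exclusion) selection on fingerprint
   Tanimoto similarity.

The four paired thresholds (sequence % identity / Tc) span fine to broad
notions of redundancy: 100/1.0, 90/0.9, 75/0.75, 60/0.6.  The greedy pass and
all tie-breaks follow a fixed canonical order (proteins by descending sequence
length, ligands by descending heavy-atom count, ties lexicographic by id) so
runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from rdkit import Chem

from .chemspace import Fingerprint, similarity_matrix
from .ingest import LigandRecord, ProteinRecord

__all__ = [
    "ClusteringLevel",
    "LEVELS",
    "ProteinFamily",
    "LigandCluster",
    "pairwise_identity",
    "IdentityCache",
    "greedy_protein_families",
    "max_dissimilarity_cluster",
    "cluster_center",
    "build_protein_ligand_clusters",
]

#: the four paired clustering levels (sequence identity %, Tc threshold)
_LEVEL_PAIRS = {60: 0.6, 75: 0.75, 90: 0.9, 100: 1.0}


@dataclass(frozen=True)
class ClusteringLevel:
    """One of the four paired (sequence identity %, Tc) clustering levels."""

    seq_identity_pct: int
    tc_threshold: float

    def __post_init__(self) -> None:
        if _LEVEL_PAIRS.get(self.seq_identity_pct) != self.tc_threshold:
            raise ValueError(
                f"unsupported level pairing {self.seq_identity_pct}/{self.tc_threshold}; "
                f"allowed: {sorted(_LEVEL_PAIRS.items())}"
            )

    @property
    def label(self) -> str:
        return f"{self.seq_identity_pct}/{self.tc_threshold:g}"


LEVELS: tuple[ClusteringLevel, ...] = tuple(
    ClusteringLevel(p, t) for p, t in sorted(_LEVEL_PAIRS.items())
)


@dataclass(frozen=True)
class ProteinFamily:
    family_id: str
    level: ClusteringLevel
    representative_id: str
    member_protein_ids: tuple[str, ...]


@dataclass(frozen=True)
class LigandCluster:
    cluster_id: str
    family_id: str
    member_ligand_ids: tuple[str, ...]
    center_ligand_id: str

    @property
    def size(self) -> int:
        return len(self.member_ligand_ids)


# --------------------------------------------------------------------------
# sequence identity
# --------------------------------------------------------------------------

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


_ALIGNER = _make_aligner()


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> tuple[float, float]:
    """Bidirectional percent identity from one exact local alignment.

    The alignment uses BLOSUM62 with gap open 11 / extend 1.  The number of
    identical aligned positions is divided by each sequence's own full length,
    giving the asymmetric pair (identity_ab, identity_ba) in [0, 100]: a short
    perfect substring of a long sequence is 100% identical in one direction
    only.
    """
    alignment = _ALIGNER.align(a.sequence, b.sequence)[0]
    ident = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        seg_a = a.sequence[a0:a1]
        seg_b = b.sequence[b0:b1]
        ident += sum(x == y for x, y in zip(seg_a, seg_b))
    return 100.0 * ident / len(a.sequence), 100.0 * ident / len(b.sequence)


class IdentityCache:
    """Memoized :func:`pairwise_identity`, shared across clustering levels."""

    def __init__(self, identity_fn: Callable = pairwise_identity) -> None:
        self._fn = identity_fn
        self._cache: dict[tuple[str, str], tuple[float, float]] = {}

    def __call__(self, a: ProteinRecord, b: ProteinRecord) -> tuple[float, float]:
        key = (a.protein_id, b.protein_id)
        if key not in self._cache:
            iab, iba = self._fn(a, b)
            self._cache[key] = (iab, iba)
            self._cache[(key[1], key[0])] = (iba, iab)
        return self._cache[key]


def _protein_order(proteins: Sequence[ProteinRecord]) -> list[ProteinRecord]:
    return sorted(proteins, key=lambda p: (-len(p.sequence), p.protein_id))


def greedy_protein_families(
    proteins: Sequence[ProteinRecord],
    level: ClusteringLevel,
    identity: Callable | None = None,
) -> list[ProteinFamily]:
    """Partition proteins into families by greedy bidirectional identity.

    Proteins are visited in canonical order; each joins the first existing
    family whose representative satisfies ``min(identity_ab, identity_ba) >=``
    the level threshold, else founds a new family.  Passing a shared
    :class:`IdentityCache` avoids recomputing alignments across levels.
    """
    if identity is None:
        identity = IdentityCache()
    seen: set[str] = set()
    unique = []
    for p in proteins:
        if p.protein_id not in seen:
            seen.add(p.protein_id)
            unique.append(p)

    reps: list[ProteinRecord] = []
    members: list[list[str]] = []
    threshold = float(level.seq_identity_pct)
    for protein in _protein_order(unique):
        for idx, rep in enumerate(reps):
            iab, iba = identity(protein, rep)
            if min(iab, iba) >= threshold:
                members[idx].append(protein.protein_id)
                break
        else:
            reps.append(protein)
            members.append([protein.protein_id])
    return [
        ProteinFamily(
            family_id=f"S{level.seq_identity_pct}_F{idx:04d}",
            level=level,
            representative_id=rep.protein_id,
            member_protein_ids=tuple(mem),
        )
        for idx, (rep, mem) in enumerate(zip(reps, members))
    ]


# --------------------------------------------------------------------------
# ligand clustering (sphere exclusion / maximum dissimilarity)
# --------------------------------------------------------------------------

def max_dissimilarity_cluster(
    ligand_fps: Sequence[Fingerprint],
    tc_threshold: float,
    sims: np.ndarray | None = None,
) -> list[tuple[int, ...]]:
    """Cluster one pool of fingerprints by maximum-dissimilarity seeding.

    The first seed is the ligand with minimal total similarity to all others;
    seeds are then added greedily (always the ligand whose nearest seed is most
    dissimilar) until every non-seed ligand has Tc >= ``tc_threshold`` to some
    seed.  Every ligand is finally assigned to its most-similar seed, ties
    resolved toward the seed earliest in the input (canonical) order.

    Returns clusters as tuples of input indices; together they partition the
    input, and each tuple lists the cluster's seed first.  The input order is
    the canonical tie-break order.
    """
    n = len(ligand_fps)
    if n == 0:
        raise ValueError("cannot cluster an empty ligand pool")
    if n == 1:
        return [(0,)]
    if sims is None:
        sims = similarity_matrix(ligand_fps)

    totals = sims.sum(axis=1)
    seeds = [int(np.argmin(totals))]
    nearest = sims[seeds[0]].copy()  # nearest-seed similarity per ligand
    is_seed = np.zeros(n, dtype=bool)
    is_seed[seeds[0]] = True
    while True:
        masked = np.where(is_seed, np.inf, nearest)
        worst = int(np.argmin(masked))  # ties -> earliest canonical position
        if masked[worst] >= tc_threshold:
            break
        seeds.append(worst)
        is_seed[worst] = True
        nearest = np.maximum(nearest, sims[worst])

    seed_sims = sims[seeds]  # (n_seeds, n)
    best = seed_sims.max(axis=0)
    # ties toward the seed earliest in canonical order: seeds sorted by index
    order = np.argsort(seeds, kind="stable")
    assignment = np.empty(n, dtype=int)
    for rank in order[::-1]:
        assignment[seed_sims[rank] == best] = rank
    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(int(assignment[i]), []).append(i)
    # emit clusters ordered by their seed's canonical position, seed first
    # within each cluster so the sphere constraint is externally checkable
    out = []
    for rank in sorted(clusters, key=lambda r: seeds[r]):
        seed = seeds[rank]
        out.append((seed, *(i for i in clusters[rank] if i != seed)))
    return out


def cluster_center(
    member_indices: Sequence[int], sims: np.ndarray
) -> int:
    """Member minimizing the summed Tc distance (1 − Tc) to the other members.

    Ties are broken toward the member earliest in canonical order.  ``sims``
    is the pool similarity matrix the member indices refer to.
    """
    if not member_indices:
        raise ValueError("empty cluster")
    if len(member_indices) == 1:
        return member_indices[0]
    idx = np.asarray(member_indices)
    sub = sims[np.ix_(idx, idx)]
    dist_sums = (1.0 - sub).sum(axis=1)
    return int(idx[int(np.argmin(dist_sums))])


def _heavy_atoms(smiles: str, cache: dict[str, int]) -> int:
    if smiles not in cache:
        mol = Chem.MolFromSmiles(smiles)
        if mol is None:
            raise ValueError(f"invalid SMILES: {smiles!r}")
        cache[smiles] = mol.GetNumHeavyAtoms()
    return cache[smiles]


def build_protein_ligand_clusters(
    ligands: Sequence[LigandRecord],
    proteins: Sequence[ProteinRecord],
    level: ClusteringLevel,
    fingerprints: Mapping[str, Fingerprint],
    identity: Callable | None = None,
    families: Sequence[ProteinFamily] | None = None,
    heavy_atom_counts: Mapping[str, int] | None = None,
) -> tuple[list[ProteinFamily], list[LigandCluster]]:
    """The full two-level clustering of one ligand set at one level.

    For each protein family, the ligands of all member proteins are pooled (a
    ligand targeting proteins in k families appears in k pools), deduplicated
    within the pool by washed SMILES, ordered canonically (descending
    heavy-atom count, then id) and clustered by sphere exclusion at the
    level's Tc threshold.  ``fingerprints`` maps ligand_id -> fingerprint.

    Returns ``(families, clusters)``; cluster ids embed the family id.
    """
    if families is None:
        families = greedy_protein_families(proteins, level, identity)

    family_of_protein: dict[str, str] = {}
    for fam in families:
        for pid in fam.member_protein_ids:
            family_of_protein[pid] = fam.family_id

    ha_cache: dict[str, int] = {}
    pools: dict[str, dict[str, LigandRecord]] = {fam.family_id: {} for fam in families}
    for rec in ligands:
        fams = {family_of_protein[t] for t in rec.target_ids if t in family_of_protein}
        for fid in fams:
            pool = pools[fid]
            # dedup within the pool by washed SMILES, keeping the smallest id
            prior = pool.get(rec.smiles_canonical)
            if prior is None or rec.ligand_id < prior.ligand_id:
                pool[rec.smiles_canonical] = rec

    clusters: list[LigandCluster] = []
    for fam in families:
        pool = list(pools[fam.family_id].values())
        if not pool:
            continue
        if heavy_atom_counts is not None:
            key = lambda r: (-heavy_atom_counts[r.ligand_id], r.ligand_id)
        else:
            key = lambda r: (-_heavy_atoms(r.smiles_canonical, ha_cache), r.ligand_id)
        pool.sort(key=key)
        fps = [fingerprints[r.ligand_id] for r in pool]
        sims = similarity_matrix(fps)
        for j, member_idx in enumerate(
            max_dissimilarity_cluster(fps, level.tc_threshold, sims=sims)
        ):
            center = cluster_center(member_idx, sims)
            clusters.append(
                LigandCluster(
                    cluster_id=f"{fam.family_id}_C{j:05d}",
                    family_id=fam.family_id,
                    member_ligand_ids=tuple(pool[i].ligand_id for i in member_idx),
                    center_ligand_id=pool[center].ligand_id,
                )
            )
    return list(families), clusters
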