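"""Two-level clustering: identities, greedy families, sphere exclusion."""

import numpy as np
import pytest

from allocomp.chemspace import ecfp6, similarity_matrix, tanimoto
from allocomp.ingest import LigandRecord, ProteinRecord, wash_record
from allocomp.redundancy import (
    LEVELS,
    ClusteringLevel,
    IdentityCache,
    build_protein_ligand_clusters,
    cluster_center,
    greedy_protein_families,
    max_dissimilarity_cluster,
    pairwise_identity,
)
from allocomp.synthetic import generate_ligand, generate_protein_family


def _protein(pid, seq):
    return ProteinRecord(pid, seq)


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=n))


class TestPairwiseIdentity:
    def test_identical(self):
        a = _protein("a", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        assert pairwise_identity(a, a) == (100.0, 100.0)

    def test_prefix_half(self):
        rng = np.random.default_rng(0)
        full = _random_seq(rng, 60)
        a = _protein("a", full[:30])
        iab, iba = pairwise_identity(a, _protein("b", full))
        assert iab == pytest.approx(100.0)
        assert iba == pytest.approx(50.0)

    def test_unrelated_random_sequences(self):
        rng = np.random.default_rng(1)
        a = _protein("a", _random_seq(rng, 300))
        b = _protein("b", _random_seq(rng, 300))
        iab, iba = pairwise_identity(a, b)
        assert iab < 30 and iba < 30


class TestGreedyFamilies:
    def test_identical_sequences_single_family(self):
        seq = "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ" * 3
        prots = [_protein(f"p{i}", seq) for i in range(3)]
        fams = greedy_protein_families(prots, ClusteringLevel(100, 1.0))
        assert len(fams) == 1 and len(fams[0].member_protein_ids) == 3

    def test_low_identity_pair_split(self):
        rng = np.random.default_rng(2)
        prots = [_protein("a", _random_seq(rng, 200)), _protein("b", _random_seq(rng, 200))]
        fams = greedy_protein_families(prots, ClusteringLevel(60, 0.6))
        assert len(fams) == 2

    def test_isoforms_grouped_at_60_separated_at_90(self):
        # constructed isoform pair at ~70% identity
        members = generate_protein_family(2, 70.0, length=300, rng=5)
        low = greedy_protein_families(members, ClusteringLevel(60, 0.6))
        high = greedy_protein_families(members, ClusteringLevel(90, 0.9))
        assert len(low) == 1 and len(high) == 2

    def test_partition_property(self):
        rng = np.random.default_rng(3)
        prots = []
        for f in range(4):
            fam = generate_protein_family(3, 90.0, length=150, rng=rng)
            prots += [_protein(f"f{f}_{p.protein_id}", p.sequence) for p in fam]
        for level in LEVELS:
            fams = greedy_protein_families(prots, level, IdentityCache())
            all_members = [pid for fam in fams for pid in fam.member_protein_ids]
            assert sorted(all_members) == sorted(p.protein_id for p in prots)

    def test_invalid_level_pairing(self):
        with pytest.raises(ValueError):
            ClusteringLevel(60, 0.9)


class TestSphereExclusion:
    def test_identical_fingerprints_single_cluster(self):
        fps = [ecfp6("c1ccccc1", ligand_id=str(i)) for i in range(5)]
        clusters = max_dissimilarity_cluster(fps, 0.6)
        assert clusters == [(0, 1, 2, 3, 4)]

    def test_dissimilar_pair_splits(self):
        fps = [ecfp6("c1ccccc1", ligand_id="a"), ecfp6("CCCCCCCC", ligand_id="b")]
        assert tanimoto(fps[0], fps[1]) == 0.0
        assert max_dissimilarity_cluster(fps, 0.6) == [(0,), (1,)]

    def test_threshold_one_groups_exact_duplicates_only(self):
        fps = [
            ecfp6("c1ccccc1", ligand_id="a"),
            ecfp6("C1=CC=CC=C1", ligand_id="b"),  # same molecule
            ecfp6("Cc1ccccc1", ligand_id="c"),
        ]
        clusters = max_dissimilarity_cluster(fps, 1.0)
        assert sorted(map(sorted, clusters)) == [[0, 1], [2]]

    def test_partition_and_seed_constraint_brute_force(self):
        rng = np.random.default_rng(4)
        for trial in range(6):
            n = int(rng.integers(2, 13))
            fps = [
                ecfp6(generate_ligand(rng), ligand_id=f"{trial}_{i}") for i in range(n)
            ]
            for tc in (0.3, 0.6, 0.9):
                clusters = max_dissimilarity_cluster(fps, tc)
                members = sorted(i for cl in clusters for i in cl)
                assert members == list(range(n))  # partition
                for cl in clusters:  # every member within tc of its seed
                    seed = cl[0]
                    for m in cl:
                        assert tanimoto(fps[m], fps[seed]) >= tc or m == seed

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError):
            max_dissimilarity_cluster([], 0.6)


class TestClusterCenter:
    def test_singleton(self):
        sims = np.array([[1.0]])
        assert cluster_center([0], sims) == 0

    def test_enumerated_three_member_cluster(self):
        # m0 close to both others; distance sums: m0=0.6, m1=1.1, m2=1.1
        sims = np.array([[1.0, 0.7, 0.7], [0.7, 1.0, 0.5], [0.7, 0.5, 1.0]])
        assert cluster_center([0, 1, 2], sims) == 0

    def test_all_identical_tie_goes_to_first(self):
        sims = np.ones((3, 3))
        assert cluster_center([0, 1, 2], sims) == 0


class TestTwoLevelClustering:
    def _ligand(self, lid, smi, targets):
        return wash_record(
            LigandRecord(lid, smi, "allosteric", target_ids=tuple(targets))
        )

    def test_one_protein_identical_ligands(self):
        prot = _protein("P1", "MKTAYIAKQRQISFVKSHFSRQLEERLGLIEVQ")
        ligs = [self._ligand(f"L{i}", "c1ccccc1", ["P1"]) for i in range(5)]
        fps = {r.ligand_id: ecfp6(r.smiles_canonical, ligand_id=r.ligand_id) for r in ligs}
        fams, cls = build_protein_ligand_clusters(ligs, [prot], ClusteringLevel(100, 1.0), fps)
        # identical ligands dedup to one per pool
        assert len(cls) == 1 and cls[0].size == 1

    def test_unrelated_proteins_give_separate_clusters(self):
        rng = np.random.default_rng(6)
        prots = [_protein("P1", _random_seq(rng, 150)), _protein("P2", _random_seq(rng, 150))]
        ligs = [
            self._ligand("L1", "c1ccccc1", ["P1"]),
            self._ligand("L2", "CCCCCCCC", ["P2"]),
        ]
        fps = {r.ligand_id: ecfp6(r.smiles_canonical, ligand_id=r.ligand_id) for r in ligs}
        fams, cls = build_protein_ligand_clusters(ligs, prots, ClusteringLevel(60, 0.6), fps)
        assert len(fams) == 2 and len(cls) == 2

    def test_multi_family_ligand_contributes_to_both_pools(self):
        rng = np.random.default_rng(7)
        prots = [_protein("P1", _random_seq(rng, 150)), _protein("P2", _random_seq(rng, 150))]
        ligs = [self._ligand("L1", "c1ccccc1", ["P1", "P2"])]
        fps = {"L1": ecfp6("c1ccccc1", ligand_id="L1")}
        _, cls = build_protein_ligand_clusters(ligs, prots, ClusteringLevel(60, 0.6), fps)
        assert len(cls) == 2
        assert all(cl.member_ligand_ids == ("L1",) for cl in cls)

    def test_recluster_of_centers_is_singleton_stable(self):
        rng = np.random.default_rng(8)
        fps = [ecfp6(generate_ligand(rng), ligand_id=str(i)) for i in range(30)]
        sims = similarity_matrix(fps)
        clusters = max_dissimilarity_cluster(fps, 0.6, sims=sims)
        centers = [cluster_center(cl, sims) for cl in clusters]
        center_fps = [fps[i] for i in centers]
        again = max_dissimilarity_cluster(center_fps, 0.6)
        # centers are mutually below threshold except exact/near duplicates,
        # so re-clustering them never merges beyond the original count
        assert len(again) <= len(centers)
        members = sorted(i for cl in again for i in cl)
        assert members == list(range(len(centers)))
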