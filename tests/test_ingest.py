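"""Curation rules: wash, dedup, assay filters, panel artifacts, readers."""

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from allocomp import ingest
from allocomp.ingest import (
    AssayRecord,
    LigandRecord,
    ProteinRecord,
    WashError,
    curate,
    dedup,
    filter_assays,
    flag_panel_artifacts,
    wash,
)
from allocomp.synthetic import generate_ligand


@pytest.mark.parametrize(
    "raw, expected",
    [
        ("CC(=O)O", "CC(=O)[O-]"),          # carboxylic acid deprotonated
        ("c1ccccc1", "c1ccccc1"),            # no ionizable group
        ("CCN.Cl", "CC[NH3+]"),              # salt stripped, amine protonated
        ("CS(=O)(=O)O", "CS(=O)(=O)[O-]"),   # sulfonic acid
        ("c1nnn[nH]1", "c1nnn[n-]1"),        # tetrazole
        ("NC(N)=N", "NC(N)=[NH2+]"),         # guanidine protonated at sp2 N
        ("Nc1ccccc1", "Nc1ccccc1"),          # aniline: weak base, untouched
        ("CC(=O)NC", "CNC(C)=O"),            # amide N untouched
    ],
)
def test_wash_rule_table(raw, expected):
    assert wash(raw) == expected


def test_wash_verified_by_independent_smarts_matcher():
    """The washed acetic acid really is the carboxylate anion."""
    mol = Chem.MolFromSmiles(wash("CC(=O)O"))
    assert mol.GetSubstructMatches(Chem.MolFromSmarts("[CX3](=O)[O-]"))
    assert Chem.GetFormalCharge(mol) == -1


def test_wash_idempotent_and_single_fragment_on_grammar_draws():
    rng = np.random.default_rng(0)
    for _ in range(60):
        w = wash(generate_ligand(rng))
        assert wash(w) == w
        assert "." not in w


def test_wash_rejects_garbage():
    with pytest.raises(WashError):
        wash("not_a_smiles((")


def _rec(lid, smi, label="allosteric", targets=("P1",)):
    return ingest.wash_record(
        LigandRecord(ligand_id=lid, smiles_raw=smi, set_label=label, target_ids=tuple(targets))
    )


class TestDedup:
    def test_exact_duplicate_collapses(self):
        out = dedup([_rec("a", "CCO"), _rec("b", "CCO")])
        assert len(out) == 1 and out[0].target_ids == ("P1",)

    def test_multi_target_union(self):
        out = dedup([_rec("a", "CCO", targets=["P1"]), _rec("a2", "OCC", targets=["P2"])])
        assert len(out) == 1
        assert out[0].target_ids == ("P1", "P2")

    def test_stereoisomers_stay_distinct(self):
        out = dedup([_rec("a", "C[C@H](O)CC"), _rec("b", "C[C@@H](O)CC")])
        assert len(out) == 2

    def test_sets_kept_separate(self):
        out = dedup([_rec("a", "CCO", "allosteric"), _rec("b", "CCO", "competitive")])
        assert len(out) == 2

    def test_empty_and_idempotent_order_insensitive(self):
        assert dedup([]) == []
        recs = [_rec("a", "CCO"), _rec("b", "CCO", targets=["P2"]), _rec("c", "CCC")]
        once = dedup(recs)
        assert dedup(once) == once
        pairs = lambda rs: {(r.smiles_canonical, r.target_ids) for r in rs}
        assert pairs(dedup(recs[::-1])) == pairs(once)


class TestFilterAssays:
    A = AssayRecord("a1", "Allosteric modulation of receptor X", False, 12.0, ("L1",))
    B = AssayRecord("a2", "allosteric HTS campaign", True, 5.0, ("L2",))
    C = AssayRecord("a3", "Binding affinity", False, 1.0, ("L3",))
    D = AssayRecord("a4", "Competitive inhibition assay", False, 2.0, ("L4",))

    def test_keyword_hts_and_blacklist(self):
        kept = filter_assays([self.A, self.B, self.C, self.D], "allosteric")
        assert [a.assay_id for a in kept] == ["a1"]
        assert filter_assays([self.A], "allosteric", ["a1"]) == []

    def test_no_stem_dropped_in_both_modes(self):
        assert filter_assays([self.C], "allosteric") == []
        assert filter_assays([self.C], "competitive") == []

    def test_subset_and_blacklist_monotone(self):
        assays = [self.A, self.B, self.C, self.D]
        kept = filter_assays(assays, "competitive")
        assert set(a.assay_id for a in kept) <= {a.assay_id for a in assays}
        for bl in (["a4"], ["a4", "a1"]):
            assert len(filter_assays(assays, "competitive", bl)) <= len(kept)

    def test_active_ligand_ids(self):
        zero = AssayRecord("z", "competitive", False, 0.0, ("L9",))
        absent = AssayRecord("w", "competitive", False, None, ("L8",))
        assert ingest.active_ligand_ids([self.A, zero, absent]) == {"L1"}


class TestPanelArtifacts:
    def test_flagging_threshold(self):
        big = LigandRecord("x", "CCO", "competitive", target_ids=tuple(f"P{i}" for i in range(250)))
        one = LigandRecord("y", "CCC", "competitive", target_ids=("P1",))
        assert flag_panel_artifacts([big, one], max_targets=100) == ["x"]
        assert flag_panel_artifacts([one]) == []

    def test_invalid_threshold(self):
        with pytest.raises(ValueError):
            flag_panel_artifacts([], max_targets=0)


class TestReaders:
    def test_ligand_table_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            {
                "ligand_id": ["L1", "L2", "L3"],
                "smiles": ["CCO", "", "c1ccccc1"],
                "set_label": ["allosteric", "allosteric", "competitive"],
                "target_ids": ["P1;P2", "P1", "P3"],
            }
        )
        path = tmp_path / "ligs.csv"
        df.to_csv(path, index=False)
        recs = ingest.read_ligand_table(path)
        assert len(recs) == 2  # empty-SMILES row skipped
        assert recs[0].target_ids == ("P1", "P2")

    def test_missing_column_is_hard_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        pd.DataFrame({"ligand_id": ["L1"], "smiles": ["CCO"]}).to_csv(path, index=False)
        with pytest.raises(ValueError, match="set_label"):
            ingest.read_ligand_table(path)

    def test_fasta(self, tmp_path):
        path = tmp_path / "p.fasta"
        path.write_text(">P1 kinase one\nMKTAYIAK\n>P2\nMSSSSSS\n")
        recs = ingest.read_fasta(path)
        assert [r.protein_id for r in recs] == ["P1", "P2"]
        assert recs[0].name == "kinase one" and recs[1].name == "None"

    def test_protein_record_validation(self):
        with pytest.raises(ValueError):
            ProteinRecord("bad", "MKTA1Z")
        with pytest.raises(ValueError):
            ProteinRecord("empty", "")


def test_curate_end_to_end(small_study):
    recs = ingest.read_ligand_table(small_study.ligands)
    assays = ingest.read_assay_table(small_study.assays)
    comp = [r for r in recs if r.set_label == "competitive"]
    report = curate(comp, assays=assays, mode="competitive", max_targets=100)
    # injected duplicates removed, panel standards flagged and excluded
    assert report.n_duplicates_removed > 0
    assert report.panel_flagged == sorted(small_study.manifest["panel_ligand_ids"])
    kept_ids = {r.ligand_id for r in report.records}
    assert not kept_ids & set(report.panel_flagged)
    # unique-ligand count equals distinct washed structures
    smiles = [r.smiles_canonical for r in report.records]
    assert len(smiles) == len(set(smiles))
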