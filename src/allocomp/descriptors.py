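"""The 29 physicochemical properties compared between the two ligand sets.

18 base descriptors (atom counts, bond counts, physical properties,
drug/lead-likeness) plus 11 size-corrected versions obtained by dividing by
the heavy-atom count (HA).  Size correction removes the strong correlation
between molecule size and raw atom/bond counts.

Atom typing notes
-----------------
The hydrogen-bond donor/acceptor, acidic-atom and basic-atom definitions are
open SMARTS-based substitutions for proprietary typers and are documented
here exactly as computed:

* donor: N or O carrying at least one hydrogen (charged ammonium included);
* acceptor: any O with charge <= 0; nitrogen that is sp (X1), imine-type
  (X2), pyridine-type aromatic (two-connected ``n``), or amine-type X3 that is
  neither an amide/sulfonamide/phosphonamide nitrogen nor positively charged.
  Pyrrole-type aromatic N (three-connected, lone pair in the ring) is not an
  acceptor;
* acidic / basic atoms: the ionizable sites of the wash rule table (strong
  acids / strong bases), counted in either protonation state;
* rotatable bond: single, acyclic, both atoms with heavy-degree >= 2,
  excluding amide C-N;
* ``logS`` uses the ESOL linear solubility model (intercept 0.16, slopes
  -0.63 SlogP, -0.0062 MW, +0.066 rotatable bonds, -0.74 aromatic
  proportion), an established open model of aqueous solubility;
* ``chiral`` counts tetrahedral stereocenters including unassigned ones, so
  database SMILES without stereo flags are treated consistently;
* ``SlogP`` is the Wildman-Crippen atomic-contribution logP.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, rdMolDescriptors

__all__ = [
    "DescriptorVector",
    "compute_descriptors",
    "descriptor_table",
    "lipinski",
    "oprea",
    "ANALYZED_CODES",
    "DISCRETE_CODES",
    "CONTINUOUS_CODES",
]

# --- descriptor code registry -------------------------------------------------

#: the 18 base property codes
BASE_CODES = (
    "a_heavy", "a_aro", "a_acc", "a_don", "a_acid", "a_base",
    "b_count", "b_ar", "b_1rotN", "FCharge", "SlogP", "logS",
    "chiral", "rings", "lip_druglike", "lip_violation", "opr_leadlike", "opr_violation",
)

#: base code -> size-corrected code, the 11 ratios
RATIO_CODES = {
    "a_aro": "a_aro/HA", "a_acc": "a_acc/HA", "a_don": "a_don/HA",
    "a_acid": "a_acid/HA", "a_base": "a_base/HA", "b_count": "b_count/HA",
    "b_ar": "b_ar/HA", "b_1rotN": "b_1rotN/HA", "FCharge": "FCharge/HA",
    "a_nC": "a_nC/HA", "chiral": "chiral/HA",
}

#: the 29 analyzed property codes (a_nC itself enters only through a_nC/HA)
ANALYZED_CODES = BASE_CODES + tuple(RATIO_CODES.values())

#: integer-valued codes binned at width 1 in the weighted histograms
DISCRETE_CODES = frozenset(
    c for c in BASE_CODES if c not in ("SlogP", "logS")
)

#: real-valued codes binned at width 0.001
CONTINUOUS_CODES = frozenset(ANALYZED_CODES) - DISCRETE_CODES

assert len(ANALYZED_CODES) == 29

# --- SMARTS atom typing -------------------------------------------------------

_DONOR = Chem.MolFromSmarts("[$([#7;!H0]),$([#8;!H0;+0])]")
_ACCEPTOR = Chem.MolFromSmarts(
    "[$([#8;X1,X2;+0,-1]),"
    "$([#7;X1;+0]),$([N;X2;+0]),$([n;X2;+0]),"
    "$([N;X3;+0;!$([N][#6,#16,#15]=[O,S,N,P])])]"
)
# ionizable sites in either protonation state (mirrors the wash rule table)
_ACID_SITES = Chem.MolFromSmarts(
    "[$([OX2H1][CX3]=O),$([OX1-][CX3]=O),"
    "$([OX2H1][SX4](=O)=O),$([OX1-][SX4](=O)=O),"
    "$([OX2H1][PX4]=O),$([OX1-][PX4]=O),"
    "$([nX3H1]1nnnc1),$([nX2-]1nnnc1)]"
)
_BASE_SITES = Chem.MolFromSmarts(
    "[$([NX3;H2,H1,H0;+0;!$([N]a);!$([N][#6]=[O,S,N,P]);!$([N][S,P]=[O,S])]),"
    "$([NX4;H3,H2,H1;+1;!$([N]a)]),"
    "$([NX2;+0]=[CX3;!$([C]=[O,S])][NX3]),"
    "$([NX3;H2,H1;+1]=[CX3;!$([C]=[O,S])][NX3])]"
)


def _rotatable_bond_count(mol: Chem.Mol) -> int:
    """Single, acyclic, non-terminal bonds, excluding amide C-N."""
    n = 0
    for bond in mol.GetBonds():
        if bond.GetBondType() != Chem.BondType.SINGLE or bond.IsInRing():
            continue
        a, b = bond.GetBeginAtom(), bond.GetEndAtom()
        if a.GetDegree() < 2 or b.GetDegree() < 2:
            continue
        if _is_amide_cn(a, b) or _is_amide_cn(b, a):
            continue
        n += 1
    return n


def _is_amide_cn(c: Chem.Atom, n: Chem.Atom) -> bool:
    if c.GetAtomicNum() != 6 or n.GetAtomicNum() != 7:
        return False
    return any(
        b.GetBondType() == Chem.BondType.DOUBLE
        and b.GetOtherAtom(c).GetAtomicNum() == 8
        for b in c.GetBonds()
    )


# --- the vector ---------------------------------------------------------------

@dataclass(frozen=True)
class DescriptorVector:
    """All analyzed properties of one washed ligand (plus MW and raw a_nC)."""

    a_heavy: int
    a_aro: int
    a_acc: int
    a_don: int
    a_acid: int
    a_base: int
    a_nC: int
    b_count: int
    b_ar: int
    b_1rotN: int
    FCharge: int
    SlogP: float
    logS: float
    chiral: int
    rings: int
    lip_violation: int
    lip_druglike: int
    opr_violation: int
    opr_leadlike: int
    mol_weight: float

    def __post_init__(self) -> None:
        if self.a_heavy < 1:
            raise ValueError("a_heavy must be >= 1")

    def as_dict(self) -> dict[str, float]:
        """The 29 analyzed properties keyed by their table codes."""
        base = {c: getattr(self, c) for c in BASE_CODES}
        ha = float(self.a_heavy)
        ratios = {ratio: getattr(self, raw) / ha for raw, ratio in RATIO_CODES.items()}
        return {**base, **ratios}


def lipinski(vector: DescriptorVector, mol_weight: float) -> tuple[int, int]:
    """Rule-of-five violations over {MW>500, SlogP>5, donors>5, acceptors>10}."""
    violations = sum(
        (mol_weight > 500, vector.SlogP > 5, vector.a_don > 5, vector.a_acc > 10)
    )
    return violations, int(violations < 2)


def oprea(vector: DescriptorVector, mol_weight: float) -> tuple[int, int]:
    """Lead-likeness violations over {MW<=450, SlogP in [-3.5, 4.5], rings<=4,
    rotatable bonds<=10, donors<=5, acceptors<=8}."""
    violations = sum(
        (
            mol_weight > 450,
            not (-3.5 <= vector.SlogP <= 4.5),
            vector.rings > 4,
            vector.b_1rotN > 10,
            vector.a_don > 5,
            vector.a_acc > 8,
        )
    )
    return violations, int(violations < 2)


def compute_descriptors(smiles_canonical: str) -> DescriptorVector:
    """Compute the full descriptor vector for one washed SMILES.

    Pure function of the molecular graph: identical SMILES give identical
    vectors across runs.
    """
    mol = Chem.MolFromSmiles(smiles_canonical)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles_canonical!r}")

    a_heavy = mol.GetNumHeavyAtoms()
    a_aro = sum(1 for a in mol.GetAtoms() if a.GetIsAromatic())
    a_nC = sum(1 for a in mol.GetAtoms() if a.GetAtomicNum() == 6)
    b_count = mol.GetNumBonds()
    b_ar = sum(1 for b in mol.GetBonds() if b.GetIsAromatic())
    b_1rotN = _rotatable_bond_count(mol)
    slogp = Crippen.MolLogP(mol)
    mw = Descriptors.MolWt(mol)
    rings = rdMolDescriptors.CalcNumRings(mol)
    aromatic_proportion = a_aro / a_heavy
    logs = 0.16 - 0.63 * slogp - 0.0062 * mw + 0.066 * b_1rotN - 0.74 * aromatic_proportion
    chiral = len(
        Chem.FindMolChiralCenters(mol, includeUnassigned=True, useLegacyImplementation=False)
    )

    partial = DescriptorVector(
        a_heavy=a_heavy,
        a_aro=a_aro,
        a_acc=len(mol.GetSubstructMatches(_ACCEPTOR)),
        a_don=len(mol.GetSubstructMatches(_DONOR)),
        a_acid=len(mol.GetSubstructMatches(_ACID_SITES)),
        a_base=len(mol.GetSubstructMatches(_BASE_SITES)),
        a_nC=a_nC,
        b_count=b_count,
        b_ar=b_ar,
        b_1rotN=b_1rotN,
        FCharge=Chem.GetFormalCharge(mol),
        SlogP=slogp,
        logS=logs,
        chiral=chiral,
        rings=rings,
        lip_violation=0,
        lip_druglike=1,
        opr_violation=0,
        opr_leadlike=1,
        mol_weight=mw,
    )
    lip_v, lip_d = lipinski(partial, mw)
    opr_v, opr_d = oprea(partial, mw)
    object.__setattr__(partial, "lip_violation", lip_v)
    object.__setattr__(partial, "lip_druglike", lip_d)
    object.__setattr__(partial, "opr_violation", opr_v)
    object.__setattr__(partial, "opr_leadlike", opr_d)
    return partial


def descriptor_table(
    smiles: Iterable[str], index: Sequence | None = None
) -> pd.DataFrame:
    """Descriptor table for many ligands, one row per SMILES.

    Columns are the 29 analyzed codes; the index is ``index`` if given
    (typically ligand ids), else the SMILES themselves.  Duplicated SMILES are
    computed once and broadcast.
    """
    smiles = list(smiles)
    cache: dict[str, dict[str, float]] = {}
    rows = []
    for smi in smiles:
        if smi not in cache:
            cache[smi] = compute_descriptors(smi).as_dict()
        rows.append(cache[smi])
    df = pd.DataFrame(rows, index=index if index is not None else smiles)
    return df[list(ANALYZED_CODES)]
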