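"""Curation of ligand / protein / assay inputs.

Reads the tabular and FASTA inputs, applies the curation rules used throughout
the package (structure wash, exact-duplicate removal, assay keyword filtering,
HTS removal, activity requirement, panel-artifact flagging) and emits clean,
labeled ligand sets ready for descriptor computation and clustering.

The *wash* normalizes each structure to the dominant species expected at
physiological pH: the largest fragment is kept (salt stripping), strong acids
are deprotonated and strong bases protonated according to a fixed SMARTS rule
table, and the result is emitted as canonical SMILES.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from rdkit import Chem
from rdkit import RDLogger

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

SET_LABELS = ("allosteric", "competitive")

#: stem searched (case-insensitive, substring-with-wildcard) in assay descriptions
KEYWORD_STEMS = {"allosteric": "alloster", "competitive": "compet"}

#: amino-acid alphabet accepted for protein sequences
AA_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

#: a ligand annotated against more targets than this is treated as a
#: panel-screening artifact (single-study panels of >200 targets exceed it;
#: ordinary polypharmacology stays below it)
DEFAULT_MAX_TARGETS = 100


class WashError(ValueError):
    """Raised when a SMILES cannot be parsed/normalized."""


@dataclass(frozen=True)
class LigandRecord:
    """One curated ligand: identity, washed structure, set label, targets."""

    ligand_id: str
    smiles_raw: str
    set_label: str
    smiles_canonical: str | None = None
    source: str = "other"
    target_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.set_label not in SET_LABELS:
            raise ValueError(f"set_label must be one of {SET_LABELS}, got {self.set_label!r}")


@dataclass(frozen=True)
class ProteinRecord:
    """A target protein sequence. ``name`` may be the sentinel 'None'."""

    protein_id: str
    sequence: str
    name: str = "None"

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if not seq:
            raise ValueError(f"protein {self.protein_id}: empty sequence")
        bad = set(seq) - AA_ALPHABET
        if bad:
            raise ValueError(f"protein {self.protein_id}: non-standard residues {sorted(bad)}")
        object.__setattr__(self, "sequence", seq)


@dataclass(frozen=True)
class AssayRecord:
    """One assay: free-text description, HTS flag, activity value, ligand links."""

    assay_id: str
    description: str
    is_hts: bool = False
    standard_value: float | None = None
    ligand_ids: tuple[str, ...] = ()


# --------------------------------------------------------------------------
# wash: salt stripping + fixed pH-7 ionization rules
# --------------------------------------------------------------------------

# (SMARTS, index of the atom to modify).  Acids lose a proton, bases gain one.
# The table covers the classic strong acids (carboxylic, sulfonic,
# phosphoric/phosphonic, tetrazole) and strong bases (aliphatic amines,
# amidines/guanidines).  Weak acids (phenols, amide N-H) and weak bases
# (anilines, aromatic N) stay neutral.  Charged forms no longer match the
# neutral patterns, which makes the wash idempotent.
_ACID_RULES: list[tuple[str, int]] = [
    ("[CX3](=O)[OX2H1]", 2),            # carboxylic acid -> carboxylate
    ("[SX4](=O)(=O)[OX2H1]", 3),        # sulfonic acid
    ("[PX4](=[OX1])[OX2H1]", 2),        # phosphonic / phosphoric O-H
    ("[nX3H1]1nnnc1", 0),               # tetrazole N-H
]

_BASE_RULES: list[tuple[str, int]] = [
    # aliphatic primary/secondary/tertiary amine: not aromatic-attached
    # (aniline-type), not amide/amidine/sulfonamide nitrogen
    ("[NX3;H2,H1,H0;+0;!$([N]a);!$([N][#6]=[O,S,N,P]);!$([N][S,P]=[O,S])]", 0),
    # amidine / guanidine: protonate the sp2 nitrogen
    ("[NX2;+0]=[CX3;!$([C]=[O,S])][NX3;+0]", 0),
]

_ACID_PATTERNS = [(Chem.MolFromSmarts(s), i) for s, i in _ACID_RULES]
_BASE_PATTERNS = [(Chem.MolFromSmarts(s), i) for s, i in _BASE_RULES]


def _largest_fragment(mol: Chem.Mol) -> Chem.Mol:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    # ties broken by canonical SMILES so the choice is order-independent
    return max(frags, key=lambda m: (m.GetNumHeavyAtoms(), Chem.MolToSmiles(m)))


def wash(smiles_raw: str) -> str:
    """Normalize a raw SMILES to its washed canonical form.

    Keeps the largest fragment by heavy-atom count, deprotonates strong acids
    and protonates strong bases per the fixed rule table, and returns canonical
    SMILES.  Idempotent: ``wash(wash(s)) == wash(s)``.

    Raises
    ------
    WashError
        If the SMILES does not parse or has no heavy atom.
    """
    mol = Chem.MolFromSmiles(smiles_raw)
    if mol is None:
        raise WashError(f"unparsable SMILES: {smiles_raw!r}")
    mol = _largest_fragment(mol)
    if mol.GetNumHeavyAtoms() < 1:
        raise WashError(f"no heavy atoms in {smiles_raw!r}")
    rw = Chem.RWMol(mol)
    for patt, pos in _ACID_PATTERNS:
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[pos])
            if atom.GetFormalCharge() == 0 and atom.GetTotalNumHs() >= 1:
                atom.SetFormalCharge(-1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() - 1)
                atom.SetNoImplicit(True)
    for patt, pos in _BASE_PATTERNS:
        for match in rw.GetSubstructMatches(patt):
            atom = rw.GetAtomWithIdx(match[pos])
            if atom.GetFormalCharge() == 0:
                atom.SetFormalCharge(+1)
                atom.SetNumExplicitHs(atom.GetTotalNumHs() + 1)
                atom.SetNoImplicit(True)
    out = rw.GetMol()
    try:
        Chem.SanitizeMol(out)
    except Exception as exc:  # pragma: no cover - rule table keeps valences legal
        raise WashError(f"sanitization failed after wash of {smiles_raw!r}: {exc}") from exc
    return Chem.MolToSmiles(out)


def wash_record(record: LigandRecord) -> LigandRecord:
    """Return a copy of ``record`` with ``smiles_canonical`` filled in."""
    return replace(record, smiles_canonical=wash(record.smiles_raw))


# --------------------------------------------------------------------------
# dedup / assay filtering / panel artifacts
# --------------------------------------------------------------------------

def dedup(records: Sequence[LigandRecord]) -> list[LigandRecord]:
    """Collapse exact (ligand, protein) duplicates within each set.

    One output record per (set_label, washed SMILES); its ``target_ids`` is the
    union over all input rows for that ligand, so a compound hitting several
    proteins keeps every link while each protein-ligand pair appears once.
    Idempotent and order-insensitive at the level of the resulting pairs.
    """
    merged: dict[tuple[str, str], dict] = {}
    for rec in records:
        if rec.smiles_canonical is None:
            raise ValueError(f"record {rec.ligand_id} is not washed")
        key = (rec.set_label, rec.smiles_canonical)
        slot = merged.setdefault(key, {"ids": set(), "targets": set(), "rec": rec})
        slot["ids"].add(rec.ligand_id)
        slot["targets"].update(rec.target_ids)
    out = []
    for (label, smi), slot in sorted(merged.items()):
        rec = slot["rec"]
        out.append(
            LigandRecord(
                ligand_id=min(slot["ids"]),
                smiles_raw=rec.smiles_raw,
                set_label=label,
                smiles_canonical=smi,
                source=rec.source,
                target_ids=tuple(sorted(slot["targets"])),
            )
        )
    return out


def filter_assays(
    assays: Sequence[AssayRecord],
    mode: str,
    curation_blacklist: Iterable[str] = (),
) -> list[AssayRecord]:
    """Keep assays whose description matches the mode's keyword stem.

    A kept assay (i) contains the stem (``alloster``/``compet``) as a
    case-insensitive substring of its description, (ii) is not flagged HTS, and
    (iii) is not blacklisted by manual curation.
    """
    if mode not in KEYWORD_STEMS:
        raise ValueError(f"mode must be one of {tuple(KEYWORD_STEMS)}, got {mode!r}")
    stem = KEYWORD_STEMS[mode]
    blacklist = set(curation_blacklist)
    return [
        a
        for a in assays
        if stem in a.description.lower() and not a.is_hts and a.assay_id not in blacklist
    ]


def active_ligand_ids(assays: Sequence[AssayRecord]) -> set[str]:
    """Ligands reported active (standard value present and > 0) in >= 1 assay."""
    out: set[str] = set()
    for a in assays:
        if a.standard_value is not None and a.standard_value > 0:
            out.update(a.ligand_ids)
    return out


def flag_panel_artifacts(
    records: Sequence[LigandRecord], max_targets: int = DEFAULT_MAX_TARGETS
) -> list[str]:
    """Ids of ligands annotated against more than ``max_targets`` targets.

    Single-study panel screens (hundreds of targets for one compound) massively
    overweight one molecule; such ligands are removed before analysis.
    """
    if max_targets < 1:
        raise ValueError("max_targets must be >= 1")
    return [r.ligand_id for r in records if len(r.target_ids) > max_targets]


# --------------------------------------------------------------------------
# readers
# --------------------------------------------------------------------------

_LIGAND_COLUMNS = ("ligand_id", "smiles", "set_label", "target_ids")
_ASSAY_COLUMNS = ("assay_id", "description", "is_hts", "standard_value", "ligand_ids")


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path, sheet_name=0)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    return pd.read_csv(path, sep=sep)


def read_ligand_table(source: str | Path | pd.DataFrame) -> list[LigandRecord]:
    """Read a ligand table (CSV/TSV/XLSX or DataFrame) into records.

    Mandatory columns: ``ligand_id, smiles, set_label, target_ids`` (targets
    ``;``-separated); optional ``source``.  Malformed rows (missing SMILES or
    unknown set label) are skipped and counted in a log message; a missing
    mandatory column is a hard error naming the column.
    """
    df = source if isinstance(source, pd.DataFrame) else _read_table(source)
    for col in _LIGAND_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"ligand table is missing mandatory column {col!r}")
    records: list[LigandRecord] = []
    skipped = 0
    for row in df.itertuples(index=False):
        smiles = getattr(row, "smiles")
        label = getattr(row, "set_label")
        if not isinstance(smiles, str) or not smiles.strip() or label not in SET_LABELS:
            skipped += 1
            continue
        raw_targets = getattr(row, "target_ids")
        targets = tuple(
            t.strip() for t in str(raw_targets).split(";") if t.strip()
        ) if pd.notna(raw_targets) else ()
        records.append(
            LigandRecord(
                ligand_id=str(getattr(row, "ligand_id")),
                smiles_raw=smiles.strip(),
                set_label=label,
                source=str(getattr(row, "source", "other") or "other"),
                target_ids=targets,
            )
        )
    if skipped:
        logger.warning("read_ligand_table: skipped %d malformed row(s)", skipped)
    return records


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-FASTA file; the id up to the first whitespace is the protein id."""
    records = []
    for entry in SeqIO.parse(str(path), "fasta"):
        name = entry.description[len(entry.id) :].strip() or "None"
        records.append(ProteinRecord(protein_id=entry.id, sequence=str(entry.seq), name=name))
    return records


def _parse_bool(x) -> bool:
    if isinstance(x, str):
        return x.strip().lower() in ("1", "true", "yes", "y", "t")
    return bool(x) and not pd.isna(x)


def read_assay_table(source: str | Path | pd.DataFrame) -> list[AssayRecord]:
    """Read an assay table with columns ``assay_id,description,is_hts,standard_value,ligand_ids``."""
    df = source if isinstance(source, pd.DataFrame) else _read_table(source)
    for col in _ASSAY_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"assay table is missing mandatory column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        sv = getattr(row, "standard_value")
        sv = None if pd.isna(sv) else float(sv)
        raw_ligs = getattr(row, "ligand_ids")
        ligs = tuple(
            t.strip() for t in str(raw_ligs).split(";") if t.strip()
        ) if pd.notna(raw_ligs) else ()
        out.append(
            AssayRecord(
                assay_id=str(getattr(row, "assay_id")),
                description=str(getattr(row, "description")),
                is_hts=_parse_bool(getattr(row, "is_hts")),
                standard_value=sv,
                ligand_ids=ligs,
            )
        )
    return out


# --------------------------------------------------------------------------
# end-to-end curation
# --------------------------------------------------------------------------

@dataclass
class CurationReport:
    """Outcome of :func:`curate`: clean records plus an audit trail."""

    records: list[LigandRecord]
    rejected: dict[str, str] = field(default_factory=dict)  # ligand_id -> reason code
    panel_flagged: list[str] = field(default_factory=list)
    n_input: int = 0
    n_duplicates_removed: int = 0
    n_assay_filtered: int = 0


def curate(
    records: Sequence[LigandRecord],
    assays: Sequence[AssayRecord] | None = None,
    mode: str | None = None,
    curation_blacklist: Iterable[str] = (),
    max_targets: int = DEFAULT_MAX_TARGETS,
) -> CurationReport:
    """Apply the full curation pipeline to one labeled ligand set.

    Steps, in order: optional assay gate (keyword + non-HTS + blacklist, then
    the activity requirement; records from the curated allosteric database
    source ``ASD`` bypass the gate), wash, rejection of ligands without targets,
    exact-duplicate removal, panel-artifact removal.
    """
    report = CurationReport(records=[], n_input=len(records))
    work = list(records)

    if assays is not None and mode is not None:
        kept_assays = filter_assays(assays, mode, curation_blacklist)
        active = active_ligand_ids(kept_assays)
        gated = []
        for rec in work:
            if rec.source == "ASD" or rec.ligand_id in active:
                gated.append(rec)
            else:
                report.n_assay_filtered += 1
        work = gated

    washed = []
    for rec in work:
        try:
            rec = wash_record(rec)
        except WashError:
            report.rejected[rec.ligand_id] = "unparsable_smiles"
            continue
        if not rec.target_ids:
            report.rejected[rec.ligand_id] = "no_targets"
            continue
        washed.append(rec)

    deduped = dedup(washed)
    report.n_duplicates_removed = len(washed) - len(deduped)

    flagged = set(flag_panel_artifacts(deduped, max_targets))
    report.panel_flagged = sorted(flagged)
    report.records = [r for r in deduped if r.ligand_id not in flagged]
    return report
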