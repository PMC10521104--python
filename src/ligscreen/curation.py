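"""Corpus curation: database-dialect filters and activity labeling.

DrugBank-dialect corpora keep only small molecules; PDB-dialect corpora drop
crystallization adjuvants, solvents and ions; ChEMBL-dialect activity rows
are restricted to single-protein assays with unqualified (=) values of the
five retained activity types, normalized to nM, then reduced to one
active/inactive label per (structure, target) pair by strict majority vote
with an activity threshold of 1000 nM (inclusive: value <= threshold is
active).
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from rdkit import Chem

from .models import ActivityRow, LabeledLigand, MoleculeRecord, Relation

log = logging.getLogger(__name__)

DEFAULT_ACTIVITY_TYPES = frozenset({"Ki", "IC50", "Kd", "EC50", "Potency"})

#: multiplicative factor to nM for each recognised concentration unit
UNIT_TO_NM = {
    "pm": 1e-3,
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,
    "mm": 1e6,
    "m": 1e9,
}


def _default_stoplist() -> frozenset:
    text = resources.files("ligscreen.data").joinpath("pdb_stoplist.txt").read_text()
    codes = {line.strip().upper() for line in text.splitlines()
             if line.strip() and not line.startswith("#")}
    return frozenset(codes)


@dataclass
class CurationConfig:
    """Constants of the three corpus filters.

    ``activity_threshold_nM`` separates active from inactive ChEMBL ligands;
    ``threshold_inclusive`` keeps the boundary value active.  The PDB
    stoplist names het codes of common solvents, buffer components and ions.
    """

    activity_threshold_nM: float = 1000.0
    threshold_inclusive: bool = True
    allowed_assay_format: str = "Single Protein"
    allowed_activity_types: frozenset = DEFAULT_ACTIVITY_TYPES
    pdb_stoplist: frozenset = field(default_factory=_default_stoplist)
    max_inorganic_heavy_atoms: int = 1

    def __post_init__(self) -> None:
        if self.activity_threshold_nM <= 0:
            raise ValueError("activity_threshold_nM must be > 0")
        if not self.pdb_stoplist:
            raise ValueError("pdb_stoplist must be non-empty")


# ---------------------------------------------------------------------------
# per-corpus molecule filters


def filter_drugbank(records: Sequence[MoleculeRecord]) -> List[MoleculeRecord]:
    """Keep only small-molecule entries (drops biologics and unknowns)."""
    from .models import MoleculeType

    kept = [r for r in records if r.molecule_type == MoleculeType.small_molecule]
    if records and not kept:
        log.warning("drugbank filter removed every record (%d)", len(records))
    return kept


def _is_contaminant(record: MoleculeRecord, config: CurationConfig) -> bool:
    if record.het_code and record.het_code.upper() in config.pdb_stoplist:
        return True
    mol = record.mol if record.mol is not None else Chem.MolFromSmiles(record.smiles)
    if mol is None:
        return False
    n_heavy = mol.GetNumHeavyAtoms()
    if n_heavy <= config.max_inorganic_heavy_atoms:
        return True  # monoatomic ions and single-atom fragments
    has_carbon = any(a.GetAtomicNum() == 6 for a in mol.GetAtoms())
    net_charge = Chem.GetFormalCharge(mol)
    if net_charge != 0 and not has_carbon:
        return True  # inorganic charged species (e.g. sulfate, phosphate)
    return False


def filter_pdb_ligands(records: Sequence[MoleculeRecord],
                       config: Optional[CurationConfig] = None) -> List[MoleculeRecord]:
    """Drop crystallization adjuvants, solvent molecules and ions."""
    config = config or CurationConfig()
    kept, skipped = [], 0
    for r in records:
        if r.het_code is None and r.mol is None and not r.smiles:
            skipped += 1
            continue
        if not _is_contaminant(r, config):
            kept.append(r)
    if skipped:
        log.warning("pdb filter skipped %d records lacking both het_code and structure", skipped)
    return kept


# ---------------------------------------------------------------------------
# activity-row curation


def convert_to_nM(value: float, units: str) -> Optional[float]:
    """Convert a concentration to nM; None when the unit is unrecognised."""
    factor = UNIT_TO_NM.get(units.strip().lower())
    if factor is None:
        return None
    return value * factor


def filter_chembl(rows: Sequence[ActivityRow],
                  config: Optional[CurationConfig] = None,
                  drop_log: Optional[list] = None) -> List[ActivityRow]:
    """Retain single-protein, unqualified rows of the allowed activity types.

    Retained rows have their ``value`` normalized to nM and ``units`` set to
    ``"nM"``.  Dropped rows are recorded in ``drop_log`` as
    ``(molecule_id, reason_code)`` when a list is supplied.
    """
    config = config or CurationConfig()
    kept: List[ActivityRow] = []
    for row in rows:
        reason = None
        if row.assay_format != config.allowed_assay_format:
            reason = "assay_format"
        elif row.activity_type not in config.allowed_activity_types:
            reason = "activity_type"
        elif row.relation != Relation.eq:
            reason = "relation"
        elif row.value is None:
            reason = "missing_value"
        else:
            value_nm = convert_to_nM(row.value, row.units)
            if value_nm is None:
                reason = "units"
        if reason is not None:
            if drop_log is not None:
                drop_log.append((row.molecule_id, reason))
            continue
        kept.append(ActivityRow(
            molecule_id=row.molecule_id, target_id=row.target_id,
            target_name=row.target_name, organism=row.organism,
            assay_format=row.assay_format, activity_type=row.activity_type,
            value=value_nm, units="nM", relation=Relation.eq,
            smiles=row.smiles, canonical_key=row.canonical_key,
        ))
    return kept


def label_activity(value_nM: float, config: Optional[CurationConfig] = None) -> str:
    """Classify a potency in nM as active or inactive at the threshold."""
    config = config or CurationConfig()
    if value_nM < 0:
        raise ValueError(f"negative activity value: {value_nM}")
    if config.threshold_inclusive:
        return "active" if value_nM <= config.activity_threshold_nM else "inactive"
    return "active" if value_nM < config.activity_threshold_nM else "inactive"


def resolve_duplicates(labels: Sequence[str], canonical_key: str = "",
                       target_id: str = "") -> Optional[LabeledLigand]:
    """Strict majority vote over duplicate labels; exact tie drops the pair."""
    if not labels:
        raise ValueError("empty label list")
    counts = Counter(labels)
    (top, n_top), *rest = counts.most_common()
    if rest and rest[0][1] == n_top:
        log.info("dropping (%s, %s): tied labels %s", canonical_key, target_id, dict(counts))
        return None
    return LabeledLigand(canonical_key=canonical_key, target_id=target_id,
                         label=top, n_supporting_rows=len(labels))


def label_ligands(rows: Sequence[ActivityRow],
                  config: Optional[CurationConfig] = None) -> List[LabeledLigand]:
    """Curated activity rows -> one label per (canonical_key, target_id).

    Rows must already have passed :func:`filter_chembl` (values in nM).
    Ties between duplicate rows are dropped.
    """
    config = config or CurationConfig()
    grouped: Dict[Tuple[str, str], List[str]] = defaultdict(list)
    for row in rows:
        key = row.canonical_key or row.molecule_id
        grouped[(key, row.target_id)].append(label_activity(row.value, config))
    out: List[LabeledLigand] = []
    for (key, target), labels in sorted(grouped.items()):
        lig = resolve_duplicates(labels, canonical_key=key, target_id=target)
        if lig is not None:
            out.append(lig)
    return out
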