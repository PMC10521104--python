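"""Shared data model for the screening pipeline.

Every stage exchanges plain dataclasses (one per record kind) plus pandas
DataFrames for tabular interchange.  Structures are carried as RDKit ``Mol``
objects; 3D conformers, when present, are in Angstroms.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from enum import Enum
from typing import Any, Mapping, Optional, Sequence

try:  # rdkit Mol is only used as an opaque payload here
    from rdkit import Chem
except ImportError:  # pragma: no cover
    Chem = None


class Corpus(str, Enum):
    drugbank = "drugbank"
    pdb = "pdb"
    chembl = "chembl"
    query = "query"


class MoleculeType(str, Enum):
    small_molecule = "small_molecule"
    biologic = "biologic"
    unknown = "unknown"


FINGERPRINT_NAMES = ("maccs", "ecfp4", "ecfp6", "fcfp4", "fcfp6")


@dataclass
class MoleculeRecord:
    """One curated ligand from a corpus.

    ``canonical_key`` is the canonical isomeric SMILES used to join the same
    chemical structure across corpora; ``mol`` optionally carries 3D
    conformers (e.g. a crystallographic pose for PDB-dialect ligands).
    """

    record_id: str
    corpus: Corpus
    smiles: str
    canonical_key: str
    name: Optional[str] = None
    molecule_type: Optional[MoleculeType] = None
    het_code: Optional[str] = None
    mol: Optional[Any] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.record_id:
            raise ValueError("record_id must be non-empty")
        self.corpus = Corpus(self.corpus)
        if self.molecule_type is not None:
            self.molecule_type = MoleculeType(self.molecule_type)


class Relation(str, Enum):
    eq = "eq"
    lt = "lt"
    gt = "gt"
    lte = "lte"
    gte = "gte"
    other = "other"


#: symbols accepted in input tables for each relation
RELATION_ALIASES = {
    "=": Relation.eq,
    "==": Relation.eq,
    "eq": Relation.eq,
    "<": Relation.lt,
    "lt": Relation.lt,
    ">": Relation.gt,
    "gt": Relation.gt,
    "<=": Relation.lte,
    "lte": Relation.lte,
    ">=": Relation.gte,
    "gte": Relation.gte,
}


@dataclass
class ActivityRow:
    """One ChEMBL-dialect bioactivity measurement."""

    molecule_id: str
    target_id: str
    target_name: str
    organism: str
    assay_format: str
    activity_type: str
    value: Optional[float]
    units: str
    relation: Relation
    smiles: str = ""
    canonical_key: str = ""

    def __post_init__(self) -> None:
        if isinstance(self.relation, str):
            self.relation = RELATION_ALIASES.get(self.relation, Relation.other)
        if self.value is not None and self.value < 0:
            raise ValueError(f"activity value must be >= 0, got {self.value}")


@dataclass
class LabeledLigand:
    """Majority-vote activity label for one (structure, target) pair."""

    canonical_key: str
    target_id: str
    label: str  # "active" | "inactive"
    n_supporting_rows: int

    def __post_init__(self) -> None:
        if self.label not in ("active", "inactive"):
            raise ValueError(f"invalid label {self.label!r}")
        if self.n_supporting_rows < 1:
            raise ValueError("n_supporting_rows must be >= 1")


@dataclass
class SimilarityRecord:
    """One query-reference pair with 2D Tanimoto values and 3D scores."""

    query_id: str
    reference_id: str
    tc: dict  # fingerprint name -> Tanimoto in [0, 1]
    tc_combo: Optional[float] = None
    shape_tanimoto: Optional[float] = None
    color_tanimoto: Optional[float] = None
    pass_2d: bool = False
    pass_3d: bool = False
    pass_consensus: bool = False

    @property
    def pair(self) -> tuple:
        return (self.query_id, self.reference_id)


@dataclass
class SimilarityTable:
    """Similarity records plus the provenance they were computed under."""

    rows: list
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = [r.pair for r in self.rows]
        if len(pairs) != len(set(pairs)):
            raise ValueError("duplicate (query_id, reference_id) pairs in table")

    def hits(self, flag: str = "pass_2d") -> list:
        return [r for r in self.rows if getattr(r, flag)]


@dataclass
class OverlayResult:
    """Optimized rigid-body superposition of a query onto a reference."""

    rotation: Any  # 3x3 proper rotation applied to the query
    translation: Any  # length-3 vector, Angstrom
    shape_tanimoto: float
    color_tanimoto: float
    tanimoto_combo: float
    n_starts_evaluated: int = 0


@dataclass
class TargetSummary:
    """One row of the per-target hit-count table used for prioritisation."""

    uniprot_id: str
    target_name: str
    organism: str
    pdb_count: int
    db_count: int
    chembl_active: int
    chembl_inactive: int

    @property
    def n_corpora(self) -> int:
        chembl = self.chembl_active + self.chembl_inactive
        return sum(1 for c in (self.pdb_count, self.db_count, chembl) if c > 0)

    @property
    def active_minus_inactive(self) -> int:
        return self.chembl_active - self.chembl_inactive

    @property
    def total_ligands(self) -> int:
        return (self.pdb_count + self.db_count
                + self.chembl_active + self.chembl_inactive)


def snapshot_hash(params: Mapping[str, Any]) -> str:
    """Stable short hash of a parameter mapping, recorded into output tables."""
    blob = json.dumps(params, sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def records_to_frame(records: Sequence[Any]):
    """Flatten a sequence of dataclass records into a pandas DataFrame."""
    import pandas as pd

    rows = []
    for r in records:
        d = asdict(r)
        d.pop("mol", None)
        tc = d.pop("tc", None)
        if tc is not None:
            for k in FINGERPRINT_NAMES:
                d[f"tc_{k}"] = tc.get(k)
        rows.append(d)
    return pd.DataFrame(rows)
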