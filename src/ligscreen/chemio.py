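"""Structure and table I/O plus SMILES canonicalization.

Supported corpus inputs
-----------------------
``.smi``
    SMILES, whitespace, identifier (one molecule per line).
``.sdf``
    V2000 SD file; 3D coordinates (Angstrom) are retained on the record.
``.csv`` / ``.tsv``
    Dialect-specific columns:

    - drugbank: ``id,smiles,type[,name]``
    - pdb:      ``het_code,smiles[,sdf_path][,name]``
    - chembl:   ``molecule_id,smiles,target_id,target_name,organism,
      assay_format,activity_type,value,units,relation``

Malformed entries are skipped and counted, never fatal; a corpus with zero
parsable records is an error.
"""
from __future__ import annotations

import json
import logging
import os
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .models import (
    ActivityRow,
    Corpus,
    MoleculeRecord,
    MoleculeType,
    SimilarityRecord,
    SimilarityTable,
    TargetSummary,
    FINGERPRINT_NAMES,
)

log = logging.getLogger(__name__)
RDLogger.DisableLog("rdApp.error")


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed."""

    def __init__(self, smiles: str):
        super().__init__(f"unparsable SMILES: {smiles!r}")
        self.smiles = smiles


class CorpusReadError(RuntimeError):
    pass


def mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(smiles)
    return mol


def canonicalize(smiles: str) -> str:
    """Canonical isomeric SMILES: the cross-corpus structure key.

    Idempotent, invariant to atom input order and aromatic/kekulized
    notation; stereo descriptors are preserved.  No tautomer normalization
    is applied — distinct tautomers keep distinct keys on purpose.
    """
    return Chem.MolToSmiles(mol_from_smiles(smiles))


# ---------------------------------------------------------------------------
# corpus readers

REQUIRED_COLUMNS = {
    Corpus.drugbank: ["id", "smiles", "type"],
    Corpus.pdb: ["het_code", "smiles"],
    Corpus.chembl: ["molecule_id", "smiles", "target_id", "assay_format",
                    "activity_type", "value", "units", "relation"],
    Corpus.query: ["id", "smiles"],
}

_TYPE_ALIASES = {
    "small molecule": MoleculeType.small_molecule,
    "small_molecule": MoleculeType.small_molecule,
    "biotech": MoleculeType.biologic,
    "biologic": MoleculeType.biologic,
}


def _molecule_type(raw: str) -> MoleculeType:
    return _TYPE_ALIASES.get(str(raw).strip().lower(), MoleculeType.unknown)


def read_corpus(path: Union[str, Path], dialect: Union[str, Corpus]) -> List[MoleculeRecord]:
    """Read one corpus file into MoleculeRecords, preserving input order.

    Unparsable entries are counted and logged, not fatal; a missing file or
    zero parsable records raises :class:`CorpusReadError`.
    """
    path = Path(path)
    dialect = Corpus(dialect)
    if not path.exists():
        raise CorpusReadError(f"corpus file not found: {path}")
    suffix = path.suffix.lower()
    if suffix == ".smi":
        records, skipped = _read_smi(path, dialect)
    elif suffix == ".sdf":
        records, skipped = _read_sdf(path, dialect)
    elif suffix in (".csv", ".tsv"):
        records, skipped = _read_table_corpus(path, dialect)
    else:
        raise CorpusReadError(f"unsupported corpus format: {path.suffix}")
    if skipped:
        log.warning("%s: skipped %d unparsable entries", path.name, skipped)
    if not records:
        raise CorpusReadError(
            f"no parsable {dialect.value}-dialect records in {path}")
    return records


def _record(dialect: Corpus, record_id: str, smiles: str, **kw) -> MoleculeRecord:
    mol = mol_from_smiles(smiles)
    return MoleculeRecord(
        record_id=str(record_id),
        corpus=dialect,
        smiles=smiles,
        canonical_key=Chem.MolToSmiles(mol),
        mol=kw.pop("mol", mol),
        **kw,
    )


def _read_smi(path: Path, dialect: Corpus):
    records, skipped = [], 0
    for i, line in enumerate(path.read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split(None, 1)
        smiles = parts[0]
        rid = parts[1].strip() if len(parts) > 1 else f"{path.stem}_{i + 1}"
        try:
            records.append(_record(dialect, rid, smiles))
        except SmilesParseError:
            skipped += 1
    return records, skipped


def _read_sdf(path: Path, dialect: Corpus):
    records, skipped = [], 0
    supplier = Chem.SDMolSupplier(str(path), removeHs=True)
    for i, mol in enumerate(supplier):
        if mol is None:
            skipped += 1
            continue
        rid = mol.GetProp("_Name") if mol.HasProp("_Name") and mol.GetProp("_Name") else f"{path.stem}_{i + 1}"
        het = mol.GetProp("het_code") if mol.HasProp("het_code") else None
        smiles = Chem.MolToSmiles(mol)
        records.append(MoleculeRecord(
            record_id=rid,
            corpus=dialect,
            smiles=smiles,
            canonical_key=smiles,
            het_code=het,
            mol=mol,
        ))
    return records, skipped


def _read_table_corpus(path: Path, dialect: Corpus):
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    required = REQUIRED_COLUMNS[dialect]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise CorpusReadError(
            f"{dialect.value} table {path} lacks required columns: {missing}")
    records, skipped = [], 0
    seen = set()
    for _, row in df.iterrows():
        try:
            if dialect == Corpus.drugbank:
                rec = _record(dialect, row["id"], row["smiles"],
                              molecule_type=_molecule_type(row["type"]),
                              name=row.get("name") or None)
            elif dialect == Corpus.pdb:
                rec = _record(dialect, row["het_code"], row["smiles"],
                              het_code=row["het_code"],
                              name=row.get("name") or None)
                sdf_path = row.get("sdf_path", "")
                if sdf_path:
                    rec.mol = _load_single_sdf(path.parent / sdf_path)
            else:  # chembl / query: one record per distinct molecule id
                rid = row.get("molecule_id") or row.get("id")
                if rid in seen:
                    continue
                seen.add(rid)
                rec = _record(dialect, rid, row["smiles"])
        except (SmilesParseError, OSError):
            skipped += 1
            continue
        records.append(rec)
    return records, skipped


def _load_single_sdf(path: Path) -> Chem.Mol:
    mols = [m for m in Chem.SDMolSupplier(str(path), removeHs=True) if m is not None]
    if not mols:
        raise OSError(f"no parsable molecule in {path}")
    return mols[0]


def read_activities(path: Union[str, Path]) -> List[ActivityRow]:
    """Read a ChEMBL-dialect CSV/TSV into ActivityRows (one per table row)."""
    path = Path(path)
    if not path.exists():
        raise CorpusReadError(f"activity file not found: {path}")
    sep = "\t" if path.suffix.lower() == ".tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS[Corpus.chembl] if c not in df.columns]
    if missing:
        raise CorpusReadError(f"chembl table {path} lacks columns: {missing}")
    rows = []
    for _, r in df.iterrows():
        try:
            value = float(r["value"]) if r["value"] != "" else None
        except ValueError:
            value = None
        try:
            key = canonicalize(r["smiles"])
        except SmilesParseError:
            key = ""
        rows.append(ActivityRow(
            molecule_id=r["molecule_id"],
            target_id=r["target_id"],
            target_name=r.get("target_name", ""),
            organism=r.get("organism", ""),
            assay_format=r["assay_format"],
            activity_type=r["activity_type"],
            value=value,
            units=r["units"],
            relation=r["relation"],
            smiles=r["smiles"],
            canonical_key=key,
        ))
    return rows


# ---------------------------------------------------------------------------
# table writers / readers

_FLOAT_FMT = "%.6g"  # fixed six-significant-digit serialization


def _format_value(v):
    if isinstance(v, float):
        return _FLOAT_FMT % v
    return v


def similarity_table_to_frame(table: SimilarityTable) -> pd.DataFrame:
    rows = []
    for r in table.rows:
        d = {"query_id": r.query_id, "reference_id": r.reference_id}
        for name in FINGERPRINT_NAMES:
            d[f"tc_{name}"] = r.tc.get(name)
        d.update(shape_tanimoto=r.shape_tanimoto, color_tanimoto=r.color_tanimoto,
                 tc_combo=r.tc_combo, pass_2d=r.pass_2d, pass_3d=r.pass_3d,
                 pass_consensus=r.pass_consensus)
        rows.append(d)
    cols = (["query_id", "reference_id"] + [f"tc_{n}" for n in FINGERPRINT_NAMES]
            + ["shape_tanimoto", "color_tanimoto", "tc_combo",
               "pass_2d", "pass_3d", "pass_consensus"])
    return pd.DataFrame(rows, columns=cols)


def frame_to_similarity_table(df: pd.DataFrame, provenance=None) -> SimilarityTable:
    rows = []
    for _, r in df.iterrows():
        def _opt(x):
            return None if pd.isna(x) else float(x)
        rows.append(SimilarityRecord(
            query_id=str(r["query_id"]), reference_id=str(r["reference_id"]),
            tc={n: float(r[f"tc_{n}"]) for n in FINGERPRINT_NAMES
                if f"tc_{n}" in r and not pd.isna(r[f"tc_{n}"])},
            shape_tanimoto=_opt(r.get("shape_tanimoto")),
            color_tanimoto=_opt(r.get("color_tanimoto")),
            tc_combo=_opt(r.get("tc_combo")),
            pass_2d=bool(r.get("pass_2d", False)),
            pass_3d=bool(r.get("pass_3d", False)),
            pass_consensus=bool(r.get("pass_consensus", False)),
        ))
    return SimilarityTable(rows=rows, provenance=provenance or {})


def summaries_to_frame(summaries: Sequence[TargetSummary]) -> pd.DataFrame:
    rows = [{
        "uniprot_id": s.uniprot_id, "target_name": s.target_name,
        "organism": s.organism, "pdb_count": s.pdb_count,
        "db_count": s.db_count, "chembl_active": s.chembl_active,
        "chembl_inactive": s.chembl_inactive, "n_corpora": s.n_corpora,
        "active_minus_inactive": s.active_minus_inactive,
    } for s in summaries]
    cols = ["uniprot_id", "target_name", "organism", "pdb_count", "db_count",
            "chembl_active", "chembl_inactive", "n_corpora",
            "active_minus_inactive"]
    return pd.DataFrame(rows, columns=cols)


def write_table(rows: Union[SimilarityTable, Sequence[TargetSummary], pd.DataFrame],
                path: Union[str, Path], format: Optional[str] = None) -> Path:
    """Serialize a table to csv/tsv/json with 6-significant-digit floats.

    Round-trips losslessly through :func:`read_table` for the same format.
    """
    path = Path(path)
    fmt = format or path.suffix.lstrip(".").lower()
    if fmt not in ("csv", "tsv", "json"):
        raise ValueError(f"unsupported table format: {fmt}")
    if isinstance(rows, SimilarityTable):
        df = similarity_table_to_frame(rows)
    elif isinstance(rows, pd.DataFrame):
        df = rows
    else:
        df = summaries_to_frame(list(rows))
    path.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "json":
        payload = [
            {k: (_FLOAT_FMT % v if isinstance(v, float) and not pd.isna(v)
                 else None if isinstance(v, float) and pd.isna(v) else v)
             for k, v in rec.items()}
            for rec in df.to_dict(orient="records")
        ]
        # floats stored as canonical 6-sig-digit strings to keep byte-level
        # determinism; read_table converts back.
        path.write_text(json.dumps(payload, indent=1) + "\n")
    else:
        sep = "\t" if fmt == "tsv" else ","
        df.to_csv(path, sep=sep, index=False, float_format=_FLOAT_FMT)
    return path


def read_table(path: Union[str, Path]) -> pd.DataFrame:
    path = Path(path)
    fmt = path.suffix.lstrip(".").lower()
    if fmt == "json":
        payload = json.loads(path.read_text())
        df = pd.DataFrame(payload)
        for col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            if not converted.isna().all():
                df[col] = converted
        return df
    sep = "\t" if fmt == "tsv" else ","
    return pd.read_csv(path, sep=sep)
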