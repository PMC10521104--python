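"""Synthetic three-corpus generator with planted ground truth.

Emulates the statistical structure of database-style ligand corpora without
any download: a DrugBank-dialect table mixing small molecules with
biologics, a PDB-dialect SD file mixing organic het groups with
solvent/ion contaminants, and a ChEMBL-dialect activity table mixing
single-protein and other assay formats, the five retained activity types
plus others, qualified relations, inconvertible units, and duplicate rows
with occasional conflicting labels.

Ground truth is planted: close analogs of the query scaffold (single
substituent swaps, so they pass the 2D thresholds by construction) are
placed in all three corpora and assigned active-range potencies against one
designated synthetic target.  A JSON manifest records every planted fact so
pipeline output can be scored for recovery.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem

from .chemio import canonicalize
from .shape import EmbeddingError, generate_conformers
from .states import StateSpace, enumerate_states

log = logging.getLogger(__name__)

#: stoplist contaminants the generator can plant (het code -> SMILES)
CONTAMINANTS = {
    "HOH": "O",
    "NA": "[Na+]",
    "CL": "[Cl-]",
    "K": "[K+]",
    "MG": "[Mg+2]",
    "ZN": "[Zn+2]",
    "SO4": "[O-]S(=O)(=O)[O-]",
    "PO4": "[O-]P(=O)([O-])[O-]",
    "GOL": "OCC(O)CO",
    "EDO": "OCCO",
    "ACT": "CC(=O)[O-]",
    "DMS": "CS(C)=O",
}

#: simple peptide-like SMILES standing in for biologic entries
_BIOLOGIC_SMILES = [
    "CC(N)C(=O)NC(C)C(=O)NC(C)C(=O)O",
    "NCC(=O)NCC(=O)NCC(=O)NCC(=O)O",
    "CC(C)C(N)C(=O)NC(CC(C)C)C(=O)NC(C)C(=O)O",
    "NC(CO)C(=O)NC(CS)C(=O)NC(C)C(=O)O",
    "NC(Cc1ccccc1)C(=O)NC(C)C(=O)NCC(=O)O",
    "NC(CCC(=O)O)C(=O)NC(C)C(=O)NC(CO)C(=O)O",
    "NC(C)C(=O)NC(CC(N)=O)C(=O)NCC(=O)O",
    "NC(CCCNC(N)=N)C(=O)NCC(=O)NC(C)C(=O)O",
]

DECOY_TARGET_POOL = [
    ("SYNTARG_%03d" % i, "Synthetic decoy target %d" % i, "Homo sapiens")
    for i in range(2, 8)
]

RETAINED_ACTIVITY_TYPES = ("IC50", "Ki", "Kd", "EC50", "Potency")
OTHER_ACTIVITY_TYPES = ("AC50", "Inhibition", "Activity")
OTHER_ASSAY_FORMATS = ("Protein Complex", "Cell-based", "Organism")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic corpora.

    Decoy potencies are log-uniform over [1, 1e5] nM (straddling the
    1000 nM activity threshold); planted analog potencies are log-uniform
    over [10, 800] nM, i.e. unambiguously active.
    """

    seed: int = 2020
    n_decoys_per_corpus: int = 30
    n_analogs: int = 5
    planted_target_id: str = "SYNTARG_001"
    planted_target_name: str = "Planted synthetic kinase"
    planted_organism: str = "Homo sapiens"
    analog_edit_ops: Tuple[str, ...] = ("F", "Cl", "C", "OC")
    n_biologics: int = 5
    n_solvent_ion_records: int = 8
    duplicate_rate: float = 0.3
    conflict_rate: float = 0.1
    decoy_value_log10_range: Tuple[float, float] = (0.0, 5.0)   # nM
    analog_value_range: Tuple[float, float] = (10.0, 800.0)     # nM

    def __post_init__(self) -> None:
        if self.n_analogs < 1:
            raise ValueError("n_analogs must be >= 1")
        for r in (self.duplicate_rate, self.conflict_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


def load_vocabulary() -> List[Tuple[str, str]]:
    """The shipped synthetic decoy vocabulary as (smiles, id) pairs."""
    text = resources.files("ligscreen.data").joinpath("decoy_vocabulary.smi").read_text()
    out = []
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        smiles, did = line.split()
        out.append((smiles, did))
    return out


# ---------------------------------------------------------------------------
# analog construction


def _attachment_positions(mol: Chem.Mol) -> List[int]:
    """Aromatic CH carbons, in canonical-rank order for determinism."""
    ranks = list(Chem.CanonicalRankAtoms(mol))
    idx = [a.GetIdx() for a in mol.GetAtoms()
           if a.GetIsAromatic() and a.GetAtomicNum() == 6 and a.GetTotalNumHs() >= 1]
    return sorted(idx, key=lambda i: ranks[i])


def _attach_fragment(mol: Chem.Mol, pos: int, fragment: str) -> Optional[str]:
    """Replace one aromatic H at ``pos`` by a substituent; None on failure."""
    em = Chem.RWMol(mol)
    prev = pos
    for ch in ([fragment] if len(fragment) == 1 or fragment in ("Cl", "Br")
               else list(fragment)):
        atom = Chem.Atom({"F": 9, "Cl": 17, "Br": 35, "C": 6, "O": 8, "N": 7}[ch])
        new_idx = em.AddAtom(atom)
        em.AddBond(prev, new_idx, Chem.BondType.SINGLE)
        prev = new_idx
    try:
        out = em.GetMol()
        Chem.SanitizeMol(out)
        return Chem.MolToSmiles(out)
    except Exception:
        return None


def make_analogs(scaffold_smiles: str, n: int,
                 edit_ops: Sequence[str] = ("F", "Cl", "C", "OC"),
                 max_retries: int = 50) -> List[str]:
    """``n`` single-substituent analogs of the scaffold (canonical SMILES).

    Substituents are attached at aromatic CH positions in a deterministic
    (position-major, substituent-minor) order; invalid products are skipped
    up to a retry bound.
    """
    mol = Chem.MolFromSmiles(scaffold_smiles)
    if mol is None:
        raise ValueError(f"invalid scaffold SMILES {scaffold_smiles!r}")
    out: List[str] = []
    seen = {canonicalize(scaffold_smiles)}
    attempts = 0
    for pos in _attachment_positions(mol):
        for op in edit_ops:
            if len(out) >= n:
                return out
            attempts += 1
            if attempts > n + max_retries:
                raise RuntimeError(f"could not build {n} valid analogs "
                                   f"(got {len(out)} after {attempts} attempts)")
            smi = _attach_fragment(mol, pos, op)
            if smi is None or smi in seen:
                continue
            seen.add(smi)
            out.append(smi)
    if len(out) < n:
        raise RuntimeError(f"scaffold offers too few attachment points for {n} analogs")
    return out


# ---------------------------------------------------------------------------
# corpus emission


def _embed_or_origin(smiles: str, seed: int) -> Chem.Mol:
    """A single 'crystal-like' conformer; tiny species get origin coordinates."""
    mol = Chem.MolFromSmiles(smiles)
    try:
        return generate_conformers(mol, n_max=1, seed=seed)
    except (EmbeddingError, ValueError):
        heavy = Chem.RemoveHs(mol)
        conf = Chem.Conformer(heavy.GetNumAtoms())
        for i in range(heavy.GetNumAtoms()):
            conf.SetAtomPosition(i, (float(i), 0.0, 0.0))
        heavy.AddConformer(conf, assignId=True)
        return heavy


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return float(10 ** rng.uniform(math.log10(lo), math.log10(hi)))


def generate_corpora(config: SyntheticConfig, query_scaffold: StateSpace,
                     outdir) -> Dict[str, Path]:
    """Write the three corpus files plus the ground-truth manifest.

    Returns a dict with paths: ``drugbank`` (csv), ``pdb`` (sdf),
    ``chembl`` (csv), ``manifest`` (json).  Byte-identical for a fixed
    config (including seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    vocab = load_vocabulary()

    base_state = enumerate_states(query_scaffold)[0]
    analog_smiles = make_analogs(base_state.smiles, config.n_analogs,
                                 config.analog_edit_ops)
    analogs = []
    for i, smi in enumerate(analog_smiles, 1):
        analogs.append({
            "analog_id": f"analog_{i:02d}",
            "smiles": smi,
            "canonical_key": canonicalize(smi),
            "drugbank_id": f"SYNDB{i:05d}",
            "pdb_het": f"A{i:02d}",
            "chembl_id": f"SYNCHEMBL{i:05d}",
        })

    def sample_decoys(n: int) -> List[Tuple[str, str]]:
        idx = rng.choice(len(vocab), size=min(n, len(vocab)), replace=False)
        return [vocab[i] for i in sorted(idx)]

    # --- DrugBank-dialect CSV ------------------------------------------------
    db_rows = []
    db_decoys = sample_decoys(config.n_decoys_per_corpus)
    for j, (smi, did) in enumerate(db_decoys, 1):
        db_rows.append((f"SYNDB9{j:04d}", smi, "small molecule", f"decoy {did}"))
    biologic_ids = []
    for j in range(config.n_biologics):
        bid = f"SYNBT{j + 1:05d}"
        biologic_ids.append(bid)
        db_rows.append((bid, _BIOLOGIC_SMILES[j % len(_BIOLOGIC_SMILES)],
                        "biotech", f"synthetic biologic {j + 1}"))
    for a in analogs:
        db_rows.append((a["drugbank_id"], a["smiles"], "small molecule",
                        a["analog_id"]))
    drugbank_path = outdir / "drugbank.csv"
    with drugbank_path.open("w") as fh:
        fh.write("id,smiles,type,name\n")
        for rid, smi, typ, name in db_rows:
            fh.write(f"{rid},{smi},{typ},{name}\n")

    # --- PDB-dialect SDF -----------------------------------------------------
    pdb_decoys = sample_decoys(config.n_decoys_per_corpus)
    cont_codes = list(CONTAMINANTS)
    cont_idx = rng.choice(len(cont_codes), size=min(config.n_solvent_ion_records,
                                                    len(cont_codes)), replace=False)
    contaminants = [cont_codes[i] for i in sorted(cont_idx)]
    pdb_path = outdir / "pdb.sdf"
    writer = Chem.SDWriter(str(pdb_path))
    writer.SetKekulize(True)
    pdb_decoy_codes = []

    def write_het(code: str, smiles: str) -> None:
        mol = _embed_or_origin(smiles, seed=int(rng.integers(1, 2 ** 31 - 2)))
        mol.SetProp("_Name", code)
        mol.SetProp("het_code", code)
        writer.write(mol)

    for a in analogs:
        write_het(a["pdb_het"], a["smiles"])
    for j, (smi, did) in enumerate(pdb_decoys, 1):
        code = f"D{j:02d}"
        pdb_decoy_codes.append(code)
        write_het(code, smi)
    for code in contaminants:
        write_het(code, CONTAMINANTS[code])
    writer.close()

    # --- ChEMBL-dialect CSV --------------------------------------------------
    threshold = 1000.0
    chembl_rows: List[dict] = []
    expected_labels: Dict[Tuple[str, str], str] = {}

    def add_row(mid, smi, target, tname, torg, fmt, atype, value, units, rel):
        chembl_rows.append(dict(molecule_id=mid, smiles=smi, target_id=target,
                                target_name=tname, organism=torg,
                                assay_format=fmt, activity_type=atype,
                                value=value, units=units, relation=rel))

    for i, a in enumerate(analogs):
        value = _log_uniform(rng, *config.analog_value_range)
        add_row(a["chembl_id"], a["smiles"], config.planted_target_id,
                config.planted_target_name, config.planted_organism,
                "Single Protein", RETAINED_ACTIVITY_TYPES[i % 5],
                round(value, 2), "nM", "=")
        expected_labels[(a["canonical_key"], config.planted_target_id)] = "active"

    chembl_decoys = sample_decoys(config.n_decoys_per_corpus)
    tie_dropped: List[List[str]] = []
    for j, (smi, did) in enumerate(chembl_decoys, 1):
        mid = f"SYNCHEMBL9{j:04d}"
        target, tname, torg = DECOY_TARGET_POOL[int(rng.integers(len(DECOY_TARGET_POOL)))]
        kind = rng.random()
        value = round(_log_uniform(rng, 10 ** config.decoy_value_log10_range[0],
                                   10 ** config.decoy_value_log10_range[1]), 2)
        key = canonicalize(smi)
        if kind < 0.15:   # wrong assay format -> dropped in curation
            fmt = OTHER_ASSAY_FORMATS[j % len(OTHER_ASSAY_FORMATS)]
            add_row(mid, smi, target, tname, torg, fmt, "IC50", value, "nM", "=")
        elif kind < 0.30:  # disallowed activity type
            add_row(mid, smi, target, tname, torg, "Single Protein",
                    OTHER_ACTIVITY_TYPES[j % len(OTHER_ACTIVITY_TYPES)],
                    value, "nM", "=")
        elif kind < 0.40:  # qualified relation
            add_row(mid, smi, target, tname, torg, "Single Protein", "IC50",
                    value, "nM", ">")
        elif kind < 0.50:  # inconvertible units
            add_row(mid, smi, target, tname, torg, "Single Protein", "IC50",
                    value, "ug.mL-1", "=")
        else:              # retained; possibly duplicated, possibly conflicting
            units, v = ("uM", round(value / 1000.0, 6)) if rng.random() < 0.3 \
                else ("nM", value)
            add_row(mid, smi, target, tname, torg, "Single Protein",
                    RETAINED_ACTIVITY_TYPES[j % 5], v, units, "=")
            label = "active" if value <= threshold else "inactive"
            labels = [label]
            if rng.random() < config.duplicate_rate:
                add_row(mid, smi, target, tname, torg, "Single Protein",
                        RETAINED_ACTIVITY_TYPES[j % 5], value, "nM", "=")
                labels.append(label)
            if rng.random() < config.conflict_rate:
                flipped = round(threshold * threshold / max(value, 1e-6), 2)
                add_row(mid, smi, target, tname, torg, "Single Protein",
                        RETAINED_ACTIVITY_TYPES[j % 5], flipped, "nM", "=")
                labels.append("inactive" if label == "active" else "active")
            counts = {l: labels.count(l) for l in set(labels)}
            top = max(counts.values())
            winners = [l for l, c in counts.items() if c == top]
            if len(winners) > 1:
                tie_dropped.append([key, target])
            else:
                expected_labels[(key, target)] = winners[0]

    chembl_path = outdir / "chembl.csv"
    with chembl_path.open("w") as fh:
        fh.write("molecule_id,smiles,target_id,target_name,organism,"
                 "assay_format,activity_type,value,units,relation\n")
        for r in chembl_rows:
            fh.write(",".join(str(r[c]) for c in
                              ("molecule_id", "smiles", "target_id", "target_name",
                               "organism", "assay_format", "activity_type",
                               "value", "units", "relation")) + "\n")

    # --- manifest ------------------------------------------------------------
    manifest = {
        "seed": config.seed,
        "config": asdict(config),
        "planted_target": {
            "target_id": config.planted_target_id,
            "target_name": config.planted_target_name,
            "organism": config.planted_organism,
            "expected_chembl_active": config.n_analogs,
            "expected_chembl_inactive": 0,
            "expected_db_count": config.n_analogs,
            "expected_pdb_count": config.n_analogs,
        },
        "analogs": analogs,
        "biologic_ids": biologic_ids,
        "contaminant_het_codes": contaminants,
        "decoys": {
            "drugbank": [did for _, did in db_decoys],
            "pdb": pdb_decoy_codes,
            "chembl": [did for _, did in chembl_decoys],
        },
        "expected_labels": [
            {"canonical_key": k, "target_id": t, "label": l}
            for (k, t), l in sorted(expected_labels.items())
        ],
        "expected_tie_dropped": sorted(tie_dropped),
    }
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True) + "\n")
    return {"drugbank": drugbank_path, "pdb": pdb_path, "chembl": chembl_path,
            "manifest": manifest_path}


# ---------------------------------------------------------------------------
# recovery scoring


def ground_truth_eval(run_result, manifest: dict) -> dict:
    """Score a pipeline run against the generator's planted facts.

    ``run_result`` is the object returned by ``pipeline.run_pipeline``.
    Reports the planted target's rank, precision/recall of consensus-hit
    structures against planted analogs, exact active/inactive count
    agreement, and contaminant/biologic leakage.  Seeds must match.
    """
    if run_result.seed != manifest["seed"]:
        raise ValueError(f"seed mismatch: run {run_result.seed} vs "
                         f"manifest {manifest['seed']}")
    planted = manifest["planted_target"]
    target_id = planted["target_id"]
    ranked = run_result.ranked_summaries
    rank = next((i + 1 for i, s in enumerate(ranked) if s.uniprot_id == target_id),
                None)
    summary = next((s for s in ranked if s.uniprot_id == target_id), None)

    analog_keys = {a["canonical_key"] for a in manifest["analogs"]}
    hit_keys = {g.canonical_key for g in run_result.joined_groups
                if g.n_corpora_passing > 0}
    tp = len(hit_keys & analog_keys)
    precision = tp / len(hit_keys) if hit_keys else 0.0
    recall = tp / len(analog_keys) if analog_keys else 0.0

    bad_ids = set(manifest["biologic_ids"]) | set(manifest["contaminant_het_codes"])
    leaked = sorted({
        row.reference_id
        for table in run_result.similarity_tables.values()
        for row in table.rows
        if row.reference_id in bad_ids
    })
    return {
        "planted_target_rank": rank,
        "counts_match": bool(
            summary is not None
            and summary.chembl_active == planted["expected_chembl_active"]
            and summary.chembl_inactive == planted["expected_chembl_inactive"]),
        "observed_counts": None if summary is None else {
            "pdb_count": summary.pdb_count, "db_count": summary.db_count,
            "chembl_active": summary.chembl_active,
            "chembl_inactive": summary.chembl_inactive},
        "consensus_precision": precision,
        "consensus_recall": recall,
        "contaminants_leaked": leaked,
        "contaminant_filter_score": 1.0 if not leaked else
            1.0 - len(leaked) / max(len(bad_ids), 1),
    }
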