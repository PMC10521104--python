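"""End-to-end orchestration: curate -> enumerate -> 2D -> 3D -> consensus -> rank.

One :func:`run_pipeline` call reads the three corpora, enumerates the query
state space, runs both similarity screens, joins hits across corpora by
canonical structure key and writes the per-target ranking, together with
every intermediate table, a parameter snapshot and a run log.  Reruns with
the same inputs and seed are byte-identical.
"""
from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import pandas as pd
import yaml
from rdkit import Chem

from . import chemio, curation, fingerprints, shape, consensus, ranking
from .models import (Corpus, MoleculeRecord, SimilarityTable, snapshot_hash)
from .states import StateSpace, enumerate_states, load_state_space, \
    oxindole_state_space, write_state_items

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """One reproducible screening run.

    ``conformers`` defaults to the full-scale screening policy; validation
    and example runs swap in :meth:`shape.ConformerPolicy` instances with
    smaller ensembles via the YAML config.
    """

    drugbank_path: Optional[str] = None
    pdb_path: Optional[str] = None
    chembl_path: Optional[str] = None
    state_space_path: Optional[str] = None  # None -> shipped oxindole fixture
    seed: int = 2020
    n_bits: int = fingerprints.DEFAULT_NBITS
    thresholds: fingerprints.ThresholdConfig = field(
        default_factory=fingerprints.ThresholdConfig)
    curation: curation.CurationConfig = field(
        default_factory=curation.CurationConfig)
    conformers: shape.ConformerPolicy = field(
        default_factory=shape.ConformerPolicy)
    tc_min: float = 1.2
    skip_3d: bool = False
    restrict_3d_to_2d_hits: bool = True
    min_corpora: int = 3
    strict_join: bool = False

    @classmethod
    def from_yaml(cls, path: Union[str, Path]) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "thresholds" in kwargs:
            kwargs["thresholds"] = fingerprints.ThresholdConfig(**kwargs["thresholds"])
        if "curation" in kwargs:
            cur = dict(kwargs["curation"])
            for key in ("allowed_activity_types", "pdb_stoplist"):
                if key in cur:
                    cur[key] = frozenset(cur[key])
            kwargs["curation"] = curation.CurationConfig(**cur)
        if "conformers" in kwargs:
            kwargs["conformers"] = shape.ConformerPolicy(**kwargs["conformers"])
        return cls(**kwargs)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["curation"]["allowed_activity_types"] = sorted(
            d["curation"]["allowed_activity_types"])
        d["curation"]["pdb_stoplist"] = sorted(d["curation"]["pdb_stoplist"])
        d["snapshot_id"] = snapshot_hash(d)
        return d


@dataclass
class RunResult:
    """In-memory view of one pipeline run (everything also lands on disk)."""

    seed: int
    outdir: Path
    snapshot: dict
    state_items: list
    query_records: list
    corpus_records: Dict[str, list]
    labels: list
    similarity_tables: Dict[str, SimilarityTable]
    joined_groups: list
    cross_hits: list
    ranked_summaries: list


def _query_records(items) -> List[MoleculeRecord]:
    return [MoleculeRecord(record_id=it.item_id, corpus=Corpus.query,
                           smiles=it.smiles, canonical_key=it.canonical_key,
                           mol=Chem.MolFromSmiles(it.smiles))
            for it in items]


def _fingerprint_map(records, n_bits):
    out = {}
    for rec in records:
        mol = rec.mol or Chem.MolFromSmiles(rec.smiles)
        out[rec.record_id] = fingerprints.fingerprint_set(mol, n_bits)
    return out


def run_pipeline(config: PipelineConfig, outdir: Union[str, Path]) -> RunResult:
    """Execute every stage and write stage outputs under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    snapshot = config.snapshot()
    (outdir / "params_snapshot.json").write_text(
        json.dumps(snapshot, indent=1, sort_keys=True, default=str) + "\n")

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    root = logging.getLogger("ligscreen")
    root.addHandler(handler)
    try:
        return _run(config, outdir, snapshot)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path, snapshot: dict) -> RunResult:
    # --- stage 1: enumerate query states ------------------------------------
    space = (load_state_space(config.state_space_path)
             if config.state_space_path else oxindole_state_space())
    items = enumerate_states(space)
    write_state_items(items, outdir / "states.smi")
    queries = _query_records(items)
    log.info("enumerated %d query states", len(items))

    # --- stage 2: curation ---------------------------------------------------
    corpus_records: Dict[str, list] = {}
    if config.drugbank_path:
        raw = chemio.read_corpus(config.drugbank_path, Corpus.drugbank)
        corpus_records["drugbank"] = curation.filter_drugbank(raw)
    if config.pdb_path:
        raw = chemio.read_corpus(config.pdb_path, Corpus.pdb)
        corpus_records["pdb"] = curation.filter_pdb_ligands(raw, config.curation)
    labels: list = []
    annotations: Dict[str, dict] = {}
    if config.chembl_path:
        rows = chemio.read_activities(config.chembl_path)
        for r in rows:
            annotations.setdefault(r.target_id, {
                "target_name": r.target_name, "organism": r.organism})
        drop_log: list = []
        kept_rows = curation.filter_chembl(rows, config.curation, drop_log)
        pd.DataFrame(drop_log, columns=["row_id", "reason_code"]).to_csv(
            outdir / "chembl_drop_log.tsv", sep="\t", index=False)
        labels = curation.label_ligands(kept_rows, config.curation)
        by_id: Dict[str, MoleculeRecord] = {}
        for r in kept_rows:
            if r.molecule_id not in by_id and r.canonical_key:
                by_id[r.molecule_id] = MoleculeRecord(
                    record_id=r.molecule_id, corpus=Corpus.chembl,
                    smiles=r.smiles, canonical_key=r.canonical_key,
                    mol=Chem.MolFromSmiles(r.smiles))
        corpus_records["chembl"] = [by_id[k] for k in sorted(by_id)]
        labels_frame = pd.DataFrame(
            [{"canonical_key": l.canonical_key, "target_id": l.target_id,
              "label": l.label, "n_supporting_rows": l.n_supporting_rows}
             for l in labels])
        chemio.write_table(labels_frame, outdir / "labels.csv")
    for corpus, records in corpus_records.items():
        frame = pd.DataFrame([{
            "record_id": r.record_id, "smiles": r.smiles,
            "canonical_key": r.canonical_key,
            "het_code": r.het_code or "",
            "molecule_type": r.molecule_type.value if r.molecule_type else "",
        } for r in records])
        chemio.write_table(frame, outdir / f"curated_{corpus}.csv")
        log.info("curated %s: %d records", corpus, len(records))

    # --- stages 3-5: per-corpus 2D + 3D screens ------------------------------
    policy = dataclasses.replace(config.conformers, seed=config.seed)
    query_fps = _fingerprint_map(queries, config.n_bits)
    tables: Dict[str, SimilarityTable] = {}
    for corpus in sorted(corpus_records):
        records = corpus_records[corpus]
        if not records:
            tables[corpus] = SimilarityTable(rows=[], provenance={
                "corpus": corpus, "snapshot_id": snapshot["snapshot_id"]})
            continue
        ref_fps = _fingerprint_map(records, config.n_bits)
        rows_2d = fingerprints.screen_2d(query_fps, ref_fps, config.thresholds)
        table_2d = SimilarityTable(rows=rows_2d, provenance={
            "corpus": corpus, "stage": "2d",
            "snapshot_id": snapshot["snapshot_id"]})
        if config.skip_3d:
            for row in table_2d.rows:
                row.pass_consensus = row.pass_2d  # degenerate 2D-only mode
            merged = table_2d
        else:
            pairs = ({(r.query_id, r.reference_id)
                      for r in table_2d.rows if r.pass_2d}
                     if config.restrict_3d_to_2d_hits else None)
            direction = ("ref_crystal_vs_query_confs" if corpus == "pdb"
                         else "query_confs_vs_ref_confs")
            results = shape.screen_3d(
                queries, records, policy=policy, direction=direction,
                tc_min=config.tc_min, pairs=pairs, ref_corpus=corpus)
            rows_3d = []
            for (qid, rid), res in sorted(results.items()):
                from .models import SimilarityRecord
                rows_3d.append(SimilarityRecord(
                    query_id=qid, reference_id=rid, tc={},
                    shape_tanimoto=res.shape_tanimoto,
                    color_tanimoto=res.color_tanimoto,
                    tc_combo=res.tanimoto_combo,
                    pass_3d=res.tanimoto_combo >= config.tc_min))
            table_3d = SimilarityTable(rows=rows_3d, provenance={
                "corpus": corpus, "stage": "3d",
                "snapshot_id": snapshot["snapshot_id"]})
            merged = consensus.merge_screens(table_2d, table_3d)
            merged.provenance.update(corpus=corpus,
                                     snapshot_id=snapshot["snapshot_id"])
        tables[corpus] = merged
        chemio.write_table(merged, outdir / f"similarity_{corpus}.csv")
        log.info("%s: %d pairs, %d 2D hits, %d consensus hits", corpus,
                 len(merged.rows), sum(r.pass_2d for r in merged.rows),
                 sum(r.pass_consensus for r in merged.rows))

    # --- stage 6: join + rank ------------------------------------------------
    reference_keys = {
        corpus: {r.record_id: r.canonical_key for r in records}
        for corpus, records in corpus_records.items()}
    groups = consensus.join_across_corpora(tables, reference_keys)
    cross = consensus.cross_corpus_hits(groups, min_corpora=config.min_corpora,
                                        strict=config.strict_join)
    (outdir / "joined.json").write_text(
        json.dumps(consensus.groups_to_json(groups), indent=1) + "\n")
    (outdir / "cross_corpus_hits.json").write_text(
        json.dumps(consensus.groups_to_json(cross), indent=1) + "\n")

    summaries = ranking.summarize_targets(groups, labels, annotations)
    if summaries:
        ranked = ranking.rank_targets(summaries)
    else:
        ranked = []
        log.warning("no consensus hits: ranking table is empty")
    frame = chemio.summaries_to_frame(ranked)
    frame.insert(0, "rank", range(1, len(ranked) + 1))
    chemio.write_table(frame, outdir / "ranking.csv")
    log.info("ranked %d targets", len(ranked))

    return RunResult(seed=config.seed, outdir=outdir, snapshot=snapshot,
                     state_items=items, query_records=queries,
                     corpus_records=corpus_records, labels=labels,
                     similarity_tables=tables, joined_groups=groups,
                     cross_hits=cross, ranked_summaries=ranked)
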