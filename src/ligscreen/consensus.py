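"""Merging 2D and 3D screens and joining hits across corpora.

A pair is a *consensus* hit when it passes both the five-threshold 2D screen
and the TanimotoCombo 3D screen.  Consensus hits from the three corpora are
then grouped by canonical isomeric SMILES, so the same chemical structure
registered under different native identifiers (a DrugBank accession, a PDB
het code, a ChEMBL molecule id) lands in one group — the pattern that
surfaces molecules reported in all three databases.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

from .models import SimilarityRecord, SimilarityTable

log = logging.getLogger(__name__)


def merge_screens(table_2d: SimilarityTable, table_3d: SimilarityTable) -> SimilarityTable:
    """Conjunction of the 2D and 3D screens per (query, reference) pair.

    Pairs present in only one input are retained with ``pass_consensus``
    False (and logged); duplicate pairs within either input are a fatal
    upstream error (raised by SimilarityTable itself).
    """
    by_pair_3d = {r.pair: r for r in table_3d.rows}
    merged: List[SimilarityRecord] = []
    seen = set()
    n_partial = 0
    for r2 in table_2d.rows:
        r3 = by_pair_3d.get(r2.pair)
        row = SimilarityRecord(
            query_id=r2.query_id, reference_id=r2.reference_id,
            tc=dict(r2.tc), pass_2d=r2.pass_2d)
        if r3 is None:
            n_partial += 1
        else:
            row.shape_tanimoto = r3.shape_tanimoto
            row.color_tanimoto = r3.color_tanimoto
            row.tc_combo = r3.tc_combo
            row.pass_3d = r3.pass_3d
        row.pass_consensus = row.pass_2d and row.pass_3d
        merged.append(row)
        seen.add(r2.pair)
    for r3 in table_3d.rows:
        if r3.pair in seen:
            continue
        n_partial += 1
        row = SimilarityRecord(
            query_id=r3.query_id, reference_id=r3.reference_id, tc=dict(r3.tc),
            shape_tanimoto=r3.shape_tanimoto, color_tanimoto=r3.color_tanimoto,
            tc_combo=r3.tc_combo, pass_3d=r3.pass_3d, pass_consensus=False)
        merged.append(row)
    if n_partial:
        log.info("merge_screens: %d pairs present in only one screen "
                 "(consensus set to False)", n_partial)
    provenance = {"merged_from": [table_2d.provenance, table_3d.provenance]}
    return SimilarityTable(rows=merged, provenance=provenance)


@dataclass
class CorpusHits:
    """Per-corpus entries of one joined structure group."""

    reference_ids: List[str] = field(default_factory=list)
    n_consensus_pairs: int = 0
    best_tc_combo: Optional[float] = None
    best_query_id: Optional[str] = None

    @property
    def any_pass(self) -> bool:
        return self.n_consensus_pairs > 0


@dataclass
class JoinedGroup:
    """One chemical structure across corpora, keyed by canonical SMILES."""

    canonical_key: str
    corpora: Dict[str, CorpusHits] = field(default_factory=dict)

    @property
    def n_corpora_present(self) -> int:
        return len(self.corpora)

    @property
    def n_corpora_passing(self) -> int:
        return sum(1 for h in self.corpora.values() if h.any_pass)

    @property
    def best_tc_combo(self) -> float:
        scores = [h.best_tc_combo for h in self.corpora.values()
                  if h.best_tc_combo is not None]
        return max(scores) if scores else 0.0


def join_across_corpora(hitlists: Mapping[str, SimilarityTable],
                        reference_keys: Mapping[str, Mapping[str, str]]) -> List[JoinedGroup]:
    """Group reference molecules across corpora by canonical structure key.

    ``reference_keys[corpus]`` maps native reference ids to canonical
    isomeric SMILES.  Every reference appearing in a hitlist lands in
    exactly one group; groups carry per-corpus native ids, consensus-pass
    counts and best TanimotoCombo.
    """
    groups: Dict[str, JoinedGroup] = {}
    for corpus in sorted(hitlists):
        table = hitlists[corpus]
        keymap = reference_keys.get(corpus, {})
        for row in table.rows:
            key = keymap.get(row.reference_id)
            if key is None:
                log.warning("reference %s (%s) lacks a canonical key; skipped",
                            row.reference_id, corpus)
                continue
            group = groups.setdefault(key, JoinedGroup(canonical_key=key))
            hits = group.corpora.setdefault(corpus, CorpusHits())
            if row.reference_id not in hits.reference_ids:
                hits.reference_ids.append(row.reference_id)
            if row.pass_consensus:
                hits.n_consensus_pairs += 1
                if row.tc_combo is not None and (
                        hits.best_tc_combo is None or row.tc_combo > hits.best_tc_combo):
                    hits.best_tc_combo = row.tc_combo
                    hits.best_query_id = row.query_id
    return [groups[k] for k in sorted(groups)]


def cross_corpus_hits(joined: Sequence[JoinedGroup], min_corpora: int = 3,
                      strict: bool = False) -> List[JoinedGroup]:
    """Groups with consensus-passing entries in at least ``min_corpora`` corpora.

    With ``strict=True`` every corpus the structure appears in must pass,
    not just ``min_corpora`` of them.  Sorted by best TanimotoCombo
    descending (canonical key breaks ties).
    """
    out = []
    for g in joined:
        if g.n_corpora_passing < min_corpora:
            continue
        if strict and g.n_corpora_passing < g.n_corpora_present:
            continue
        out.append(g)
    return sorted(out, key=lambda g: (-g.best_tc_combo, g.canonical_key))


def groups_to_json(groups: Sequence[JoinedGroup]) -> list:
    """JSON-serializable view of joined groups."""
    return [{
        "canonical_key": g.canonical_key,
        "n_corpora_present": g.n_corpora_present,
        "n_corpora_passing": g.n_corpora_passing,
        "best_tc_combo": g.best_tc_combo,
        "corpora": {
            corpus: {
                "reference_ids": h.reference_ids,
                "n_consensus_pairs": h.n_consensus_pairs,
                "best_tc_combo": h.best_tc_combo,
                "best_query_id": h.best_query_id,
            } for corpus, h in sorted(g.corpora.items())
        },
    } for g in groups]
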