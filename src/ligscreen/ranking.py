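"""Per-target hit summaries and repurposing prioritisation.

Each candidate target accumulates the number of *distinct* consensus-hit
structures per corpus, split into active/inactive for ChEMBL-labelled
ligands.  Targets are then ordered by a lexicographic key encoding the
screening rationale: structures recovered from several independent
databases first, then the surplus of active over inactive similars, then
total evidence volume.  The ranking is a heuristic prioritisation, not a
statistical test — no null model is attached to the counts.
"""
from __future__ import annotations

import logging
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

from .consensus import JoinedGroup
from .models import LabeledLigand, TargetSummary

log = logging.getLogger(__name__)

UNKNOWN_TARGET = "UNKNOWN"

#: default lexicographic precedence (all descending)
DEFAULT_SORT_KEYS = ("n_corpora", "active_minus_inactive", "total_ligands",
                     "chembl_active")


def summarize_targets(groups: Sequence[JoinedGroup],
                      labels: Sequence[LabeledLigand],
                      annotations: Optional[Mapping[str, Mapping[str, str]]] = None,
                      target_links: Optional[Mapping[str, Sequence[str]]] = None,
                      ) -> List[TargetSummary]:
    """Aggregate consensus-hit structure groups into per-target count rows.

    Target association is structural: a group's canonical key maps to
    targets through its ChEMBL activity labels and, optionally, through
    ``target_links`` (extra key -> target ids, e.g. curated annotations for
    DrugBank/PDB-only molecules).  A group passing only in corpora without
    any target association is counted under ``UNKNOWN``.  Counts are
    distinct canonical keys per target, corpus and label.
    """
    annotations = annotations or {}
    label_by_key: Dict[str, List[LabeledLigand]] = {}
    for lig in labels:
        label_by_key.setdefault(lig.canonical_key, []).append(lig)

    # (target, field) -> set of canonical keys
    counts: Dict[Tuple[str, str], set] = {}

    def add(target: str, fld: str, key: str) -> None:
        counts.setdefault((target, fld), set()).add(key)

    for g in groups:
        if g.n_corpora_passing == 0:
            continue
        key = g.canonical_key
        ligands = label_by_key.get(key, [])
        targets = {lig.target_id for lig in ligands}
        if target_links and key in target_links:
            targets.update(target_links[key])
        if not targets:
            targets = {UNKNOWN_TARGET}
            log.info("hit %s has no target annotation; counted under %s",
                     key, UNKNOWN_TARGET)
        pdb_pass = g.corpora.get("pdb") and g.corpora["pdb"].any_pass
        db_pass = g.corpora.get("drugbank") and g.corpora["drugbank"].any_pass
        chembl_pass = g.corpora.get("chembl") and g.corpora["chembl"].any_pass
        for target in targets:
            if pdb_pass:
                add(target, "pdb", key)
            if db_pass:
                add(target, "db", key)
            if chembl_pass:
                lab = next((l.label for l in ligands if l.target_id == target), None)
                if lab is None:
                    add(target, "chembl_unlabeled", key)
                else:
                    add(target, f"chembl_{lab}", key)

    targets = sorted({t for t, _ in counts})
    out = []
    for t in targets:
        meta = annotations.get(t, {})
        n_unlabeled = len(counts.get((t, "chembl_unlabeled"), ()))
        if n_unlabeled:
            log.info("target %s: %d ChEMBL hits without labels dropped from counts",
                     t, n_unlabeled)
        out.append(TargetSummary(
            uniprot_id=t,
            target_name=meta.get("target_name", ""),
            organism=meta.get("organism", ""),
            pdb_count=len(counts.get((t, "pdb"), ())),
            db_count=len(counts.get((t, "db"), ())),
            chembl_active=len(counts.get((t, "chembl_active"), ())),
            chembl_inactive=len(counts.get((t, "chembl_inactive"), ())),
        ))
    return out


def rank_targets(summaries: Sequence[TargetSummary],
                 sort_keys: Sequence[str] = DEFAULT_SORT_KEYS) -> List[TargetSummary]:
    """Total descending order on the configured lexicographic key.

    Defaults: corpora spanned, then active-minus-inactive surplus, then
    total distinct ligands, then active count; remaining ties break on
    uniprot id ascending, so the order is deterministic and total.
    """
    if not summaries:
        raise ValueError("rank_targets requires a non-empty summary list")

    def key(s: TargetSummary):
        return tuple(-getattr(s, k) for k in sort_keys) + (s.uniprot_id,)

    return sorted(summaries, key=key)
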