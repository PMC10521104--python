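"""Screen merging and cross-corpus structure joining."""
import numpy as np
import pytest

from ligscreen.consensus import (cross_corpus_hits, join_across_corpora,
                                 merge_screens)
from ligscreen.models import SimilarityRecord, SimilarityTable


def _row(qid, rid, pass_2d=False, tc_combo=None, pass_3d=False,
         pass_consensus=False):
    return SimilarityRecord(query_id=qid, reference_id=rid, tc={},
                            tc_combo=tc_combo, pass_2d=pass_2d,
                            pass_3d=pass_3d, pass_consensus=pass_consensus)


class TestMergeScreens:
    def test_conjunction(self):
        t2d = SimilarityTable(rows=[_row("q", "a", pass_2d=True),
                                    _row("q", "b", pass_2d=True),
                                    _row("q", "c", pass_2d=False)])
        t3d = SimilarityTable(rows=[_row("q", "a", tc_combo=1.3, pass_3d=True),
                                    _row("q", "b", tc_combo=1.0, pass_3d=False),
                                    _row("q", "c", tc_combo=1.4, pass_3d=True)])
        merged = {r.pair: r for r in merge_screens(t2d, t3d).rows}
        assert merged[("q", "a")].pass_consensus is True
        assert merged[("q", "b")].pass_consensus is False  # 3D below cut
        assert merged[("q", "c")].pass_consensus is False  # 2D failed
        assert merged[("q", "a")].tc_combo == 1.3

    def test_pair_absent_from_3d_fails_consensus(self):
        t2d = SimilarityTable(rows=[_row("q", "a", pass_2d=True)])
        merged = merge_screens(t2d, SimilarityTable(rows=[])).rows
        assert merged[0].pass_consensus is False

    def test_pair_only_in_3d_retained_without_consensus(self):
        t3d = SimilarityTable(rows=[_row("q", "x", tc_combo=1.9, pass_3d=True)])
        merged = merge_screens(SimilarityTable(rows=[]), t3d).rows
        assert len(merged) == 1 and merged[0].pass_consensus is False

    def test_matches_boolean_conjunction_oracle(self):
        rng = np.random.default_rng(17)
        pairs = [(f"q{i}", f"r{j}") for i in range(6) for j in range(8)]
        flags_2d = {p: bool(rng.integers(2)) for p in pairs}
        flags_3d = {p: bool(rng.integers(2)) for p in pairs}
        t2d = SimilarityTable(rows=[_row(q, r, pass_2d=flags_2d[(q, r)])
                                    for q, r in pairs])
        t3d = SimilarityTable(rows=[_row(q, r, tc_combo=1.5,
                                         pass_3d=flags_3d[(q, r)])
                                    for q, r in pairs])
        merged = merge_screens(t2d, t3d)
        for row in merged.rows:
            assert row.pass_consensus == (flags_2d[row.pair] and flags_3d[row.pair])


def _hitlists():
    """Same structure under three native ids; a decoy in one corpus only."""
    key_shared = "Cc1ccc2[nH]c(=O)cc2c1"
    key_decoy = "CCOC(=O)c1ccccc1"
    tables = {
        "drugbank": SimilarityTable(rows=[
            _row("q1", "DB0001", pass_2d=True, tc_combo=1.31, pass_3d=True,
                 pass_consensus=True)]),
        "pdb": SimilarityTable(rows=[
            _row("q1", "XYZ", pass_2d=True, tc_combo=1.45, pass_3d=True,
                 pass_consensus=True)]),
        "chembl": SimilarityTable(rows=[
            _row("q1", "CHEM1", pass_2d=True, tc_combo=1.50, pass_3d=True,
                 pass_consensus=True),
            _row("q1", "CHEM2", pass_2d=True, tc_combo=1.22, pass_3d=True,
                 pass_consensus=True)]),
    }
    keys = {
        "drugbank": {"DB0001": key_shared},
        "pdb": {"XYZ": key_shared},
        "chembl": {"CHEM1": key_shared, "CHEM2": key_decoy},
    }
    return tables, keys, key_shared, key_decoy


class TestJoin:
    def test_same_structure_groups_across_corpora(self):
        tables, keys, key_shared, key_decoy = _hitlists()
        groups = {g.canonical_key: g for g in join_across_corpora(tables, keys)}
        assert set(groups) == {key_shared, key_decoy}
        shared = groups[key_shared]
        assert shared.n_corpora_present == 3
        assert shared.corpora["drugbank"].reference_ids == ["DB0001"]
        assert shared.best_tc_combo == pytest.approx(1.50)

    def test_stereoisomers_stay_separate(self):
        tables = {"chembl": SimilarityTable(rows=[
            _row("q", "a", pass_consensus=True, tc_combo=1.3),
            _row("q", "b", pass_consensus=True, tc_combo=1.3)])}
        keys = {"chembl": {"a": "N[C@@H](C)C(=O)O", "b": "N[C@H](C)C(=O)O"}}
        assert len(join_across_corpora(tables, keys)) == 2

    def test_empty_hitlists(self):
        assert join_across_corpora({}, {}) == []

    def test_partition_every_reference_in_exactly_one_group(self):
        rng = np.random.default_rng(23)
        key_pool = [f"K{k}" for k in range(5)]
        tables, keys = {}, {}
        for corpus in ("drugbank", "pdb", "chembl"):
            refs = {f"{corpus}_r{j}": key_pool[rng.integers(5)] for j in range(8)}
            tables[corpus] = SimilarityTable(rows=[
                _row("q", rid, pass_consensus=bool(rng.integers(2)), tc_combo=1.3)
                for rid in refs])
            keys[corpus] = refs
        groups = join_across_corpora(tables, keys)
        seen = []
        for g in groups:
            for corpus, hits in g.corpora.items():
                seen.extend((corpus, r) for r in hits.reference_ids)
        assert len(seen) == len(set(seen)) == 24
        assert len(groups) <= len(key_pool)


class TestCrossCorpusHits:
    def test_planted_three_corpus_molecule_found(self):
        tables, keys, key_shared, _ = _hitlists()
        groups = join_across_corpora(tables, keys)
        hits = cross_corpus_hits(groups, min_corpora=3)
        assert [g.canonical_key for g in hits] == [key_shared]

    def test_min_corpora_one_returns_all_passing(self):
        tables, keys, *_ = _hitlists()
        groups = join_across_corpora(tables, keys)
        assert len(cross_corpus_hits(groups, min_corpora=1)) == 2

    def test_sorted_by_best_combo_descending(self):
        tables, keys, *_ = _hitlists()
        hits = cross_corpus_hits(join_across_corpora(tables, keys), min_corpora=1)
        scores = [g.best_tc_combo for g in hits]
        assert scores == sorted(scores, reverse=True)

    def test_no_consensus_passes_gives_empty(self):
        tables = {"chembl": SimilarityTable(rows=[_row("q", "a", pass_2d=True)])}
        keys = {"chembl": {"a": "CCO"}}
        assert cross_corpus_hits(join_across_corpora(tables, keys), 1) == []

    def test_strict_mode_requires_pass_everywhere_present(self):
        key = "CCO"
        tables = {
            "drugbank": SimilarityTable(rows=[
                _row("q", "d", pass_consensus=True, tc_combo=1.3)]),
            "chembl": SimilarityTable(rows=[_row("q", "c", pass_2d=True)]),
        }
        keys = {"drugbank": {"d": key}, "chembl": {"c": key}}
        groups = join_across_corpora(tables, keys)
        assert len(cross_corpus_hits(groups, min_corpora=1)) == 1
        assert cross_corpus_hits(groups, min_corpora=1, strict=True) == []
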