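"""Corpus filters and activity labeling."""
from collections import Counter

import pytest
from hypothesis import given, settings, strategies as st

from ligscreen.chemio import canonicalize
from ligscreen.curation import (CurationConfig, convert_to_nM, filter_chembl,
                                filter_drugbank, filter_pdb_ligands,
                                label_activity, label_ligands, resolve_duplicates)
from ligscreen.models import ActivityRow, MoleculeRecord


def _mol(rid, smiles, corpus="drugbank", **kw):
    return MoleculeRecord(record_id=rid, corpus=corpus, smiles=smiles,
                          canonical_key=canonicalize(smiles), **kw)


def _row(**kw):
    base = dict(molecule_id="m1", target_id="T1", target_name="t", organism="Hs",
                assay_format="Single Protein", activity_type="IC50",
                value=500.0, units="nM", relation="=")
    base.update(kw)
    return ActivityRow(**base)


class TestFilterDrugbank:
    def test_keeps_only_small_molecules(self):
        records = [_mol("a", "CCO", molecule_type="small_molecule"),
                   _mol("b", "CCN", molecule_type="biologic"),
                   _mol("c", "CCC", molecule_type="small_molecule")]
        kept = filter_drugbank(records)
        assert [r.record_id for r in kept] == ["a", "c"]

    def test_all_biologic_gives_empty(self):
        records = [_mol("b", "CCN", molecule_type="biologic")]
        assert filter_drugbank(records) == []

    def test_empty_input(self):
        assert filter_drugbank([]) == []

    def test_idempotent(self):
        records = [_mol("a", "CCO", molecule_type="small_molecule"),
                   _mol("b", "CCN", molecule_type="biologic")]
        once = filter_drugbank(records)
        assert filter_drugbank(once) == once


class TestFilterPdb:
    @pytest.mark.parametrize("het,smiles", [
        ("HOH", "O"),                      # solvent
        ("NA", "[Na+]"),                   # monoatomic ion
        ("SO4", "[O-]S(=O)(=O)[O-]"),      # charged inorganic
        ("GOL", "OCC(O)CO"),               # stoplisted adjuvant
    ])
    def test_contaminants_removed(self, het, smiles):
        rec = _mol(het, smiles, corpus="pdb", het_code=het)
        assert filter_pdb_ligands([rec]) == []

    def test_unlisted_monoatomic_ion_removed_by_structure(self):
        rec = _mol("RB", "[Rb+]", corpus="pdb", het_code="RB")
        assert filter_pdb_ligands([rec]) == []

    def test_organic_het_group_kept(self):
        smi = "CC(=O)Nc1ccc2ncccc2c1C(=O)N1CCOCC1"  # 20+ heavy atoms
        rec = _mol("LIG", smi, corpus="pdb", het_code="LIG")
        kept = filter_pdb_ligands([rec])
        assert [r.record_id for r in kept] == ["LIG"]

    def test_idempotent(self):
        records = [_mol("HOH", "O", corpus="pdb", het_code="HOH"),
                   _mol("LIG", "c1ccc2[nH]ccc2c1CCNC(C)=O", corpus="pdb",
                        het_code="LIG")]
        once = filter_pdb_ligands(records)
        assert filter_pdb_ligands(once) == once


class TestFilterChembl:
    def test_single_protein_eq_nM_kept(self):
        assert len(filter_chembl([_row()])) == 1

    def test_other_assay_format_dropped(self):
        drop = []
        out = filter_chembl([_row(assay_format="Protein Complex")], drop_log=drop)
        assert out == [] and drop == [("m1", "assay_format")]

    def test_disallowed_activity_type_dropped(self):
        assert filter_chembl([_row(activity_type="AC50")]) == []

    def test_qualified_relation_dropped(self):
        assert filter_chembl([_row(relation=">")]) == []

    def test_micromolar_normalized_to_nM(self):
        out = filter_chembl([_row(value=0.5, units="uM")])
        assert out[0].value == pytest.approx(500.0) and out[0].units == "nM"

    def test_unconvertible_units_dropped_with_reason(self):
        drop = []
        assert filter_chembl([_row(units="ug.mL-1")], drop_log=drop) == []
        assert drop == [("m1", "units")]

    def test_idempotent(self):
        rows = [_row(), _row(units="uM", value=2.0), _row(relation=">")]
        once = filter_chembl(rows)
        assert filter_chembl(once) == once

    @pytest.mark.parametrize("units,factor", [
        ("pM", 1e-3), ("nM", 1.0), ("uM", 1e3), ("µM", 1e3), ("mM", 1e6),
        ("M", 1e9)])
    def test_unit_conversion_oracle(self, units, factor):
        assert convert_to_nM(3.0, units) == pytest.approx(3.0 * factor)


class TestLabeling:
    @pytest.mark.parametrize("value,label", [
        (500.0, "active"), (5000.0, "inactive"), (1000.0, "active"),
        (1000.001, "inactive"), (0.0, "active")])
    def test_threshold(self, value, label):
        assert label_activity(value) == label

    def test_negative_value_rejected(self):
        with pytest.raises(ValueError):
            label_activity(-1.0)

    @given(st.floats(min_value=0, max_value=1e7, allow_nan=False),
           st.floats(min_value=0, max_value=1e7, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_monotone(self, a, b):
        """Lowering the value never flips active -> inactive."""
        lo, hi = sorted((a, b))
        if label_activity(hi) == "active":
            assert label_activity(lo) == "active"


class TestResolveDuplicates:
    def test_majority_wins(self):
        lig = resolve_duplicates(["active", "active", "inactive"], "k", "T")
        assert lig.label == "active" and lig.n_supporting_rows == 3

    def test_singleton(self):
        assert resolve_duplicates(["inactive"], "k", "T").label == "inactive"

    def test_exact_tie_dropped(self):
        assert resolve_duplicates(["active", "inactive"], "k", "T") is None

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resolve_duplicates([])

    @given(st.lists(st.sampled_from(["active", "inactive"]), min_size=1,
                    max_size=25))
    @settings(max_examples=200, deadline=None)
    def test_matches_frequency_oracle(self, labels):
        counts = Counter(labels)
        result = resolve_duplicates(labels, "k", "T")
        if counts["active"] == counts["inactive"]:
            assert result is None
        else:
            expected = "active" if counts["active"] > counts["inactive"] else "inactive"
            assert result.label == expected
            assert result.n_supporting_rows == len(labels)


class TestLabelLigands:
    def test_groups_by_structure_and_target(self):
        rows = [
            _row(molecule_id="a", smiles="CCO", canonical_key="CCO", value=100),
            _row(molecule_id="b", smiles="OCC", canonical_key="CCO", value=200),
            _row(molecule_id="c", smiles="CCO", canonical_key="CCO",
                 target_id="T2", value=5e4),
            _row(molecule_id="d", smiles="CCN", canonical_key="CCN", value=10),
            _row(molecule_id="e", smiles="CCN", canonical_key="CCN", value=9e5),
        ]
        ligs = {(l.canonical_key, l.target_id): l for l in label_ligands(rows)}
        assert ligs[("CCO", "T1")].label == "active"
        assert ligs[("CCO", "T1")].n_supporting_rows == 2
        assert ligs[("CCO", "T2")].label == "inactive"
        assert ("CCN", "T1") not in ligs  # tie dropped
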