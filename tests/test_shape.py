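"""Gaussian overlap volumes, overlay optimization and the 3D screen."""
import math

import numpy as np
import pytest
from rdkit import Chem
from scipy.spatial.transform import Rotation

from ligscreen.shape import (BONDI_RADII, ConformerPolicy, MolShape,
                             ShapeParams, _overlap, best_pair_overlay,
                             feature_points, generate_conformers, mol_shape,
                             overlay_shapes, optimize_overlay,
                             pairwise_overlap_volume, screen_3d)
from ligscreen.models import Corpus, MoleculeRecord

PARAMS = ShapeParams()


def grid_overlap(xa, aa, xb, ab, p, h=0.15, pad=4.0):
    """Numerical grid integration of the product Gaussian density."""
    allx = np.vstack([xa, xb])
    lo, hi = allx.min(0) - pad, allx.max(0) + pad
    axes = [np.arange(lo[d], hi[d], h) for d in range(3)]
    G = np.stack(np.meshgrid(*axes, indexing="ij"), -1).reshape(-1, 3)
    rho_a = sum(p * np.exp(-aa[i] * ((G - xa[i]) ** 2).sum(1)) for i in range(len(xa)))
    rho_b = sum(p * np.exp(-ab[j] * ((G - xb[j]) ** 2).sum(1)) for j in range(len(xb)))
    return float((rho_a * rho_b).sum() * h ** 3)


def _embedded(smiles, n=1, seed=7):
    return generate_conformers(Chem.MolFromSmiles(smiles), n, seed=seed)


class TestOverlapVolume:
    def test_coincident_carbons_closed_form(self):
        # two identical atoms at distance 0: p^2 (pi / 2 alpha)^(3/2)
        alpha = PARAMS.alpha(BONDI_RADII[6])
        x = np.zeros((1, 3))
        a = np.array([alpha])
        expected = PARAMS.p ** 2 * (math.pi / (2 * alpha)) ** 1.5
        assert _overlap(x, a, x, a, PARAMS.p) == pytest.approx(expected, rel=1e-12)

    def test_distant_atoms_vanish(self):
        alpha = np.array([PARAMS.alpha(1.7)])
        a = np.zeros((1, 3))
        b = np.array([[50.0, 0.0, 0.0]])
        assert _overlap(a, alpha, b, alpha, PARAMS.p) < 1e-10

    def test_symmetric(self):
        rng = np.random.default_rng(3)
        xa, xb = rng.normal(size=(3, 3)), rng.normal(size=(2, 3))
        aa = np.array([PARAMS.alpha(r) for r in rng.uniform(1.4, 1.9, 3)])
        ab = np.array([PARAMS.alpha(r) for r in rng.uniform(1.4, 1.9, 2)])
        assert _overlap(xa, aa, xb, ab, PARAMS.p) == \
            pytest.approx(_overlap(xb, ab, xa, aa, PARAMS.p), rel=1e-12)

    @pytest.mark.parametrize("trial", range(5))
    def test_matches_grid_integration(self, trial):
        rng = np.random.default_rng(100 + trial)
        na, nb = rng.integers(1, 4, size=2)
        xa = rng.uniform(-1.5, 1.5, (na, 3))
        xb = rng.uniform(-1.5, 1.5, (nb, 3))
        aa = np.array([PARAMS.alpha(r) for r in rng.uniform(1.4, 1.9, na)])
        ab = np.array([PARAMS.alpha(r) for r in rng.uniform(1.4, 1.9, nb)])
        analytic = _overlap(xa, aa, xb, ab, PARAMS.p)
        numeric = grid_overlap(xa, aa, xb, ab, PARAMS.p)
        assert analytic == pytest.approx(numeric, rel=0.01)

    def test_molshape_self_overlap_positive(self):
        shape = mol_shape(_embedded("CCO"), params=PARAMS)
        assert shape.self_shape > 0
        assert pairwise_overlap_volume(shape, shape) == \
            pytest.approx(shape.self_shape)


class TestConformers:
    def test_rigid_benzene_collapses_to_one(self):
        mol = _embedded("c1ccccc1", n=5)
        assert mol.GetNumConformers() == 1

    def test_flexible_hexane_within_bounds(self):
        mol = _embedded("CCCCCC", n=5)
        assert 1 <= mol.GetNumConformers() <= 5

    def test_same_seed_identical_coordinates(self):
        a = _embedded("CCCCO", n=3, seed=11)
        b = _embedded("CCCCO", n=3, seed=11)
        assert a.GetNumConformers() == b.GetNumConformers()
        for ca, cb in zip(a.GetConformers(), b.GetConformers()):
            assert np.allclose(ca.GetPositions(), cb.GetPositions())

    def test_heavy_atoms_only(self):
        mol = _embedded("CCO")
        assert all(atom.GetAtomicNum() != 1 for atom in mol.GetAtoms())


class TestFeaturePoints:
    def test_benzene_has_one_ring_no_donor(self):
        feats = feature_points(_embedded("c1ccccc1"))
        assert len(feats["ring"]) == 1
        assert len(feats["donor"]) == 0

    def test_phenol_donor_and_acceptor(self):
        feats = feature_points(_embedded("Oc1ccccc1"))
        assert len(feats["donor"]) == 1
        assert len(feats["acceptor"]) >= 1

    def test_ring_centroid_at_geometric_center(self):
        mol = _embedded("c1ccccc1")
        feats = feature_points(mol)
        centroid = mol.GetConformer().GetPositions().mean(axis=0)
        assert np.allclose(feats["ring"][0], centroid, atol=1e-6)


class TestOverlay:
    def test_self_overlay_near_perfect(self):
        mol = _embedded("CC(=O)Nc1ccc(O)cc1")
        res = optimize_overlay(mol, mol)
        assert res.shape_tanimoto >= 0.99
        assert res.tanimoto_combo >= 1.98
        assert res.n_starts_evaluated >= 4

    def test_rigid_motion_invariance(self):
        mol = _embedded("c1ccc2[nH]ccc2c1CCN")
        base = optimize_overlay(mol, mol)
        shape_ref = mol_shape(mol, params=PARAMS)
        moved = mol_shape(mol, params=PARAMS)
        R = Rotation.from_euler("xyz", [90, 30, -45], degrees=True).as_matrix()
        t = np.array([5.0, -2.0, 1.0])
        moved.coords = moved.coords @ R.T + t
        moved.features = {k: (v @ R.T + t if len(v) else v)
                          for k, v in moved.features.items()}
        res = overlay_shapes(moved, shape_ref, PARAMS)
        assert res.tanimoto_combo == pytest.approx(base.tanimoto_combo, abs=1e-2)

    def test_transform_is_proper_rotation(self):
        mol = _embedded("CCOc1ccccc1")
        res = optimize_overlay(mol, mol)
        R = np.asarray(res.rotation)
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-8)

    def test_dissimilar_shapes_score_low(self):
        methane = _embedded("C")
        benzene = _embedded("c1ccccc1")
        res = optimize_overlay(methane, benzene)
        assert res.shape_tanimoto < 0.5

    def test_degenerate_collinear_query_still_optimizes(self):
        co2_like = _embedded("O=C=O")
        ref = _embedded("OCCO")
        res = optimize_overlay(co2_like, ref)
        assert 0.0 < res.shape_tanimoto <= 1.0
        assert res.n_starts_evaluated > 4  # random-rotation fallback engaged


class TestScreen3D:
    def _records(self, spec):
        out = []
        for rid, smiles in spec:
            out.append(MoleculeRecord(record_id=rid, corpus=Corpus.chembl,
                                      smiles=smiles,
                                      canonical_key=Chem.CanonSmiles(smiles),
                                      mol=Chem.MolFromSmiles(smiles)))
        return out

    def test_max_over_conformer_pairs_matches_brute_force(self):
        policy = ConformerPolicy(n_query_default=3, n_ref_chembl=3, seed=5)
        params = ShapeParams()
        qmol = generate_conformers(Chem.MolFromSmiles("CCCCCO"), 3, seed=policy.seed)
        rmol = generate_conformers(Chem.MolFromSmiles("CCCCCN"), 3, seed=policy.seed)
        qshapes = [mol_shape(qmol, c.GetId(), params) for c in qmol.GetConformers()]
        rshapes = [mol_shape(rmol, c.GetId(), params) for c in rmol.GetConformers()]
        brute = max(overlay_shapes(q, r, params, seed=policy.seed).tanimoto_combo
                    for q in qshapes for r in rshapes)
        best = best_pair_overlay(qshapes, rshapes, params, seed=policy.seed)
        assert best.tanimoto_combo == pytest.approx(brute, rel=1e-9)

    def test_identical_molecules_pass_cut(self):
        queries = self._records([("q", "CC(=O)Nc1ccc(O)cc1")])
        refs = self._records([("r", "CC(=O)Nc1ccc(O)cc1")])
        policy = ConformerPolicy(n_query_default=1, n_ref_chembl=1, seed=9)
        results = screen_3d(queries, refs, policy=policy)
        assert results[("q", "r")].tanimoto_combo >= 1.2

    def test_crystal_mode_requires_coordinates(self):
        queries = self._records([("q", "CCO")])
        ref = self._records([("r", "CCN")])[0]
        ref.mol.RemoveAllConformers()
        results = screen_3d(queries, [ref],
                            policy=ConformerPolicy(n_query_vs_pdb=1, seed=9),
                            direction="ref_crystal_vs_query_confs")
        assert results == {}

    def test_pairs_argument_restricts_work(self):
        queries = self._records([("q1", "CCO"), ("q2", "CCN")])
        refs = self._records([("r1", "CCC"), ("r2", "CCCl")])
        policy = ConformerPolicy(n_query_default=1, n_ref_chembl=1, seed=9)
        results = screen_3d(queries, refs, policy=policy,
                            pairs={("q1", "r2")})
        assert set(results) == {("q1", "r2")}
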