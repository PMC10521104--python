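"""Conformer generation and Gaussian shape/color overlay scoring.

Molecular volume is modelled the standard fast way: one spherical Gaussian
per heavy atom, amplitude ``p = 2*sqrt(2)`` and width ``alpha`` chosen so the
Gaussian integrates to the atom's hard-sphere (Bondi) volume,

    alpha_i = pi * (3 p / (4 pi r_i^3))^(2/3).

Only first-order (pairwise) products are kept, so the overlap of two
molecules is a closed-form double sum over atom pairs,

    O_AB = sum_ij p^2 (pi / (a_i + a_j))^(3/2) exp(-a_i a_j / (a_i + a_j) d_ij^2),

and ShapeTanimoto = O_AB / (O_AA + O_BB - O_AB) at the optimized rigid
superposition.  "Color" scoring applies the same machinery to pharmacophore
feature points (donor, acceptor, cation, anion, hydrophobe, aromatic-ring
centroid), with only same-type pairs contributing; TanimotoCombo is the sum
of the two Tanimotos (range 0-2, screening cut 1.2).

Overlays start from centroid superposition in the reference inertial frame
over the four proper axis-flip combinations, each refined by a
derivative-free simplex search over rotation and translation.
"""
from __future__ import annotations

import logging
import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Chem import rdMolAlign
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from .models import MoleculeRecord, OverlayResult

log = logging.getLogger(__name__)

#: Bondi van der Waals radii (Angstrom) for the common heavy elements
BONDI_RADII = {
    6: 1.70, 7: 1.55, 8: 1.52, 9: 1.47, 15: 1.80, 16: 1.80,
    17: 1.75, 35: 1.85, 53: 1.98, 5: 1.92, 14: 2.10,
}
DEFAULT_RADIUS = 1.70

#: pharmacophore feature patterns (SMARTS); each match contributes one
#: feature point at the centroid of the matched atoms
FEATURE_SMARTS = {
    "donor": ["[$([N;!H0;v3,v4&+1]),$([O;H1;+0]),$([S;H1;+0]),$([n;H1])]"],
    "acceptor": ["[$([O;H0;v2;!$(O=N-*)]),$([O;-]),$([o;H0;X2]),"
                 "$([N;H0;v3;!$(N=O)]),$([n;H0;X2])]",
                 "[O;H1;$(O-!@[#6;!$(C=!@O)])]"],
    "cation": ["[+,$([N;H2&+0;$(N-[#6])]),$([N;H1&+0;$(N(-[#6])-[#6])])]"],
    "anion": ["[-,$([O;H1,-]C=O),$([S;H1,-]C=O)]"],
    "hydrophobe": ["[C;D3,D4;!$(C~[#7,#8,#9,#15,#16,Cl,Br,I])]",
                   "[Cl,Br,I]",
                   "[S;D2;$(S(-[#6])-[#6])]"],
    "ring": [],  # aromatic rings come from ring perception, not SMARTS
}

FEATURE_TYPES = tuple(FEATURE_SMARTS)


@dataclass(frozen=True)
class ShapeParams:
    """Constants of the Gaussian shape/color model."""

    p: float = 2.0 * math.sqrt(2.0)
    radii: Mapping[int, float] = field(default_factory=lambda: dict(BONDI_RADII))
    default_radius: float = DEFAULT_RADIUS
    color_radius: float = 1.0  # Angstrom, per feature Gaussian
    uniform_radius: Optional[float] = None  # "radius-uniform" mode
    heavy_atoms_only: bool = True
    color_both_empty: float = 1.0
    optimizer_tol: float = 1e-4
    optimizer_maxiter: int = 300

    def alpha(self, radius: float) -> float:
        return math.pi * (3.0 * self.p / (4.0 * math.pi * radius ** 3)) ** (2.0 / 3.0)


@dataclass(frozen=True)
class ConformerPolicy:
    """How many conformers each side of a comparison receives.

    The full-scale defaults mirror common screening practice (5 query
    conformers; 50 ChEMBL / 600 DrugBank reference conformers; 50 query
    conformers against single crystallographic PDB poses); validation runs
    scale these down through the pipeline configuration.
    """

    n_query_default: int = 5
    n_ref_chembl: int = 50
    n_ref_drugbank: int = 600
    n_query_vs_pdb: int = 50
    seed: int = 2020
    rmsd_dedup: float = 0.5  # Angstrom

    def __post_init__(self) -> None:
        for f in ("n_query_default", "n_ref_chembl", "n_ref_drugbank", "n_query_vs_pdb"):
            if getattr(self, f) < 1:
                raise ValueError(f"{f} must be >= 1")


class EmbeddingError(RuntimeError):
    pass


def _derived_seed(seed: int, tag: str) -> int:
    return int((seed + zlib.crc32(tag.encode())) % (2 ** 31 - 2)) + 1


def generate_conformers(mol: Chem.Mol, n_max: int, seed: int = 2020,
                        rmsd_dedup: float = 0.5) -> Chem.Mol:
    """Distance-geometry embedding + MMFF relaxation + RMSD deduplication.

    Returns a heavy-atom molecule carrying up to ``n_max`` conformers;
    deterministic for a fixed seed.  Raises :class:`EmbeddingError` when no
    conformer can be embedded.
    """
    molH = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = seed
    params.useRandomCoords = False
    n_embed = max(n_max * 2, 4)  # oversample, dedup prunes back
    ids = AllChem.EmbedMultipleConfs(molH, numConfs=n_embed, params=params)
    if len(ids) == 0:
        params.useRandomCoords = True
        ids = AllChem.EmbedMultipleConfs(molH, numConfs=n_embed, params=params)
    if len(ids) == 0:
        raise EmbeddingError(f"3D embedding failed for {Chem.MolToSmiles(mol)}")
    try:
        AllChem.MMFFOptimizeMoleculeConfs(molH, maxIters=200)
    except Exception:  # missing MMFF parameters: keep raw DG geometry
        pass
    heavy = Chem.RemoveHs(molH)
    kept: List[int] = []
    for cid in [c.GetId() for c in heavy.GetConformers()]:
        duplicate = False
        for kid in kept:
            rms = rdMolAlign.GetBestRMS(heavy, heavy, prbId=cid, refId=kid)
            if rms < rmsd_dedup:
                duplicate = True
                break
        if not duplicate:
            kept.append(cid)
        if len(kept) >= n_max:
            break
    out = Chem.Mol(heavy)
    out.RemoveAllConformers()
    for kid in kept:
        conf = Chem.Conformer(heavy.GetConformer(kid))
        out.AddConformer(conf, assignId=True)
    return out


# ---------------------------------------------------------------------------
# Gaussian shape model


@dataclass
class MolShape:
    """Precomputed Gaussian representation of one conformer."""

    coords: np.ndarray  # (N, 3) heavy-atom positions, centered copies not assumed
    alphas: np.ndarray  # (N,)
    features: Dict[str, np.ndarray]  # type -> (M, 3) feature points
    params: ShapeParams
    self_shape: float = 0.0
    self_color: float = 0.0

    def __post_init__(self) -> None:
        self.self_shape = _overlap(self.coords, self.alphas,
                                   self.coords, self.alphas, self.params.p)
        self.self_color = _color_overlap(self.features, self.features, self.params)


def _overlap(xa: np.ndarray, aa: np.ndarray, xb: np.ndarray, ab: np.ndarray,
             p: float) -> float:
    if len(xa) == 0 or len(xb) == 0:
        return 0.0
    diff = xa[:, None, :] - xb[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    asum = aa[:, None] + ab[None, :]
    aprod = aa[:, None] * ab[None, :]
    return float(np.sum(p * p * (np.pi / asum) ** 1.5 * np.exp(-aprod / asum * d2)))


def _color_overlap(fa: Mapping[str, np.ndarray], fb: Mapping[str, np.ndarray],
                   params: ShapeParams) -> float:
    alpha = params.alpha(params.color_radius)
    total = 0.0
    for ftype in FEATURE_TYPES:
        xa, xb = fa.get(ftype), fb.get(ftype)
        if xa is None or xb is None or len(xa) == 0 or len(xb) == 0:
            continue
        total += _overlap(xa, np.full(len(xa), alpha),
                          xb, np.full(len(xb), alpha), params.p)
    return total


_COMPILED_FEATURES = None


def _compiled_features():
    global _COMPILED_FEATURES
    if _COMPILED_FEATURES is None:
        _COMPILED_FEATURES = {
            ftype: [Chem.MolFromSmarts(s) for s in patterns]
            for ftype, patterns in FEATURE_SMARTS.items()
        }
    return _COMPILED_FEATURES


def feature_points(mol: Chem.Mol, conf_id: int = -1) -> Dict[str, np.ndarray]:
    """Pharmacophore feature points of one conformer (type -> (M, 3))."""
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    out: Dict[str, np.ndarray] = {}
    matched: Dict[str, set] = {}
    for ftype, patterns in _compiled_features().items():
        points, seen = [], set()
        for patt in patterns:
            if patt is None:
                continue
            for match in mol.GetSubstructMatches(patt):
                key = tuple(sorted(match))
                if key in seen:
                    continue
                seen.add(key)
                points.append(pos[list(match)].mean(axis=0))
        matched[ftype] = seen
        out[ftype] = np.asarray(points, dtype=float).reshape(-1, 3)
    ring_points = []
    for ring in mol.GetRingInfo().AtomRings():
        if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in ring):
            ring_points.append(pos[list(ring)].mean(axis=0))
    out["ring"] = np.asarray(ring_points, dtype=float).reshape(-1, 3)
    return out


def mol_shape(mol: Chem.Mol, conf_id: int = -1,
              params: Optional[ShapeParams] = None) -> MolShape:
    """Build the Gaussian representation of one conformer."""
    params = params or ShapeParams()
    conf = mol.GetConformer(conf_id)
    pos = conf.GetPositions()
    idx, radii = [], []
    for atom in mol.GetAtoms():
        if params.heavy_atoms_only and atom.GetAtomicNum() == 1:
            continue
        idx.append(atom.GetIdx())
        if params.uniform_radius is not None:
            radii.append(params.uniform_radius)
        else:
            radii.append(params.radii.get(atom.GetAtomicNum(), params.default_radius))
    coords = pos[idx]
    alphas = np.array([params.alpha(r) for r in radii])
    return MolShape(coords=coords, alphas=alphas,
                    features=feature_points(mol, conf_id), params=params)


def pairwise_overlap_volume(a: MolShape, b: MolShape) -> float:
    """First-order Gaussian overlap volume (Angstrom^3); symmetric, > 0."""
    return _overlap(a.coords, a.alphas, b.coords, b.alphas, a.params.p)


# ---------------------------------------------------------------------------
# rigid-body overlay optimization


def _principal_axes(coords: np.ndarray) -> np.ndarray:
    """Right-handed inertial axes (columns), deterministically signed."""
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(len(centered), 1)
    _, vecs = np.linalg.eigh(cov)
    vecs = vecs[:, ::-1]  # descending variance
    for k in range(3):
        j = int(np.argmax(np.abs(vecs[:, k])))
        if vecs[j, k] < 0:
            vecs[:, k] = -vecs[:, k]
    if np.linalg.det(vecs) < 0:
        vecs[:, 2] = -vecs[:, 2]
    return vecs


_PROPER_FLIPS = [np.diag(d) for d in
                 ((1, 1, 1), (1, -1, -1), (-1, 1, -1), (-1, -1, 1))]


def _is_degenerate(coords: np.ndarray) -> bool:
    centered = coords - coords.mean(axis=0)
    cov = centered.T @ centered / max(len(centered), 1)
    vals = np.linalg.eigvalsh(cov)
    return bool(vals[1] < 1e-6)  # rank < 2: collinear (or single point)


def optimize_overlay(query_mol: Chem.Mol, ref_mol: Chem.Mol,
                     params: Optional[ShapeParams] = None,
                     query_conf: int = -1, ref_conf: int = -1,
                     seed: int = 0) -> OverlayResult:
    """Best rigid superposition of the query conformer onto the reference.

    Starts from centroid superposition in the reference inertial frame over
    the four proper axis flips (plus seeded random-rotation starts for
    degenerate, near-collinear queries); each start is refined by
    Nelder-Mead over (axis-angle, translation).
    """
    params = params or ShapeParams()
    q = mol_shape(query_mol, query_conf, params)
    r = mol_shape(ref_mol, ref_conf, params)
    return overlay_shapes(q, r, params, seed=seed)


def overlay_shapes(q: MolShape, r: MolShape, params: Optional[ShapeParams] = None,
                   seed: int = 0) -> OverlayResult:
    params = params or q.params
    q_centroid = q.coords.mean(axis=0)
    r_centroid = r.coords.mean(axis=0)
    q0 = q.coords - q_centroid
    r_coords = r.coords
    q_feats0 = {t: (f - q_centroid if len(f) else f) for t, f in q.features.items()}
    axes_q = _principal_axes(q.coords)
    axes_r = _principal_axes(r.coords)

    starts = [axes_r @ flip @ axes_q.T for flip in _PROPER_FLIPS]
    if _is_degenerate(q.coords):
        log.debug("degenerate query geometry: adding random-rotation starts")
        rng = np.random.default_rng(seed or 12345)
        starts += [Rotation.random(random_state=rng).as_matrix() for _ in range(4)]

    alpha_c = params.alpha(params.color_radius)

    def objective(x: np.ndarray, base_rot: np.ndarray) -> float:
        rot = base_rot @ Rotation.from_rotvec(x[:3]).as_matrix()
        moved = q0 @ rot.T + r_centroid + x[3:]
        val = _overlap(moved, q.alphas, r_coords, r.alphas, params.p)
        for ftype in FEATURE_TYPES:
            fa, fb = q_feats0.get(ftype), r.features.get(ftype)
            if fa is None or fb is None or len(fa) == 0 or len(fb) == 0:
                continue
            fmoved = fa @ rot.T + r_centroid + x[3:]
            val += _overlap(fmoved, np.full(len(fa), alpha_c),
                            fb, np.full(len(fb), alpha_c), params.p)
        return -val

    best = None
    for base_rot in starts:
        res = minimize(objective, np.zeros(6), args=(base_rot,),
                       method="Nelder-Mead",
                       options={"xatol": params.optimizer_tol,
                                "fatol": params.optimizer_tol,
                                "maxiter": params.optimizer_maxiter,
                                "disp": False})
        if best is None or res.fun < best[0]:
            best = (res.fun, base_rot, res.x)

    _, base_rot, x = best
    rot = base_rot @ Rotation.from_rotvec(x[:3]).as_matrix()
    translation = r_centroid + x[3:] - rot @ q_centroid
    moved = q0 @ rot.T + r_centroid + x[3:]
    o_ab = _overlap(moved, q.alphas, r_coords, r.alphas, params.p)
    shape_t = o_ab / (q.self_shape + r.self_shape - o_ab)
    feats_moved = {t: (f @ rot.T + r_centroid + x[3:] if len(f) else f)
                   for t, f in q_feats0.items()}
    c_ab = _color_overlap(feats_moved, r.features, params)
    if q.self_color == 0.0 and r.self_color == 0.0:
        color_t = params.color_both_empty
    elif q.self_color == 0.0 or r.self_color == 0.0:
        color_t = 0.0
    else:
        color_t = c_ab / (q.self_color + r.self_color - c_ab)
    return OverlayResult(rotation=rot, translation=translation,
                         shape_tanimoto=float(shape_t),
                         color_tanimoto=float(color_t),
                         tanimoto_combo=float(shape_t + color_t),
                         n_starts_evaluated=len(starts))


# ---------------------------------------------------------------------------
# the 3D screen


def _conformer_shapes(mol: Chem.Mol, params: ShapeParams) -> List[MolShape]:
    return [mol_shape(mol, conf.GetId(), params) for conf in mol.GetConformers()]


def best_pair_overlay(query_shapes: Sequence[MolShape],
                      ref_shapes: Sequence[MolShape],
                      params: ShapeParams, seed: int = 0) -> OverlayResult:
    """Max TanimotoCombo over all conformer pairs of one molecule pair."""
    best: Optional[OverlayResult] = None
    for qs in query_shapes:
        for rs in ref_shapes:
            result = overlay_shapes(qs, rs, params, seed=seed)
            if best is None or result.tanimoto_combo > best.tanimoto_combo:
                best = result
    return best


def screen_3d(queries: Sequence[MoleculeRecord],
              references: Sequence[MoleculeRecord],
              policy: Optional[ConformerPolicy] = None,
              direction: str = "query_confs_vs_ref_confs",
              tc_min: float = 1.2,
              params: Optional[ShapeParams] = None,
              pairs: Optional[set] = None,
              ref_corpus: str = "chembl") -> Dict[Tuple[str, str], OverlayResult]:
    """Conformer-ensemble 3D screen of query records against references.

    ``direction='ref_crystal_vs_query_confs'`` uses the reference's stored
    (crystallographic) conformer directly and requires reference coordinates;
    otherwise reference conformers are generated per the policy
    (``n_ref_chembl`` or ``n_ref_drugbank`` by ``ref_corpus``).  ``pairs``
    optionally restricts scoring to a subset of (query_id, reference_id).
    Returns the best overlay per scored pair; callers derive
    ``pass_3d = tanimoto_combo >= tc_min``.
    """
    policy = policy or ConformerPolicy()
    params = params or ShapeParams()
    crystal = direction == "ref_crystal_vs_query_confs"
    n_query = policy.n_query_vs_pdb if crystal else policy.n_query_default
    n_ref = policy.n_ref_drugbank if ref_corpus == "drugbank" else policy.n_ref_chembl

    query_shapes: Dict[str, List[MolShape]] = {}
    for rec in queries:
        if pairs is not None and not any(p[0] == rec.record_id for p in pairs):
            continue
        try:
            confs = generate_conformers(
                rec.mol or Chem.MolFromSmiles(rec.smiles), n_query,
                seed=_derived_seed(policy.seed, rec.record_id),
                rmsd_dedup=policy.rmsd_dedup)
        except EmbeddingError as exc:
            log.warning("query %s skipped: %s", rec.record_id, exc)
            continue
        query_shapes[rec.record_id] = _conformer_shapes(confs, params)

    results: Dict[Tuple[str, str], OverlayResult] = {}
    for rec in references:
        if pairs is not None and not any(p[1] == rec.record_id for p in pairs):
            continue
        if crystal:
            if rec.mol is None or rec.mol.GetNumConformers() == 0:
                log.warning("reference %s has no coordinates in crystal mode; skipped",
                            rec.record_id)
                continue
            ref_shapes = _conformer_shapes(Chem.RemoveHs(rec.mol), params)
        else:
            try:
                confs = generate_conformers(
                    rec.mol or Chem.MolFromSmiles(rec.smiles), n_ref,
                    seed=_derived_seed(policy.seed, rec.record_id),
                    rmsd_dedup=policy.rmsd_dedup)
            except EmbeddingError as exc:
                log.warning("reference %s skipped: %s", rec.record_id, exc)
                continue
            ref_shapes = _conformer_shapes(confs, params)
        for qid, qshapes in query_shapes.items():
            if pairs is not None and (qid, rec.record_id) not in pairs:
                continue
            results[(qid, rec.record_id)] = best_pair_overlay(
                qshapes, ref_shapes, params, seed=policy.seed)
    return results


def apply_3d_results(records: Sequence, results: Mapping[Tuple[str, str], OverlayResult],
                     tc_min: float = 1.2) -> None:
    """Write best 3D scores and pass_3d flags onto SimilarityRecords in place."""
    for rec in records:
        res = results.get((rec.query_id, rec.reference_id))
        if res is None:
            continue
        rec.shape_tanimoto = res.shape_tanimoto
        rec.color_tanimoto = res.color_tanimoto
        rec.tc_combo = res.tanimoto_combo
        rec.pass_3d = res.tanimoto_combo >= tc_min
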