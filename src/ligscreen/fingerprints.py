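"""2D fingerprints, Tanimoto coefficients and the five-threshold screen.

Five fingerprint types are computed per molecule: MACCS structural keys
(166 bits) and the hashed circular ECFP4/ECFP6/FCFP4/FCFP6 fingerprints
(diameter 4/6 bonds, i.e. Morgan radius 2/3; the FCFP variants use
pharmacophoric feature invariants).  A query-reference pair passes the 2D
screen only when *all five* Tanimoto coefficients reach their thresholds
(defaults: MACCS >= 0.7, ECFP4 >= 0.3, ECFP6 >= 0.4, FCFP4 >= 0.3,
FCFP6 >= 0.4).
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdFingerprintGenerator

from .models import FINGERPRINT_NAMES, SimilarityRecord

DEFAULT_NBITS = 2048


@dataclass(frozen=True)
class ThresholdConfig:
    """Per-fingerprint Tanimoto thresholds of the 2D screen (inclusive)."""

    tc_maccs: float = 0.7
    tc_ecfp4: float = 0.3
    tc_ecfp6: float = 0.4
    tc_fcfp4: float = 0.3
    tc_fcfp6: float = 0.4

    def as_dict(self) -> Dict[str, float]:
        return {name: getattr(self, f"tc_{name}") for name in FINGERPRINT_NAMES}

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"threshold tc_{name}={v} outside [0, 1]")


@dataclass
class FingerprintSet:
    """The five bitsets of one molecule (boolean numpy arrays)."""

    maccs: np.ndarray
    ecfp4: np.ndarray
    ecfp6: np.ndarray
    fcfp4: np.ndarray
    fcfp6: np.ndarray

    def __getitem__(self, name: str) -> np.ndarray:
        return getattr(self, name)


def _bitvect_to_array(bv) -> np.ndarray:
    arr = np.zeros(bv.GetNumBits(), dtype=bool)
    arr[list(bv.GetOnBits())] = True
    return arr


_GENERATOR_CACHE: dict = {}


def _morgan_generator(radius: int, n_bits: int, features: bool):
    key = (radius, n_bits, features)
    if key not in _GENERATOR_CACHE:
        inv = (rdFingerprintGenerator.GetMorganFeatureAtomInvGen()
               if features else None)
        _GENERATOR_CACHE[key] = rdFingerprintGenerator.GetMorganGenerator(
            radius=radius, fpSize=n_bits, atomInvariantsGenerator=inv)
    return _GENERATOR_CACHE[key]


def fingerprint(mol: Chem.Mol, kind: str, n_bits: int = DEFAULT_NBITS) -> np.ndarray:
    """One fingerprint bitset; ``kind`` is maccs/ecfp4/ecfp6/fcfp4/fcfp6.

    The numeric suffix of the circular fingerprints is the environment
    *diameter* in bonds, so ecfp4 uses Morgan radius 2 and ecfp6 radius 3.
    """
    if mol.GetNumHeavyAtoms() == 0:
        raise ValueError("cannot fingerprint a molecule with zero heavy atoms")
    if kind == "maccs":
        # RDKit emits 167 bits with bit 0 always off; keep the 166 keys
        return _bitvect_to_array(MACCSkeys.GenMACCSKeys(mol))[1:]
    if kind in ("ecfp4", "ecfp6", "fcfp4", "fcfp6"):
        radius = {"4": 2, "6": 3}[kind[-1]]
        gen = _morgan_generator(radius, n_bits, features=kind.startswith("f"))
        return _bitvect_to_array(gen.GetFingerprint(mol))
    raise ValueError(f"unknown fingerprint kind {kind!r}")


def fingerprint_set(mol: Chem.Mol, n_bits: int = DEFAULT_NBITS) -> FingerprintSet:
    return FingerprintSet(**{k: fingerprint(mol, k, n_bits) for k in FINGERPRINT_NAMES})


def tanimoto(a: np.ndarray, b: np.ndarray, both_empty: float = 1.0) -> float:
    """Tanimoto coefficient |a&b| / |a|+|b|-|a&b| of two equal-length bitsets.

    Two all-zero bitsets are indistinguishable to the fingerprint, so the
    coefficient defaults to 1 there (configurable via ``both_empty``).
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"bitset length mismatch: {a.shape} vs {b.shape}")
    inter = int(np.count_nonzero(a & b))
    union = int(np.count_nonzero(a)) + int(np.count_nonzero(b)) - inter
    if union == 0:
        return both_empty
    return inter / union


def tanimoto_profile(q: FingerprintSet, r: FingerprintSet) -> Dict[str, float]:
    return {name: tanimoto(q[name], r[name]) for name in FINGERPRINT_NAMES}


def passes_thresholds(tc: Mapping[str, float], thresholds: ThresholdConfig) -> bool:
    limits = thresholds.as_dict()
    return all(tc[name] >= limits[name] for name in FINGERPRINT_NAMES)


def screen_2d(queries: Mapping[str, FingerprintSet],
              references: Mapping[str, FingerprintSet],
              thresholds: Optional[ThresholdConfig] = None) -> list:
    """All-against-all 2D screen.

    Returns one :class:`SimilarityRecord` per (query, reference) pair with
    all five coefficients; ``pass_2d`` is the conjunction over the five
    thresholds.  Failing records stay in the table (the hit view filters).
    """
    if not queries or not references:
        raise ValueError("screen_2d requires non-empty query and reference maps")
    thresholds = thresholds or ThresholdConfig()
    records = []
    for qid, qfp in queries.items():
        for rid, rfp in references.items():
            tc = tanimoto_profile(qfp, rfp)
            records.append(SimilarityRecord(
                query_id=qid, reference_id=rid, tc=tc,
                pass_2d=passes_thresholds(tc, thresholds)))
    return records
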