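"""Molecular featurization: descriptors, circular fingerprints, scaffolds, similarity.

All structure-derived features used by the pipeline live here so that the
training and screening stages are guaranteed to share one parameterization.
Fingerprints are Morgan (ECFP-like) bit vectors; scaffolds are Bemis–Murcko
frameworks; similarity is the Tanimoto coefficient on bit sets.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import Crippen, Descriptors, rdFingerprintGenerator, rdMolDescriptors
from rdkit.Chem.Scaffolds import MurckoScaffold

RDLogger.DisableLog("rdApp.*")

__all__ = [
    "FingerprintParams",
    "DescriptorProfile",
    "mol_from_smiles",
    "compute_descriptors",
    "fingerprint",
    "fingerprint_matrix",
    "fingerprint_bit_info",
    "murcko_scaffold",
    "tanimoto",
    "tanimoto_matrix",
]


@dataclass(frozen=True)
class FingerprintParams:
    """Morgan fingerprint settings shared between training and screening.

    Defaults: radius 2, 2048 bits, chirality excluded. ``config_hash`` lets a
    screening run assert byte-identical settings against the training echo.
    """

    radius: int = 2
    n_bits: int = 2048
    use_chirality: bool = False

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()

    def _generator(self):
        return rdFingerprintGenerator.GetMorganGenerator(
            radius=self.radius,
            fpSize=self.n_bits,
            includeChirality=self.use_chirality,
        )


DEFAULT_FP_PARAMS = FingerprintParams()


@dataclass(frozen=True)
class DescriptorProfile:
    """Physicochemical summary of one molecule.

    ``lipinski_violations`` counts rules broken among MW>500, LogP>5, HBD>5,
    HBA>10; it is reported as an indicator only, never used for exclusion.
    """

    mw: float
    logp: float
    hbd: int
    hba: int
    tpsa: float
    rotatable_bonds: int
    ring_count: int
    lipinski_violations: int

    def to_dict(self) -> dict:
        return asdict(self)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse a SMILES string, raising ``ValueError`` on failure."""
    if smiles is None or not isinstance(smiles, str) or not smiles:
        raise ValueError("empty SMILES")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES: {smiles!r}")
    return mol


def compute_descriptors(smiles: str) -> DescriptorProfile:
    """Compute the eight-descriptor profile for a valid structure.

    LogP is the Crippen estimate and TPSA the Ertl topological estimate,
    the toolkit-standard algorithms for these named descriptors.
    """
    mol = mol_from_smiles(smiles)
    mw = Descriptors.MolWt(mol)
    logp = Crippen.MolLogP(mol)
    hbd = rdMolDescriptors.CalcNumHBD(mol)
    hba = rdMolDescriptors.CalcNumHBA(mol)
    tpsa = rdMolDescriptors.CalcTPSA(mol)
    rot = rdMolDescriptors.CalcNumRotatableBonds(mol)
    rings = rdMolDescriptors.CalcNumRings(mol)
    violations = int(mw > 500) + int(logp > 5) + int(hbd > 5) + int(hba > 10)
    return DescriptorProfile(
        mw=mw,
        logp=logp,
        hbd=hbd,
        hba=hba,
        tpsa=tpsa,
        rotatable_bonds=rot,
        ring_count=rings,
        lipinski_violations=violations,
    )


def fingerprint(smiles: str, params: FingerprintParams = DEFAULT_FP_PARAMS) -> np.ndarray:
    """Morgan fingerprint of one molecule as a uint8 0/1 vector of length n_bits."""
    mol = mol_from_smiles(smiles)
    fp = params._generator().GetFingerprint(mol)
    arr = np.zeros(params.n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr


def fingerprint_matrix(
    smiles_list, params: FingerprintParams = DEFAULT_FP_PARAMS
) -> np.ndarray:
    """Stack fingerprints for a sequence of SMILES into an (n, n_bits) matrix."""
    n = len(smiles_list)
    out = np.zeros((n, params.n_bits), dtype=np.uint8)
    gen = params._generator()
    for i, smi in enumerate(smiles_list):
        mol = mol_from_smiles(smi)
        out[i, list(gen.GetFingerprint(mol).GetOnBits())] = 1
    return out


def fingerprint_bit_info(
    smiles: str, params: FingerprintParams = DEFAULT_FP_PARAMS
) -> tuple[np.ndarray, dict[int, tuple[tuple[int, int], ...]]]:
    """Fingerprint plus the bit → ((center_atom, radius), ...) map for one molecule."""
    mol = mol_from_smiles(smiles)
    gen = params._generator()
    ao = rdFingerprintGenerator.AdditionalOutput()
    ao.AllocateBitInfoMap()
    fp = gen.GetFingerprint(mol, additionalOutput=ao)
    arr = np.zeros(params.n_bits, dtype=np.uint8)
    arr[list(fp.GetOnBits())] = 1
    return arr, dict(ao.GetBitInfoMap())


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko framework (rings plus linkers) as canonical SMILES.

    Acyclic molecules return the empty string, which downstream code treats
    as its own scaffold group.
    """
    mol = mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """Tanimoto coefficient |A∩B|/|A∪B| of two equal-length bit vectors.

    Defined as 0.0 when both vectors are all-zero.
    """
    a = np.asarray(fp_a, dtype=bool)
    b = np.asarray(fp_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"fingerprint length mismatch: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        return 0.0
    return float(np.logical_and(a, b).sum() / union)


def tanimoto_matrix(fps_a: np.ndarray, fps_b: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto matrix between two stacks of bit vectors.

    Rows index ``fps_a``, columns ``fps_b``. All-zero vs all-zero pairs get 0.
    """
    a = np.asarray(fps_a, dtype=np.float64)
    b = np.asarray(fps_b, dtype=np.float64)
    if a.ndim != 2 or b.ndim != 2 or a.shape[1] != b.shape[1]:
        raise ValueError("fingerprint matrices must be 2-D with equal width")
    inter = a @ b.T
    union = a.sum(axis=1)[:, None] + b.sum(axis=1)[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.where(union > 0, union, 1.0), 0.0)
    return sim
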