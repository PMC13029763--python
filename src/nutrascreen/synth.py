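"""Synthetic bioactivity data with known ground truth.

Emulates the two data regimes the pipeline consumes without any external
download: (a) a bioactivity-database-style activity-record table — replicate
measurements
in mixed nM/µM units, inexact relations, low-confidence assays, salts and
unparsable structures — over compounds built from scaffold families with
planted substituent effects on a latent pActivity; (b) a food-catalogue-style
screening library mixing in-family compounds with structurally remote decoy
chemotypes, plus duplicates and defective rows.

Everything is drawn from seeded generators in a documented order, so an
identical spec yields byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem

from .features import murcko_scaffold

__all__ = [
    "SyntheticSpec",
    "generate_activity_table",
    "generate_screening_library",
    "distinct_scaffolds",
    "distinct_scaffold_library",
    "write_synthetic_outputs",
]

# Fixed unparsable strings injected as invalid structures (deterministic audit counts).
INVALID_SMILES = ("notasmiles", "C1CC", "X[Qq]Z", "c1ccccc", "(((", "C(C)(C)(C)(C)C")

# Counter-ions appended to make multi-fragment (salt) entries.
SALT_FRAGMENTS = ("Cl", "[Na+]", "O", "OC(=O)C(=O)O")

# Default substituent pool: acyclic fragments with a dummy-atom attachment point.
DEFAULT_POOL = (
    "*C",
    "*CC",
    "*O",
    "*OC",
    "*N",
    "*F",
    "*Cl",
    "*C#N",
    "*C(=O)O",
    "*C(=O)N",
)

# Planted effects on latent pActivity (log10 units); unlisted substituents are neutral.
DEFAULT_MOTIF_EFFECTS = {"*C(=O)O": 1.5, "*C(=O)N": 0.7, "*Cl": -0.7}

_AROMATIC_RINGS = (
    "c1ccccc1",
    "c1ccncc1",
    "c1ccnnc1",
    "c1ccoc1",
    "c1ccsc1",
    "c1cc[nH]c1",
    "c1cncnc1",
    "c1ccc2ccccc2c1",
    "c1ccc2[nH]ccc2c1",
    "c1ccc2ncccc2c1",
)

_SATURATED_RINGS = (
    "C1CC1",
    "C1CCC1",
    "C1CCCC1",
    "C1CCCCC1",
    "C1CCCCCC1",
    "C1CCCCCCC1",
    "C1CCOC1",
    "C1CCNC1",
    "C1CCSC1",
    "C1CCOCC1",
    "C1CCNCC1",
    "C1CCSCC1",
    "C1CCOCCC1",
    "C1CCNCCC1",
    "C1COCCN1",
    "C1CNCCN1",
    "C1COCCO1",
    "C1CSCCN1",
)

_ALL_RINGS = _AROMATIC_RINGS + _SATURATED_RINGS


@dataclass(frozen=True)
class SyntheticSpec:
    """Study conditions for the synthetic activity table and screening library.

    Latent pActivity of a compound is ``base_pactivity`` plus the sum of the
    planted effects of its substituents; each activity record reports
    IC50 = 10^(9 − (latent + Gaussian record noise)) in nM, a
    ``micromolar_fraction`` of records being re-expressed in µM.
    """

    n_compounds: int = 2000
    n_scaffold_families: int = 150
    substituent_pool: tuple[str, ...] = DEFAULT_POOL
    motif_effects: dict = field(default_factory=lambda: dict(DEFAULT_MOTIF_EFFECTS))
    base_pactivity: float = 5.5
    noise_sd: float = 0.3
    micromolar_fraction: float = 0.3
    replicate_rate: float = 0.3
    inexact_relation_rate: float = 0.05
    invalid_smiles_rate: float = 0.02
    salt_rate: float = 0.05
    low_confidence_rate: float = 0.05
    other_assay_rate: float = 0.05
    max_substituents: int = 3
    n_library: int = 600
    library_decoy_fraction: float = 0.5
    library_duplicate_rate: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if self.n_compounds <= 0 or self.n_scaffold_families <= 0:
            raise ValueError("n_compounds and n_scaffold_families must be positive")
        if not self.substituent_pool:
            raise ValueError("substituent pool must not be empty")
        for name, p in (
            ("micromolar_fraction", self.micromolar_fraction),
            ("inexact_relation_rate", self.inexact_relation_rate),
            ("invalid_smiles_rate", self.invalid_smiles_rate),
            ("salt_rate", self.salt_rate),
            ("low_confidence_rate", self.low_confidence_rate),
            ("other_assay_rate", self.other_assay_rate),
            ("library_decoy_fraction", self.library_decoy_fraction),
            ("library_duplicate_rate", self.library_duplicate_rate),
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.noise_sd < 0 or self.replicate_rate < 0:
            raise ValueError("noise_sd and replicate_rate must be non-negative")
        if self.max_substituents < 1:
            raise ValueError("max_substituents must be at least 1")


def distinct_scaffolds(n: int) -> list[str]:
    """Enumerate ``n`` SMILES with pairwise-distinct Murcko frameworks.

    Candidates are single rings followed by ring–(CH2)k–ring assemblies over a
    fixed ring alphabet (k = 0..5); each candidate is its own Murcko scaffold,
    so distinct canonical SMILES guarantee distinct scaffold groups. The
    enumeration order is fixed, making the output deterministic.
    """
    seen: set[str] = set()
    out: list[str] = []

    def _try(smi: str) -> None:
        mol = Chem.MolFromSmiles(smi)
        if mol is None:
            return
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            return
        if murcko_scaffold(canon) != canon:
            return  # not a pure framework; skip for safety
        seen.add(canon)
        out.append(canon)

    for ring in _ALL_RINGS:
        if len(out) >= n:
            return out[:n]
        _try(ring)
    for k in range(6):
        linker = "C" * k
        for a in _ALL_RINGS:
            for b in _ALL_RINGS:
                if len(out) >= n:
                    return out[:n]
                _try(a + linker + b)
    if len(out) < n:
        raise ValueError(f"can only enumerate {len(out)} distinct scaffolds, need {n}")
    return out[:n]


def distinct_scaffold_library(n: int, prefix: str = "SCF") -> pd.DataFrame:
    """Bare-scaffold compound table (id, smiles): one compound per distinct scaffold."""
    smiles = distinct_scaffolds(n)
    return pd.DataFrame(
        {"compound_id": [f"{prefix}{i:05d}" for i in range(n)], "smiles": smiles}
    )


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    """Carbon atoms with at least one hydrogen, eligible for substitution."""
    return [
        a.GetIdx()
        for a in mol.GetAtoms()
        if a.GetSymbol() == "C" and a.GetTotalNumHs() >= 1
    ]

def _build_compound(core_smiles: str, sites: list[int], frags: list[str]) -> str:
    """Attach dummy-labelled fragments to core atoms; return canonical SMILES."""
    mol = Chem.MolFromSmiles(core_smiles)
    rw = Chem.RWMol(mol)
    for site, frag_smiles in zip(sites, frags):
        frag = Chem.MolFromSmiles(frag_smiles)
        offset = rw.GetNumAtoms()
        combo = Chem.RWMol(Chem.CombineMols(rw.GetMol(), frag))
        dummy = next(
            a.GetIdx()
            for a in combo.GetAtoms()
            if a.GetIdx() >= offset and a.GetAtomicNum() == 0
        )
        anchor = combo.GetAtomWithIdx(dummy).GetNeighbors()[0].GetIdx()
        combo.AddBond(site, anchor, Chem.BondType.SINGLE)
        combo.RemoveAtom(dummy)
        rw = combo
    product = rw.GetMol()
    Chem.SanitizeMol(product)
    return Chem.MolToSmiles(product)


def generate_activity_table(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate (activity-record table, ground-truth table) under ``spec``.

    Draw order per compound (one global seeded stream): scaffold family,
    number of substituents, attachment sites, substituents, invalid-SMILES
    draw, salt draw, replicate count, then per record: noise, unit, relation,
    assay type, confidence, year. Injections are logged in the ground truth.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cores = distinct_scaffolds(spec.n_scaffold_families)
    pool = list(spec.substituent_pool)
    records: list[dict] = []
    truth: list[dict] = []
    n_invalid_used = 0
    for i in range(spec.n_compounds):
        cid = f"SYN{i:05d}"
        fam = int(rng.integers(0, len(cores)))
        core = cores[fam]
        sites_all = _attachment_sites(Chem.MolFromSmiles(core))
        k = int(rng.integers(1, spec.max_substituents + 1))
        k = min(k, len(sites_all), len(pool))
        sites = [int(s) for s in rng.choice(sites_all, size=k, replace=False)]
        subs = [pool[int(j)] for j in rng.choice(len(pool), size=k, replace=False)]
        smiles = _build_compound(core, sites, subs)
        latent = spec.base_pactivity + sum(
            spec.motif_effects.get(s, 0.0) for s in subs
        )
        emit_invalid = bool(rng.random() < spec.invalid_smiles_rate)
        emit_salt = bool(rng.random() < spec.salt_rate)
        if emit_invalid:
            emitted = INVALID_SMILES[n_invalid_used % len(INVALID_SMILES)]
            n_invalid_used += 1
        elif emit_salt:
            salt = SALT_FRAGMENTS[int(rng.integers(0, len(SALT_FRAGMENTS)))]
            emitted = f"{smiles}.{salt}"
        else:
            emitted = smiles
        n_rec = 1 + int(rng.poisson(spec.replicate_rate))
        for _ in range(n_rec):
            noise = float(rng.normal(0.0, spec.noise_sd)) if spec.noise_sd > 0 else 0.0
            pact = latent + noise
            value_nm = 10.0 ** (9.0 - pact)
            if rng.random() < spec.micromolar_fraction:
                value, unit = value_nm / 1000.0, "uM"
            else:
                value, unit = value_nm, "nM"
            relation = ">" if rng.random() < spec.inexact_relation_rate else "="
            assay_type = "Ki" if rng.random() < spec.other_assay_rate else "IC50"
            confidence = 5 if rng.random() < spec.low_confidence_rate else 9
            year = 2010 + int(rng.integers(0, 15))
            records.append(
                {
                    "compound_id": cid,
                    "smiles": emitted,
                    "assay_type": assay_type,
                    "relation": relation,
                    "value": value,
                    "unit": unit,
                    "confidence": confidence,
                    "standardization_flag": "validated",
                    "year": year,
                }
            )
        truth.append(
            {
                "compound_id": cid,
                "smiles": smiles,
                "scaffold_family": fam,
                "scaffold_smiles": core,
                "latent_pactivity": latent,
                "planted_motifs": ";".join(sorted(subs)),
                "emitted_invalid": emit_invalid,
                "emitted_salt": (not emit_invalid) and emit_salt,
                "n_records": n_rec,
            }
        )
    return pd.DataFrame(records), pd.DataFrame(truth)


def _build_decoy(rng: np.random.Generator) -> str:
    """Acyclic decoy chemotype far from the ring-based training families."""
    kind = int(rng.integers(0, 3))
    m = int(rng.integers(3, 11))
    if kind == 0:  # perfluoroalkane
        return "FC(F)(F)" + "C(F)(F)" * m + "F"
    if kind == 1:  # polyol chain
        return "OC" + "C(O)" * m + "CO"
    return "CCCCCCCC(=O)OC" + "C" * m  # fatty ester


def generate_screening_library(
    spec: SyntheticSpec, with_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """Screening table (id, name, smiles) mixing in-family compounds and decoys.

    In-family entries are built exactly like the training compounds (same
    cores and substituent pool) so they can fall inside the applicability
    domain; decoys are remote acyclic chemotypes so the domain split is
    non-degenerate. Duplicates, salts and invalid rows are injected at the
    spec rates. A separate seeded stream keeps the library independent of the
    activity table draws.
    """
    spec.validate()
    rng = np.random.default_rng([spec.seed, 1])
    cores = distinct_scaffolds(spec.n_scaffold_families)
    pool = list(spec.substituent_pool)
    n_decoy = int(round(spec.n_library * spec.library_decoy_fraction))
    rows: list[dict] = []
    kinds: list[str] = []
    n_invalid_used = 0
    for i in range(spec.n_library):
        if i < spec.n_library - n_decoy:
            fam = int(rng.integers(0, len(cores)))
            core = cores[fam]
            sites_all = _attachment_sites(Chem.MolFromSmiles(core))
            k = int(rng.integers(1, spec.max_substituents + 1))
            k = min(k, len(sites_all), len(pool))
            sites = [int(s) for s in rng.choice(sites_all, size=k, replace=False)]
            subs = [pool[int(j)] for j in rng.choice(len(pool), size=k, replace=False)]
            smiles = _build_compound(core, sites, subs)
            kind = "family"
        else:
            smiles = _build_decoy(rng)
            kind = "decoy"
        if rng.random() < spec.library_duplicate_rate and rows:
            src = rows[int(rng.integers(0, len(rows)))]
            smiles, kind = src["smiles"], "duplicate"
        elif rng.random() < spec.invalid_smiles_rate:
            smiles = INVALID_SMILES[n_invalid_used % len(INVALID_SMILES)]
            n_invalid_used += 1
            kind = "invalid"
        elif rng.random() < spec.salt_rate:
            salt = SALT_FRAGMENTS[int(rng.integers(0, len(SALT_FRAGMENTS)))]
            smiles = f"{smiles}.{salt}"
            kind = kind + "+salt"
        rows.append(
            {"id": f"EXT{i:05d}", "name": f"synthetic-food-{i:05d}", "smiles": smiles}
        )
        kinds.append(kind)
    library = pd.DataFrame(rows)
    if with_truth:
        truth = pd.DataFrame({"id": library["id"], "kind": kinds})
        return library, truth
    return library


def write_synthetic_outputs(spec: SyntheticSpec, out_dir: str | Path) -> dict:
    """Write activity table, ground truth, library (CSV + .smi) and spec echo."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    activity, truth = generate_activity_table(spec)
    library = generate_screening_library(spec)
    paths = {
        "activity": out / "activity.csv",
        "ground_truth": out / "ground_truth.csv",
        "library_csv": out / "library.csv",
        "library_smi": out / "library.smi",
        "spec": out / "spec.yaml",
    }
    activity.to_csv(paths["activity"], index=False)
    truth.to_csv(paths["ground_truth"], index=False)
    library.to_csv(paths["library_csv"], index=False)
    with open(paths["library_smi"], "w") as fh:
        for _, row in library.iterrows():
            fh.write(f"{row['smiles']}\t{row['id']}\n")
    cfg = {k: (list(v) if isinstance(v, tuple) else v) for k, v in vars(spec).items()}
    with open(paths["spec"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
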