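"""Molecule records, fingerprints, similarity search, and library hygiene.

This module holds the cheminformatics primitives of the hit-optimization
workflow: canonical SMILES bookkeeping, SMARTS substructure filtering,
Murcko scaffolds, binary fingerprints of several kinds, Tanimoto distances,
and the nearest-neighbour expansion used to diversify an analog library.

All molecule handling goes through RDKit; fingerprints are deterministic for
a fixed (SMILES, kind, seed) triple within one RDKit build, but bit-level
identity across cheminformatics toolkits is not promised.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem, RDLogger
from rdkit.Chem import AllChem, rdFingerprintGenerator
from rdkit.Chem.Pharm2D import Generate as Pharm2DGenerate
from rdkit.Chem.Pharm2D import Gobbi_Pharm2D
from rdkit.Chem.Scaffolds import MurckoScaffold

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")


class ChemlibError(ValueError):
    """Base error for library-hygiene and similarity operations."""


class UnsupportedFingerprintError(ChemlibError):
    """Raised for fingerprint kinds with no available implementation."""


class SourceTag(str, Enum):
    """Provenance of a library member."""

    CLOSEST = "closest"
    GENERAL = "general"
    SYNTHETIC = "synthetic"


class FingerprintKind(str, Enum):
    """Supported molecular featurizations.

    path7_2048   RDKit path (Daylight-style) fingerprint, max path 7, 2048 bits
    ecfp6_2048   Morgan / extended-connectivity fingerprint, radius 3, 2048 bits
    e3fp_default three-dimensional extended fingerprint (no implementation here)
    ph4_2d_1024  2D pharmacophore-pair fingerprint folded to 1024 bits
    ph4_3d_1024  3D pharmacophore-pair fingerprint (seeded conformer), 1024 bits
    """

    PATH7_2048 = "path7_2048"
    ECFP6_2048 = "ecfp6_2048"
    E3FP_DEFAULT = "e3fp_default"
    PH4_2D_1024 = "ph4_2d_1024"
    PH4_3D_1024 = "ph4_3d_1024"


_FP_LENGTH = {
    FingerprintKind.PATH7_2048: 2048,
    FingerprintKind.ECFP6_2048: 2048,
    FingerprintKind.PH4_2D_1024: 1024,
    FingerprintKind.PH4_3D_1024: 1024,
}


@dataclass(frozen=True)
class Fingerprint:
    """A binary molecular fingerprint of a declared kind."""

    kind: FingerprintKind
    bits: np.ndarray  # uint8 0/1 vector

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        expected = _FP_LENGTH.get(self.kind)
        if expected is not None and bits.shape != (expected,):
            raise ChemlibError(
                f"fingerprint kind {self.kind.value} requires length {expected}, "
                f"got {bits.shape}"
            )

    @property
    def on_bits(self) -> frozenset[int]:
        return frozenset(np.flatnonzero(self.bits).tolist())


@dataclass
class MoleculeRecord:
    """One library member.

    ``smiles`` is stored canonical and isomeric.  ``scaffold_smiles`` is the
    Murcko scaffold (empty for acyclic molecules).  ``substituents`` carries
    the substituent labels attached by the synthetic analog generator and is
    None for molecules of external provenance.
    """

    id: str
    smiles: str
    net_formal_charge: int = 0
    scaffold_smiles: str = ""
    source_tag: SourceTag = SourceTag.SYNTHETIC
    substituents: tuple[str, ...] | None = None

    @classmethod
    def from_smiles(
        cls,
        mol_id: str,
        smiles: str,
        source_tag: SourceTag = SourceTag.SYNTHETIC,
        substituents: tuple[str, ...] | None = None,
    ) -> "MoleculeRecord":
        mol = mol_from_smiles(smiles)
        return cls(
            id=mol_id,
            smiles=Chem.MolToSmiles(mol),
            net_formal_charge=Chem.GetFormalCharge(mol),
            scaffold_smiles=murcko_scaffold(smiles),
            source_tag=source_tag,
            substituents=substituents,
        )

    def to_mol(self) -> Chem.Mol:
        return mol_from_smiles(self.smiles)


@dataclass
class RejectionReport:
    """Per-record rejections collected by library hygiene ops."""

    rejected: list[tuple[str, str]] = field(default_factory=list)  # (id, reason)

    def add(self, mol_id: str, reason: str) -> None:
        self.rejected.append((mol_id, reason))
        logger.info("rejected %s: %s", mol_id, reason)


def mol_from_smiles(smiles: str) -> Chem.Mol:
    """Parse SMILES, raising :class:`ChemlibError` on failure."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ChemlibError(f"unparseable SMILES: {smiles!r}")
    return mol


def canonical_smiles(smiles: str) -> str:
    return Chem.MolToSmiles(mol_from_smiles(smiles))


def murcko_scaffold(smiles: str) -> str:
    """Murcko scaffold: ring systems plus linkers, side chains pruned.

    Acyclic molecules have no scaffold and return the empty string.
    """
    mol = mol_from_smiles(smiles)
    scaffold = MurckoScaffold.GetScaffoldForMol(mol)
    if scaffold is None or scaffold.GetNumAtoms() == 0:
        return ""
    return Chem.MolToSmiles(scaffold)


def canonicalize_and_dedup(
    records: Iterable[MoleculeRecord],
    report: RejectionReport | None = None,
) -> list[MoleculeRecord]:
    """Deduplicate on canonical isomeric SMILES and drop charged molecules.

    The first record carrying a given canonical SMILES wins; records whose
    net formal charge is nonzero are removed; input order is otherwise
    preserved.  Unparseable records are rejected into ``report`` rather than
    raising.
    """
    seen: set[str] = set()
    kept: list[MoleculeRecord] = []
    for rec in records:
        try:
            mol = mol_from_smiles(rec.smiles)
        except ChemlibError as exc:
            if report is not None:
                report.add(rec.id, str(exc))
            continue
        charge = Chem.GetFormalCharge(mol)
        if charge != 0:
            if report is not None:
                report.add(rec.id, f"net formal charge {charge:+d}")
            continue
        canon = Chem.MolToSmiles(mol)
        if canon in seen:
            if report is not None:
                report.add(rec.id, f"duplicate of canonical SMILES {canon}")
            continue
        seen.add(canon)
        updated = MoleculeRecord(
            id=rec.id,
            smiles=canon,
            net_formal_charge=charge,
            scaffold_smiles=rec.scaffold_smiles or murcko_scaffold(canon),
            source_tag=rec.source_tag,
            substituents=rec.substituents,
        )
        kept.append(updated)
    return kept


def substructure_filter(
    records: Sequence[MoleculeRecord], pattern: str
) -> list[MoleculeRecord]:
    """Keep exactly the records containing >=1 match of the SMARTS pattern."""
    query = Chem.MolFromSmarts(pattern)
    if query is None:
        raise ChemlibError(f"invalid SMARTS pattern: {pattern!r}")
    return [rec for rec in records if rec.to_mol().HasSubstructMatch(query)]


def _fold_bits(on_bits: Iterable[int], n_bits: int) -> np.ndarray:
    vec = np.zeros(n_bits, dtype=np.uint8)
    for b in on_bits:
        vec[b % n_bits] = 1
    return vec


def _embed_conformer(mol: Chem.Mol, seed: int) -> Chem.Mol:
    molh = Chem.AddHs(mol)
    params = AllChem.ETKDGv3()
    params.randomSeed = int(seed) & 0x7FFFFFFF
    if AllChem.EmbedMolecule(molh, params) != 0:
        raise ChemlibError("conformer generation failed")
    AllChem.MMFFOptimizeMolecule(molh, maxIters=200)
    return Chem.RemoveHs(molh)


def featurize(
    record: MoleculeRecord | str,
    kind: FingerprintKind | str = FingerprintKind.ECFP6_2048,
    seed: int = 2024,
) -> Fingerprint:
    """Compute a binary fingerprint of the requested kind.

    3D kinds embed a single seeded ETKDG conformer (MMFF-relaxed); the same
    (SMILES, kind, seed) always yields identical bits.
    """
    kind = FingerprintKind(kind)
    smiles = record.smiles if isinstance(record, MoleculeRecord) else record
    mol = mol_from_smiles(smiles)

    if kind is FingerprintKind.ECFP6_2048:
        gen = rdFingerprintGenerator.GetMorganGenerator(radius=3, fpSize=2048)
        bits = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    elif kind is FingerprintKind.PATH7_2048:
        gen = rdFingerprintGenerator.GetRDKitFPGenerator(maxPath=7, fpSize=2048)
        bits = np.asarray(gen.GetFingerprintAsNumPy(mol), dtype=np.uint8)
    elif kind is FingerprintKind.PH4_2D_1024:
        sig = Pharm2DGenerate.Gen2DFingerprint(mol, Gobbi_Pharm2D.factory)
        bits = _fold_bits(sig.GetOnBits(), 1024)
    elif kind is FingerprintKind.PH4_3D_1024:
        conf_mol = _embed_conformer(mol, seed)
        dmat = Chem.Get3DDistanceMatrix(conf_mol)
        sig = Pharm2DGenerate.Gen2DFingerprint(
            conf_mol, Gobbi_Pharm2D.factory, dMat=dmat
        )
        bits = _fold_bits(sig.GetOnBits(), 1024)
    else:
        raise UnsupportedFingerprintError(
            f"no implementation available for fingerprint kind {kind.value}"
        )
    return Fingerprint(kind=kind, bits=bits)


def tanimoto_distance(a: Fingerprint, b: Fingerprint) -> float:
    """1 - |a AND b| / |a OR b|; two all-zero fingerprints have distance 0."""
    if a.kind is not b.kind:
        raise ChemlibError(
            f"fingerprint kind mismatch: {a.kind.value} vs {b.kind.value}"
        )
    inter = int(np.sum((a.bits & b.bits) > 0))
    union = int(np.sum((a.bits | b.bits) > 0))
    if union == 0:
        return 0.0
    return 1.0 - inter / union


def fingerprint_matrix(
    records: Sequence[MoleculeRecord],
    kind: FingerprintKind | str = FingerprintKind.ECFP6_2048,
    seed: int = 2024,
) -> np.ndarray:
    """Stack fingerprints of all records into an (n, n_bits) uint8 matrix."""
    return np.vstack([featurize(r, kind, seed=seed).bits for r in records])


def tanimoto_distance_matrix(xa: np.ndarray, xb: np.ndarray) -> np.ndarray:
    """Pairwise Tanimoto distances between rows of two binary matrices."""
    xa = np.asarray(xa, dtype=np.float64)
    xb = np.asarray(xb, dtype=np.float64)
    inter = xa @ xb.T
    na = xa.sum(axis=1)[:, None]
    nb = xb.sum(axis=1)[None, :]
    union = na + nb - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        sim = np.where(union > 0, inter / np.maximum(union, 1e-300), 1.0)
    return 1.0 - sim


def nearest_neighbors(
    queries: Sequence[MoleculeRecord],
    pool: Sequence[MoleculeRecord],
    k: int = 3,
    exclude_ids: Iterable[str] = (),
) -> list[MoleculeRecord]:
    """Union of the k Tanimoto-nearest pool members of each query.

    Distances use ECFP6-2048 fingerprints; ties are broken by pool order;
    the union is deduplicated by id preserving first-discovery order.
    ``exclude_ids`` removes pool members (e.g. the queries themselves)
    before ranking.
    """
    if k < 1:
        raise ChemlibError("k must be >= 1")
    excluded = set(exclude_ids)
    eligible = [rec for rec in pool if rec.id not in excluded]
    if k > len(eligible):
        raise ChemlibError(f"k={k} exceeds eligible pool size {len(eligible)}")
    xq = fingerprint_matrix(queries, FingerprintKind.ECFP6_2048)
    xp = fingerprint_matrix(eligible, FingerprintKind.ECFP6_2048)
    dist = tanimoto_distance_matrix(xq, xp)
    chosen: list[MoleculeRecord] = []
    seen: set[str] = set()
    for qi in range(len(queries)):
        order = np.argsort(dist[qi], kind="stable")[:k]
        for pi in order:
            rec = eligible[int(pi)]
            if rec.id not in seen:
                seen.add(rec.id)
                chosen.append(rec)
    return chosen


def read_library(path: str | Path) -> list[MoleculeRecord]:
    """Read a library from CSV (``id,smiles[,source_tag]``) or ``.smi``.

    The ``.smi`` dialect is whitespace-separated ``smiles id`` per line.
    """
    path = Path(path)
    records: list[MoleculeRecord] = []
    if path.suffix.lower() == ".smi":
        for i, line in enumerate(path.read_text().splitlines()):
            parts = line.split()
            if not parts:
                continue
            smiles = parts[0]
            mol_id = parts[1] if len(parts) > 1 else f"mol{i}"
            records.append(MoleculeRecord.from_smiles(mol_id, smiles))
        return records
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "id" not in reader.fieldnames:
            raise ChemlibError(f"{path}: expected CSV header with id,smiles")
        for row in reader:
            tag = SourceTag(row.get("source_tag") or "synthetic")
            records.append(
                MoleculeRecord.from_smiles(row["id"], row["smiles"], source_tag=tag)
            )
    return records


def write_library(records: Sequence[MoleculeRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "smiles", "source_tag"])
        for rec in records:
            writer.writerow([rec.id, rec.smiles, rec.source_tag.value])
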