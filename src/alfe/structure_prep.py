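"""Docking-pose filter cascades, representative-frame selection, atom mapping.

The docking engines themselves are out of scope: pose tables arrive as data
(score, clash component, RMSD columns) and are filtered with the inclusive
thresholds of the two-stage cascade.  Representative-frame selection and the
distance-constrained maximum-common-substructure atom mapping operate on
plain coordinate arrays in Angstrom.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import rdFMCS

from .chemlib import ChemlibError, mol_from_smiles

logger = logging.getLogger(__name__)

# Inclusive filter thresholds of the two-stage docking cascade.
RMSD_INDOLE_MAX = 5.0   # Angstrom, template-free stage
SCORE_MAX = -6.0        # docking score, both stages (lower is better)
RMSD_MURCKO_MAX = 4.0   # Angstrom, template stage
CLASH_MAX = 0.5         # clash score component, template stage
DEFAULT_DMAX = 1.1      # Angstrom, atom-mapping distance cap


class AtomRole(str, Enum):
    LIGAND_HEAVY = "ligand_heavy"
    PROTEIN_CALPHA = "protein_calpha"
    OTHER = "other"


class RmsdField(str, Enum):
    INDOLE = "indole"
    MURCKO = "murcko"


@dataclass
class DockedPoseRecord:
    """One docked pose of one molecule; RMSDs are to a reference pose."""

    molecule_id: str
    pose_id: int
    docking_score: float
    clash_component: float = 0.0
    rmsd_indole: float | None = None
    rmsd_murcko: float | None = None
    coords: pd.DataFrame | None = None  # columns atom_label,x,y,z (Angstrom)

    def rmsd(self, which: RmsdField) -> float | None:
        return self.rmsd_indole if which is RmsdField.INDOLE else self.rmsd_murcko


@dataclass
class ToyTrajectory:
    """Frames x atoms x xyz coordinate stack with per-atom roles."""

    frames: np.ndarray  # (n_frames, n_atoms, 3), Angstrom
    atom_roles: Sequence[AtomRole]

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[1] != len(self.atom_roles):
            raise ValueError("atom_roles length must match atom count")


@dataclass
class AtomMapping:
    """Pairs of (reference, target) heavy-atom indices within a distance cap."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    max_pair_distance: float = DEFAULT_DMAX

    def __len__(self) -> int:
        return len(self.pairs)


def best_pose_per_molecule(
    poses: Sequence[DockedPoseRecord], rmsd_field: RmsdField | str
) -> list[DockedPoseRecord]:
    """Keep one pose per molecule: minimal named RMSD, then better score, then
    lower pose id.  Molecules whose poses all lack the RMSD are dropped with a
    logged reason."""
    which = RmsdField(rmsd_field)
    by_mol: dict[str, list[DockedPoseRecord]] = {}
    order: list[str] = []
    for pose in poses:
        if pose.molecule_id not in by_mol:
            order.append(pose.molecule_id)
        by_mol.setdefault(pose.molecule_id, []).append(pose)
    best: list[DockedPoseRecord] = []
    for mol_id in order:
        candidates = [p for p in by_mol[mol_id] if p.rmsd(which) is not None]
        if not candidates:
            logger.info("molecule %s: no pose carries rmsd_%s", mol_id, which.value)
            continue
        best.append(
            min(candidates, key=lambda p: (p.rmsd(which), p.docking_score, p.pose_id))
        )
    return best


def stage1_filter(
    best_poses: Sequence[DockedPoseRecord],
    rmsd_indole_max: float = RMSD_INDOLE_MAX,
    score_max: float = SCORE_MAX,
) -> list[str]:
    """Template-free stage: retain molecules with RMSD_indole <= 5 A and
    docking score <= -6 (both boundaries inclusive)."""
    return [
        p.molecule_id
        for p in best_poses
        if p.rmsd_indole is not None
        and p.rmsd_indole <= rmsd_indole_max
        and p.docking_score <= score_max
    ]


def stage2_filter(
    best_poses: Sequence[DockedPoseRecord],
    rmsd_murcko_max: float = RMSD_MURCKO_MAX,
    score_max: float = SCORE_MAX,
    clash_max: float = CLASH_MAX,
) -> list[str]:
    """Template stage: retain molecules with RMSD_Murcko <= 4 A, docking score
    <= -6 and clash component <= 0.5 (all inclusive)."""
    return [
        p.molecule_id
        for p in best_poses
        if p.rmsd_murcko is not None
        and p.rmsd_murcko <= rmsd_murcko_max
        and p.docking_score <= score_max
        and p.clash_component <= clash_max
    ]


def representative_frame(traj: ToyTrajectory, discard_fraction: float = 0.1) -> int:
    """Index of the retained frame closest (RMSD, no superposition) to the
    average structure over ligand heavy atoms and protein C-alpha atoms.

    The leading ``discard_fraction`` of frames is treated as equilibration and
    excluded both from the average and from the candidates.  Ties go to the
    earliest frame; the returned index is in original frame numbering.
    """
    if not 0.0 <= discard_fraction < 1.0:
        raise ValueError("discard_fraction must be in [0, 1)")
    n_frames = traj.frames.shape[0]
    start = int(math.floor(discard_fraction * n_frames))
    if start >= n_frames:
        raise ValueError("no frames remain after discard")
    mask = np.array(
        [role in (AtomRole.LIGAND_HEAVY, AtomRole.PROTEIN_CALPHA) for role in traj.atom_roles]
    )
    if not mask.any():
        raise ValueError("trajectory has no ligand-heavy or C-alpha atoms")
    retained = traj.frames[start:, mask, :]
    average = retained.mean(axis=0)
    rmsd = np.sqrt(((retained - average) ** 2).sum(axis=2).mean(axis=1))
    return start + int(np.argmin(rmsd))


def _heavy_coords(coords: np.ndarray, mol: Chem.Mol) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    if coords.shape != (mol.GetNumAtoms(), 3):
        raise ValueError(
            f"coords shape {coords.shape} does not cover the "
            f"{mol.GetNumAtoms()} heavy atoms"
        )
    return coords


def map_atoms(
    ref_smiles: str,
    ref_coords: np.ndarray,
    target_smiles: str,
    target_coords: np.ndarray,
    dmax: float = DEFAULT_DMAX,
    timeout_s: int = 60,
) -> AtomMapping:
    """Distance-constrained maximum-common-substructure atom mapping.

    A connected MCS (element- and bond-order-matched) is found between the two
    molecules; candidate substructure embeddings on both sides are paired and
    the embedding pair retaining the most atom pairs within ``dmax`` Angstrom
    wins.  Hydrogens never enter (SMILES parse is heavy-atom only).  An empty
    mapping is a valid result and signals a fully decoupled transformation.
    """
    ref = mol_from_smiles(ref_smiles)
    target = mol_from_smiles(target_smiles)
    ref_xyz = _heavy_coords(ref_coords, ref)
    tgt_xyz = _heavy_coords(target_coords, target)

    params = rdFMCS.MCSParameters()
    params.AtomTyper = rdFMCS.AtomCompare.CompareElements
    params.BondTyper = rdFMCS.BondCompare.CompareOrder
    params.Timeout = timeout_s
    mcs = rdFMCS.FindMCS([ref, target], params)
    if mcs.canceled:
        logger.warning("MCS search hit the %d s timeout", timeout_s)
    if not mcs.smartsString or mcs.numAtoms == 0:
        return AtomMapping(pairs=[], max_pair_distance=dmax)
    query = Chem.MolFromSmarts(mcs.smartsString)
    if query is None:  # pragma: no cover - rdkit always parses its own SMARTS
        raise ChemlibError(f"MCS produced unusable SMARTS {mcs.smartsString!r}")

    ref_matches = ref.GetSubstructMatches(query, uniquify=False, maxMatches=500)
    tgt_matches = target.GetSubstructMatches(query, uniquify=False, maxMatches=500)
    best_pairs: list[tuple[int, int]] = []
    for rm, tm in itertools.islice(itertools.product(ref_matches, tgt_matches), 50000):
        pairs = [
            (int(ri), int(ti))
            for ri, ti in zip(rm, tm)
            if np.linalg.norm(ref_xyz[ri] - tgt_xyz[ti]) <= dmax
        ]
        if len(pairs) > len(best_pairs):
            best_pairs = pairs
    mapping = AtomMapping(pairs=sorted(best_pairs), max_pair_distance=dmax)
    _validate_mapping(mapping, ref_xyz, tgt_xyz)
    return mapping


def _validate_mapping(
    mapping: AtomMapping, ref_xyz: np.ndarray, tgt_xyz: np.ndarray
) -> None:
    ref_side = [r for r, _ in mapping.pairs]
    tgt_side = [t for _, t in mapping.pairs]
    assert len(set(ref_side)) == len(ref_side), "duplicate reference atom in mapping"
    assert len(set(tgt_side)) == len(tgt_side), "duplicate target atom in mapping"
    assert len(mapping.pairs) <= min(len(ref_xyz), len(tgt_xyz))
    for r, t in mapping.pairs:
        assert np.linalg.norm(ref_xyz[r] - tgt_xyz[t]) <= mapping.max_pair_distance + 1e-9


def read_pose_table(path) -> list[DockedPoseRecord]:
    """Read a docked-pose table from CSV.

    Expected columns: ``molecule_id,pose_id,docking_score`` and optionally
    ``clash_component,rmsd_indole,rmsd_murcko``; empty cells are null RMSDs.
    """
    df = pd.read_csv(path)
    poses = []
    for row in df.itertuples(index=False):
        poses.append(
            DockedPoseRecord(
                molecule_id=str(row.molecule_id),
                pose_id=int(row.pose_id),
                docking_score=float(row.docking_score),
                clash_component=float(getattr(row, "clash_component", 0.0) or 0.0),
                rmsd_indole=_maybe_float(getattr(row, "rmsd_indole", None)),
                rmsd_murcko=_maybe_float(getattr(row, "rmsd_murcko", None)),
            )
        )
    return poses


def write_pose_table(poses: Sequence[DockedPoseRecord], path) -> None:
    rows = [
        {
            "molecule_id": p.molecule_id,
            "pose_id": p.pose_id,
            "docking_score": p.docking_score,
            "clash_component": p.clash_component,
            "rmsd_indole": p.rmsd_indole,
            "rmsd_murcko": p.rmsd_murcko,
        }
        for p in poses
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _maybe_float(value) -> float | None:
    if value is None:
        return None
    value = float(value)
    return None if math.isnan(value) else value
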