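"""Synthetic inputs with the statistical structure the workflow assumes.

Every expensive external stage (vendor library, docking, MD/TI simulation,
binding assay) has a generator here so the whole pipeline runs at desk scale
with known ground truth:

* an analog-library enumerator decorating a scaffold with substituents,
* an additive group-contribution affinity oracle (base dG plus one term per
  substituent plus Gaussian noise, seeded per molecule),
* a mock docking-table generator whose scores track true affinity and whose
  RMSD/clash columns control the filter pass fraction,
* a gradient-series generator producing AR(1)-correlated dU/dlambda samples
  around a polynomial mean curve calibrated so that quadrature over the
  lambda-schedule reproduces a requested free energy exactly, with an
  optional exponentially decaying equilibration transient.

All generators are bit-reproducible for fixed seeds.
"""

from __future__ import annotations

import itertools
import math
import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chemlib import ChemlibError, MoleculeRecord, SourceTag
from .structure_prep import DockedPoseRecord
from .ti import GradientSeries, LambdaSchedule, Leg

DEFAULT_NOISE_SD = 0.5  # kcal/mol, comparable to a TI stderr


class SynthError(ValueError):
    """Raised for invalid generator specifications."""


@dataclass
class SyntheticOracleSpec:
    """Additive group-contribution affinity landscape with Gaussian noise."""

    base_dg: float = -5.0  # kcal/mol
    group_contributions: Mapping[str, float] = field(default_factory=dict)
    noise_sd: float = DEFAULT_NOISE_SD
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise SynthError("noise_sd must be >= 0")


@dataclass
class GradientProfileSpec:
    """Mean-curve + noise model for one transformation's gradient series.

    ``curve_coeffs[leg]`` are polynomial coefficients (ascending powers) of
    the mean dU/dlambda curve; :func:`calibrated_profile` shifts the constant
    term so that quadrature over the schedule hits a target exactly.
    """

    curve_coeffs: Mapping[Leg, Sequence[float]]
    noise_sd: float = 1.0  # kcal/mol per sample
    autocorrelation_time: float = 5.0  # samples
    transient_amplitude: float = 0.0  # kcal/mol at t=0
    transient_length: float = 0.0  # fraction of the series
    seed: int = 0

    def mean_curve(self, leg: Leg, lam: float) -> float:
        return float(np.polynomial.polynomial.polyval(lam, np.asarray(self.curve_coeffs[leg], float)))


def _molecule_rng(seed: int, mol_id: str) -> np.random.Generator:
    """Per-molecule reproducible stream, independent of query order."""
    return np.random.default_rng((seed ^ zlib.crc32(mol_id.encode())) & 0x7FFFFFFF)


def generate_analog_library(
    scaffold: str,
    substituent_sets: Sequence[Sequence[str]],
    n_max: int = 1000,
    seed: int = 0,
    id_prefix: str = "syn",
) -> list[MoleculeRecord]:
    """Enumerate analogs of a scaffold with marked attachment points.

    ``scaffold`` is a SMILES with dummy atoms ``[*:1] ... [*:k]``; the i-th
    substituent set lists fragment SMILES each carrying the matching
    ``[*:i]`` dummy.  The full product is enumerated, or sampled without
    replacement down to ``n_max`` with the given seed.  Records carry their
    substituent labels for the group-contribution oracle.
    """
    scaffold_mol = Chem.MolFromSmiles(scaffold)
    if scaffold_mol is None:
        raise SynthError(f"scaffold does not parse: {scaffold!r}")
    for site, frags in enumerate(substituent_sets, start=1):
        for frag in frags:
            if Chem.MolFromSmiles(frag) is None:
                raise SynthError(f"invalid fragment {frag!r} at site {site}")

    combos = list(itertools.product(*[range(len(s)) for s in substituent_sets]))
    if len(combos) > n_max:
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(combos), size=n_max, replace=False)
        combos = [combos[int(i)] for i in sorted(picked)]

    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    for idx, combo in enumerate(combos):
        combined = scaffold_mol
        labels = []
        for site, frag_idx in enumerate(combo, start=1):
            frag = Chem.MolFromSmiles(substituent_sets[site - 1][frag_idx])
            combined = Chem.CombineMols(combined, frag)
            labels.append(f"R{site}:{substituent_sets[site - 1][frag_idx]}")
        product = Chem.molzip(combined)
        Chem.SanitizeMol(product)
        smiles = Chem.MolToSmiles(product)
        if smiles in seen:
            continue
        seen.add(smiles)
        records.append(
            MoleculeRecord.from_smiles(
                f"{id_prefix}{idx:05d}", smiles,
                source_tag=SourceTag.SYNTHETIC, substituents=tuple(labels),
            )
        )
    return records


def affinity_oracle(record: MoleculeRecord, spec: SyntheticOracleSpec) -> float:
    """Ground-truth dG: base + sum of substituent contributions + noise.

    The noise draw is seeded per molecule id, so repeated queries of one
    molecule return the identical value.
    """
    if record.substituents is None:
        raise SynthError(f"record {record.id} carries no substituent labels")
    total = spec.base_dg
    for label in record.substituents:
        if label not in spec.group_contributions:
            raise SynthError(f"unknown substituent label {label!r}")
        total += spec.group_contributions[label]
    if spec.noise_sd > 0:
        total += float(_molecule_rng(spec.seed, record.id).normal(0.0, spec.noise_sd))
    return total


def true_affinity(record: MoleculeRecord, spec: SyntheticOracleSpec) -> float:
    """Noise-free ground truth (for enrichment scoring in tests/reports)."""
    return affinity_oracle(
        record,
        SyntheticOracleSpec(
            base_dg=spec.base_dg,
            group_contributions=spec.group_contributions,
            noise_sd=0.0,
            seed=spec.seed,
        ),
    )


def mock_docking(
    records: Sequence[MoleculeRecord],
    oracle_spec: SyntheticOracleSpec,
    seed: int = 0,
    pass_fraction: float = 0.8,
    score_scale: float = 1.0,
    score_noise_sd: float = 0.0,
    score_offset: float = -2.0,
) -> list[DockedPoseRecord]:
    """Three poses per molecule with affinity-linked scores.

    The docking score of the best pose is ``score_scale * true_dg +
    score_offset + noise`` (the constant offset keeps typical scores below
    the -6 retention gate without disturbing the affinity ranking); RMSD and
    clash columns are drawn so that approximately ``pass_fraction`` of
    molecules pass both stage filters.
    """
    rng = np.random.default_rng(seed)
    poses: list[DockedPoseRecord] = []
    for rec in records:
        truth = true_affinity(rec, oracle_spec)
        passes = rng.random() < pass_fraction
        for pose_id in range(3):
            score = score_scale * truth + score_offset + (
                rng.normal(0.0, score_noise_sd) if score_noise_sd > 0 else 0.0
            )
            score += 0.4 * pose_id  # later poses score slightly worse
            if passes:
                rmsd_i = rng.uniform(0.5, 4.5) + pose_id
                rmsd_m = rng.uniform(0.5, 3.5) + pose_id
                clash = rng.uniform(0.0, 0.45)
            else:
                # force a geometry violation on every pose
                rmsd_i = rng.uniform(5.5, 9.0) + pose_id
                rmsd_m = rng.uniform(4.5, 8.0) + pose_id
                clash = rng.uniform(0.6, 2.0)
            poses.append(
                DockedPoseRecord(
                    molecule_id=rec.id,
                    pose_id=pose_id,
                    docking_score=float(score),
                    clash_component=float(clash),
                    rmsd_indole=float(rmsd_i),
                    rmsd_murcko=float(rmsd_m),
                )
            )
    return poses


def calibrated_profile(
    targets: Mapping[Leg, float],
    schedule: LambdaSchedule,
    base_coeffs: Sequence[float] = (0.0, 4.0, -4.0),
    **kwargs,
) -> GradientProfileSpec:
    """Build a profile whose quadrature equals each leg's target exactly.

    The base polynomial sets the curve shape; its constant term is shifted by
    (target - quadrature(base)), which is exact because the quadrature of a
    constant is that constant.
    """
    coeffs: dict[Leg, tuple[float, ...]] = {}
    nodes = np.asarray(schedule.nodes)
    weights = np.asarray(schedule.weights)
    base = np.asarray(base_coeffs, float)
    quad = float(np.dot(weights, np.polynomial.polynomial.polyval(nodes, base)))
    for leg, target in targets.items():
        shifted = base.copy()
        shifted[0] += float(target) - quad
        coeffs[Leg(leg)] = tuple(shifted)
    return GradientProfileSpec(curve_coeffs=coeffs, **kwargs)


class GradientSampler:
    """Stateful AR(1) gradient stream for one (leg, lambda) window.

    Successive ``draw(n)`` calls continue the same autocorrelated process
    and transient clock, emulating a simulation that is extended in place.
    The transient decays as amplitude * exp(-t / tau_tr) with
    tau_tr = transient_length * n_nominal / 2, so the transient is still
    ~0.14 of its amplitude at the stated fraction of the series and
    meaningfully perturbs everything before it.
    """

    def __init__(
        self,
        spec: GradientProfileSpec,
        leg: Leg,
        lambda_value: float,
        lambda_index: int,
        n_nominal: int,
        seed_offset: int = 0,
    ) -> None:
        self.mean = spec.mean_curve(leg, lambda_value)
        self.noise_sd = spec.noise_sd
        tau = max(spec.autocorrelation_time, 1e-9)
        self.phi = math.exp(-1.0 / tau)
        self.innov_sd = spec.noise_sd * math.sqrt(max(1.0 - self.phi**2, 1e-12))
        self.transient_amplitude = spec.transient_amplitude
        if spec.transient_length > 0:
            self.transient_tau = spec.transient_length * n_nominal / 2.0
        else:
            self.transient_tau = None
        leg_tag = 0 if leg is Leg.COMPLEX else 1
        self.rng = np.random.default_rng(
            (spec.seed * 1000003 + leg_tag * 101 + lambda_index * 7 + seed_offset)
            & 0x7FFFFFFF
        )
        self._state = float(self.rng.normal(0.0, self.noise_sd)) if self.noise_sd > 0 else 0.0
        self._t = 0

    def draw(self, n: int) -> np.ndarray:
        out = np.empty(n)
        for i in range(n):
            if self.noise_sd > 0:
                self._state = self.phi * self._state + float(
                    self.rng.normal(0.0, self.innov_sd)
                )
            value = self.mean + self._state
            if self.transient_tau is not None and self.transient_amplitude != 0.0:
                value += self.transient_amplitude * math.exp(-self._t / self.transient_tau)
            out[i] = value
            self._t += 1
        return out


def synth_gradient_series(
    spec: GradientProfileSpec,
    schedule: LambdaSchedule,
    n_samples: int = 500,
    dt: float = 0.005,
    replicate_id: int = 0,
) -> list[GradientSeries]:
    """Generate one gradient series per (leg, lambda-node)."""
    out: list[GradientSeries] = []
    for leg in (Leg.COMPLEX, Leg.SOLVENT):
        if leg not in spec.curve_coeffs:
            continue
        for i, lam in enumerate(schedule.nodes):
            sampler = GradientSampler(
                spec, leg, lam, i, n_nominal=n_samples, seed_offset=replicate_id * 9973
            )
            out.append(
                GradientSeries(
                    leg=leg,
                    lambda_index=i,
                    samples=sampler.draw(n_samples),
                    dt=dt,
                    replicate_id=replicate_id,
                )
            )
    return out


DEFAULT_SCAFFOLD = "O=C(N[*:1])C(=O)Nc1ccc([*:2])cc1"
DEFAULT_SUBSTITUENTS: tuple[tuple[str, ...], ...] = (
    (
        "[*:1]C", "[*:1]CC", "[*:1]CCC", "[*:1]CCCC", "[*:1]C(C)C",
        "[*:1]C(C)(C)C", "[*:1]CCO", "[*:1]CCN", "[*:1]CCF", "[*:1]CC#N",
        "[*:1]c1ccccc1", "[*:1]Cc1ccccc1", "[*:1]CCc1ccccc1",
        "[*:1]c1ccccn1", "[*:1]c1cccnc1", "[*:1]Cc1ccco1", "[*:1]Cc1cccs1",
        "[*:1]C1CC1", "[*:1]C1CCC1", "[*:1]C1CCCC1", "[*:1]C1CCCCC1",
        "[*:1]CC1CC1", "[*:1]C1CCOCC1", "[*:1]C1CCNCC1", "[*:1]CC(F)(F)F",
        "[*:1]CCOC", "[*:1]CC(C)C", "[*:1]CCCl", "[*:1]Cc1ccncc1",
        "[*:1]Cc1ccc(F)cc1", "[*:1]Cc1ccc(C)cc1", "[*:1]Cc1ccc(OC)cc1",
        "[*:1]CCCO",
    ),
    (
        "[*:2][H]", "[*:2]F", "[*:2]Cl", "[*:2]Br", "[*:2]C", "[*:2]CC",
        "[*:2]CCC", "[*:2]C(C)C", "[*:2]O", "[*:2]OC", "[*:2]OCC",
        "[*:2]C(F)(F)F", "[*:2]OC(F)(F)F", "[*:2]C#N", "[*:2]N", "[*:2]NC",
        "[*:2]N(C)C", "[*:2]C(=O)C", "[*:2]C(=O)OC", "[*:2]C(=O)N",
        "[*:2]S(C)(=O)=O", "[*:2]SC", "[*:2]CO", "[*:2]CCO", "[*:2]CF",
        "[*:2]C(F)F", "[*:2]c1ccccc1", "[*:2]c1ccncc1", "[*:2]C1CC1",
        "[*:2]OC1CC1", "[*:2]CC#N", "[*:2]OCC(F)(F)F", "[*:2]C(C)(C)C",
    ),
)


def default_oracle_spec(seed: int = 0, noise_sd: float = DEFAULT_NOISE_SD) -> SyntheticOracleSpec:
    """Landscape over the default oxamide analog library.

    Contributions are spread over roughly [-1.5, +1.0] kcal/mol per site so
    the best analogs sit ~3 kcal/mol below the base, mimicking the dynamic
    range of a hit-optimization series.
    """
    rng = np.random.default_rng(seed + 77)
    contributions: dict[str, float] = {}
    for site, frags in enumerate(DEFAULT_SUBSTITUENTS, start=1):
        values = rng.uniform(-1.5, 1.0, size=len(frags))
        for frag, val in zip(frags, values):
            contributions[f"R{site}:{frag}"] = float(val)
    return SyntheticOracleSpec(
        base_dg=-5.5, group_contributions=contributions, noise_sd=noise_sd, seed=seed
    )


def default_library(n_max: int = 100, seed: int = 0) -> list[MoleculeRecord]:
    return generate_analog_library(
        DEFAULT_SCAFFOLD, DEFAULT_SUBSTITUENTS, n_max=n_max, seed=seed
    )
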