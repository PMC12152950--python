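"""Perturbation-map thermodynamics: RBFE -> ABFE conversion and bookkeeping.

A perturbation map is a directed graph whose edges carry computed relative
binding free energies (ddG, kcal/mol) between a reference and a target
ligand.  Anchoring one or more nodes to experimentally known absolute binding
free energies converts every reachable node by summing signed edge values
along the unique tree path (the production map is a tree; cycles, when
present, are reported through a closure check rather than refit).

Also provides the dissociation-constant conversion dG = RT ln(KD / 1 M) at
298 K and the mean-absolute-error metric used to compare computed and
experimental affinities.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

GAS_CONSTANT_KCAL = 1.987204e-3  # kcal / (mol K)
STANDARD_TEMPERATURE_K = 298.0
STANDARD_CONC_M = 1.0


class ThermoError(ValueError):
    """Raised for malformed perturbation maps or conversions."""


@dataclass
class AffinityRecord:
    """Absolute binding free energy of one ligand, with provenance."""

    ligand_id: str
    dg_abs: float  # kcal/mol
    stderr: float = 0.0
    provenance: str = "anchor"
    kd: float | None = None  # molar


class PerturbationMap:
    """Directed graph of reference -> target RBFE edges."""

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    def add_node(self, ligand_id: str) -> None:
        self.graph.add_node(ligand_id)

    def add_edge(
        self, reference_id: str, target_id: str, ddg: float, stderr: float = 0.0
    ) -> None:
        self.graph.add_edge(reference_id, target_id, ddg=float(ddg), stderr=float(stderr))

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        return [
            (u, v, d["ddg"], d["stderr"]) for u, v, d in self.graph.edges(data=True)
        ]

    @classmethod
    def from_csv(cls, path: str | Path) -> "PerturbationMap":
        """CSV dialect: ``reference_id,target_id,ddg_kcal,stderr_kcal``."""
        df = pd.read_csv(path)
        pmap = cls()
        for row in df.itertuples(index=False):
            pmap.add_edge(
                str(row.reference_id),
                str(row.target_id),
                float(row.ddg_kcal),
                float(getattr(row, "stderr_kcal", 0.0) or 0.0),
            )
        return pmap

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {"reference_id": u, "target_id": v, "ddg_kcal": g, "stderr_kcal": s}
                for u, v, g, s in self.edges
            ]
        ).to_csv(path, index=False)

    def to_abfe(
        self, anchors: Sequence[tuple[str, float]], provenance: str | dict[str, str] = "pre_AL"
    ) -> list[AffinityRecord]:
        """Convert RBFE edges to absolute binding free energies.

        Each node takes the value of its nearest anchor (by unweighted path
        length on the undirected skeleton) plus the signed ddG sum along that
        path; edges traversed against their direction contribute -ddG.  The
        stderr accumulates in quadrature along the path.  Unreachable nodes
        raise; a node whose multiple-anchor values disagree beyond 3 sigma is
        reported with a warning and keeps its nearest-anchor value.
        """
        if not anchors:
            raise ThermoError("at least one anchor is required")
        anchor_ids = {a for a, _ in anchors}
        missing = anchor_ids - set(self.graph.nodes)
        if missing:
            raise ThermoError(f"anchors absent from the map: {sorted(missing)}")
        und = self.graph.to_undirected(as_view=True)

        # per-anchor breadth-first signed path sums
        per_anchor: dict[str, dict[str, tuple[float, float, int]]] = {}
        for anchor_id, anchor_dg in anchors:
            values: dict[str, tuple[float, float, int]] = {
                anchor_id: (float(anchor_dg), 0.0, 0)
            }
            for u, v in nx.bfs_edges(und, anchor_id):
                dg_u, var_u, depth = values[u]
                if self.graph.has_edge(u, v):
                    data = self.graph.edges[u, v]
                    step = data["ddg"]
                else:  # traversed against edge direction
                    data = self.graph.edges[v, u]
                    step = -data["ddg"]
                values[v] = (dg_u + step, var_u + data["stderr"] ** 2, depth + 1)
            per_anchor[anchor_id] = values

        records: list[AffinityRecord] = []
        orphans: list[str] = []
        prov_map = provenance if isinstance(provenance, dict) else {}
        for node in self.graph.nodes:
            hits = [
                (depth, aid, dg, var)
                for aid, values in per_anchor.items()
                for n, (dg, var, depth) in values.items()
                if n == node
            ]
            if not hits:
                orphans.append(node)
                continue
            hits.sort(key=lambda h: (h[0], h[1]))
            depth, aid, dg, var = hits[0]
            for d2, aid2, dg2, var2 in hits[1:]:
                sigma = math.sqrt(var + var2)
                if sigma > 0 and abs(dg - dg2) > 3 * sigma:
                    logger.warning(
                        "node %s: anchors %s and %s disagree (%.3f vs %.3f kcal/mol)",
                        node, aid, aid2, dg, dg2,
                    )
            prov = (
                "anchor"
                if node in anchor_ids
                else prov_map.get(node, provenance if isinstance(provenance, str) else "pre_AL")
            )
            records.append(
                AffinityRecord(
                    ligand_id=node, dg_abs=dg, stderr=math.sqrt(var), provenance=prov
                )
            )
        if orphans:
            raise ThermoError(f"nodes unreachable from any anchor: {sorted(orphans)}")
        return records

    def cycle_closure(self) -> list[tuple[list[str], float]]:
        """Signed ddG sum around each independent cycle; trees return []."""
        und = self.graph.to_undirected(as_view=True)
        out: list[tuple[list[str], float]] = []
        for cycle in nx.cycle_basis(und):
            total = 0.0
            for u, v in zip(cycle, cycle[1:] + cycle[:1]):
                if self.graph.has_edge(u, v):
                    total += self.graph.edges[u, v]["ddg"]
                else:
                    total -= self.graph.edges[v, u]["ddg"]
            out.append((cycle, total))
        return out


def kd_to_dg(kd: float, temperature_k: float = STANDARD_TEMPERATURE_K) -> float:
    """dG = R T ln(KD / 1 M), kcal/mol; KD in molar."""
    if kd <= 0:
        raise ThermoError("KD must be positive")
    return GAS_CONSTANT_KCAL * temperature_k * math.log(kd / STANDARD_CONC_M)


def dg_to_kd(dg: float, temperature_k: float = STANDARD_TEMPERATURE_K) -> float:
    """Inverse of :func:`kd_to_dg`: KD = exp(dG / RT) M."""
    return STANDARD_CONC_M * math.exp(dg / (GAS_CONSTANT_KCAL * temperature_k))


def mae(computed: Sequence[float], experimental: Sequence[float]) -> float:
    """Mean absolute error between computed and experimental values."""
    if len(computed) != len(experimental) or len(computed) == 0:
        raise ThermoError("computed and experimental must have equal nonzero length")
    return float(
        sum(abs(c - e) for c, e in zip(computed, experimental)) / len(computed)
    )


def hit_rate_percent(n_confirmed: int, n_tested: int) -> float:
    """Confirmed-binder rate as a percentage of tested molecules."""
    if n_tested <= 0:
        raise ThermoError("n_tested must be positive")
    if not 0 <= n_confirmed <= n_tested:
        raise ThermoError("n_confirmed must lie in [0, n_tested]")
    return 100.0 * n_confirmed / n_tested


def read_anchors(path: str | Path) -> list[tuple[str, float]]:
    """Anchors CSV: ``ligand_id,dg_abs_kcal``."""
    df = pd.read_csv(path)
    return [(str(r.ligand_id), float(r.dg_abs_kcal)) for r in df.itertuples(index=False)]


def write_affinities(records: Iterable[AffinityRecord], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "ligand_id": r.ligand_id,
                "dg_abs_kcal": round(r.dg_abs, 2),
                "stderr_kcal": round(r.stderr, 2),
                "provenance": r.provenance,
                "kd_molar": dg_to_kd(r.dg_abs),
            }
            for r in records
        ]
    ).to_csv(path, index=False)
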