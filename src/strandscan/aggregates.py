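"""Oligomer identification and orientational order of peptide aggregates.

Self-assembling peptides pass through transient oligomeric aggregates
("molten globules") before maturing into fibrils.  Oligomers are detected
as connected components of the peptide centre-of-mass graph thresholded at
11 Angstrom (1.1 nm, the typical equatorial spacing of cross-beta
structures in fibre diffraction), and their internal order is scored with
the nematic order parameter P2 — the largest eigenvalue of the
orientational order tensor of the peptide end-to-end axes — together with
the radius of gyration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .contacts import pairwise_distances
from .topology import BackboneFrame, SystemTopology

__all__ = [
    "OligomerSet",
    "OrderReport",
    "OligomerOrder",
    "peptide_centers",
    "identify_oligomers",
    "nematic_p2",
    "radius_of_gyration",
    "order_report",
]

DEFAULT_OLIGOMER_CUTOFF = 11.0  # Angstrom, = 1.1 nm


def peptide_centers(
    frame: BackboneFrame, topology: SystemTopology
) -> np.ndarray:
    """Centre of each peptide: unweighted mean of its backbone grains.

    Only backbone grains are available at this coarsening level, so the
    centre of mass reduces to their plain average.
    """
    centers = np.empty((topology.n_strands, 3))
    for s in range(topology.n_strands):
        centers[s] = frame.coordinates[topology.grains_of_strand(s)].mean(axis=0)
    return centers


@dataclass
class OligomerSet:
    """Distance-threshold connected components of peptide centres.

    ``components`` lists the oligomers (size >= 2) as sorted peptide-index
    tuples; unaggregated peptides appear in ``singletons``.
    """

    components: list[tuple[int, ...]]
    singletons: tuple[int, ...]
    cutoff: float
    time: float | None = None

    @property
    def n_oligomers(self) -> int:
        return len(self.components)

    @property
    def largest(self) -> int:
        return max((len(c) for c in self.components), default=1 if self.singletons else 0)


def identify_oligomers(
    centers: np.ndarray,
    cutoff: float = DEFAULT_OLIGOMER_CUTOFF,
    box: np.ndarray | None = None,
    time: float | None = None,
) -> OligomerSet:
    """Cluster peptide centres into oligomers.

    Two peptides are neighbours when their centre distance (minimum image
    if a box is given) is <= ``cutoff``; oligomers are the connected
    components of the resulting graph.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.ndim != 2 or centers.shape[1] != 3 or len(centers) == 0:
        raise ValueError("centers must be a non-empty (N, 3) array")
    d = pairwise_distances(centers, box)
    adjacency = (d <= cutoff)
    np.fill_diagonal(adjacency, False)
    n, labels = connected_components(
        csr_matrix(adjacency), directed=False, return_labels=True
    )
    groups: dict[int, list[int]] = {}
    for idx, lab in enumerate(labels):
        groups.setdefault(int(lab), []).append(idx)
    components = sorted(
        tuple(sorted(g)) for g in groups.values() if len(g) >= 2
    )
    singletons = tuple(
        sorted(g[0] for g in groups.values() if len(g) == 1)
    )
    return OligomerSet(components, singletons, cutoff, time)


def _axes(
    frame: BackboneFrame, topology: SystemTopology, members: Sequence[int]
) -> np.ndarray:
    axes = np.empty((len(members), 3))
    for row, m in enumerate(members):
        grains = topology.grains_of_strand(m)
        vec = frame.coordinates[grains[-1]] - frame.coordinates[grains[0]]
        norm = np.linalg.norm(vec)
        if norm == 0:
            raise ValueError(f"peptide {m} has a zero-length end-to-end axis")
        axes[row] = vec / norm
    return axes


def nematic_p2(
    frame: BackboneFrame, topology: SystemTopology, members: Sequence[int]
) -> float:
    """Nematic order parameter P2 of a set of peptides.

    Each peptide's molecular axis is the unit vector from its first to its
    last backbone grain.  P2 is the largest eigenvalue of the order tensor

        Q = (1/N) sum_m (3/2 u_m u_m^T - 1/2 I),

    1 for perfectly (anti)parallel axes, tending to 0 for an isotropic
    set.  Axis head-tail flips leave P2 unchanged.
    """
    if len(members) < 2:
        raise ValueError("P2 needs at least two peptides")
    u = _axes(frame, topology, members)
    Q = 1.5 * np.einsum("mi,mj->ij", u, u) / len(u) - 0.5 * np.eye(3)
    return float(np.linalg.eigvalsh(Q)[-1])


def radius_of_gyration(
    frame: BackboneFrame,
    topology: SystemTopology,
    members: Sequence[int],
) -> float:
    """Radius of gyration (Angstrom) of the member peptides' grains:
    root-mean-square distance from their unweighted centroid."""
    grains = np.concatenate(
        [topology.grains_of_strand(m) for m in members]
    )
    coords = frame.coordinates[grains]
    centroid = coords.mean(axis=0)
    return float(np.sqrt(((coords - centroid) ** 2).sum(axis=1).mean()))


@dataclass
class OligomerOrder:
    members: tuple[int, ...]
    size: int
    p2: float
    radius_of_gyration: float


@dataclass
class OrderReport:
    """Per-oligomer size, P2 and radius of gyration for one frame."""

    oligomers: list[OligomerOrder]
    time: float | None = None

    @property
    def mean_p2(self) -> float | None:
        if not self.oligomers:
            return None
        return float(np.mean([o.p2 for o in self.oligomers]))


def order_report(
    frame: BackboneFrame,
    topology: SystemTopology,
    oligomers: OligomerSet,
    min_size: int = 2,
) -> OrderReport:
    """Score every identified oligomer of at least ``min_size`` peptides."""
    rows = [
        OligomerOrder(
            members=c,
            size=len(c),
            p2=nematic_p2(frame, topology, c),
            radius_of_gyration=radius_of_gyration(frame, topology, c),
        )
        for c in oligomers.components
        if len(c) >= min_size
    ]
    return OrderReport(rows, oligomers.time)
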