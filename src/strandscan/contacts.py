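"""Beta-contacts and the system backbone contact (BB) matrix.

Two backbone grains on *different* strands form a beta-contact when their
distance falls in the typical inter-strand hydrogen-bond window of
cross-beta structures, 4.7-5.3 Angstrom.  The BB matrix collects these
binary contacts for every grain pair in the system; per-strand-pair
submatrices of it are what the shift-template matching operates on.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import UNASSIGNED, BackboneFrame, SystemTopology

__all__ = [
    "ContactRange",
    "BBMatrix",
    "beta_contact",
    "pairwise_distances",
    "build_bb_matrix",
    "pair_submatrix",
]


@dataclass(frozen=True)
class ContactRange:
    """Closed distance interval [r_min, r_max] (Angstrom) defining a
    beta-contact.  Defaults to the 4.7-5.3 A inter-strand spacing of
    cross-beta structures."""

    r_min: float = 4.7
    r_max: float = 5.3

    def __post_init__(self) -> None:
        if not 0 < self.r_min < self.r_max:
            raise ValueError(
                f"need 0 < r_min < r_max, got [{self.r_min}, {self.r_max}]"
            )


def beta_contact(r_ij: float, contact_range: ContactRange = ContactRange()) -> int:
    """Binary beta-contact indicator: 1 iff r_min <= r_ij <= r_max.

    Both bounds are inclusive; 4.70 A and 5.30 A count as contacts under
    the default range, 4.69 A and 5.31 A do not.
    """
    if r_ij < 0:
        raise ValueError(f"distance must be non-negative, got {r_ij}")
    return int(contact_range.r_min <= r_ij <= contact_range.r_max)


def pairwise_distances(
    coords: np.ndarray, box: np.ndarray | None = None
) -> np.ndarray:
    """All-pairs Euclidean distances, minimum-image under an orthorhombic
    box when one is given."""
    diff = coords[:, None, :] - coords[None, :, :]
    if box is not None:
        diff -= box * np.round(diff / box)
    return np.sqrt(np.einsum("ijk,ijk->ij", diff, diff))


@dataclass
class BBMatrix:
    """Binary system-wide beta-contact matrix over all grains.

    Symmetric, zero diagonal blocks for same-strand pairs: contacts are
    inter-strand by definition (covalent neighbours along a strand are the
    other lattice axis).
    """

    entries: np.ndarray
    topology: SystemTopology

    def __post_init__(self) -> None:
        e = np.asarray(self.entries, dtype=np.uint8)
        if e.ndim != 2 or e.shape[0] != e.shape[1]:
            raise ValueError("entries must be square")
        if e.shape[0] != self.topology.n_grains:
            raise ValueError("entry dimension does not match topology")
        self.entries = e

    @property
    def n_contacts(self) -> int:
        """Number of unordered contact pairs."""
        return int(self.entries.sum()) // 2


def build_bb_matrix(
    frame: BackboneFrame,
    topology: SystemTopology,
    contact_range: ContactRange = ContactRange(),
) -> BBMatrix:
    """Compute the BB matrix of a frame.

    Distances use the minimum-image convention when the frame carries a
    periodic box (orthorhombic only), plain Euclidean otherwise.  Grain
    pairs on the same strand — and grains excluded from the partition —
    never contribute entries.
    """
    if frame.n_grains != topology.n_grains:
        raise ValueError(
            f"frame has {frame.n_grains} grains, topology expects "
            f"{topology.n_grains}"
        )
    d = pairwise_distances(frame.coordinates, frame.box)
    strand = topology.strand_of_grain
    inter = (strand[:, None] != strand[None, :]) & (
        (strand != UNASSIGNED)[:, None] & (strand != UNASSIGNED)[None, :]
    )
    within = (d >= contact_range.r_min) & (d <= contact_range.r_max)
    return BBMatrix((within & inter).astype(np.uint8), topology)


def pair_submatrix(bb: BBMatrix, p: int, q: int) -> np.ndarray:
    """SL x SL contact submatrix for the strand pair (p, q).

    Rows follow the grains of p in in-strand order, columns those of q;
    ``pair_submatrix(bb, q, p)`` is the transpose.
    """
    if p == q:
        raise ValueError("strand pair requires two distinct strands")
    gp = bb.topology.grains_of_strand(p)
    gq = bb.topology.grains_of_strand(q)
    return bb.entries[np.ix_(gp, gq)]
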