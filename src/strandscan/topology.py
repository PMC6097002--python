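"""System topology: strands of backbone grains and per-frame coordinates.

A coarse-grained peptide system is described by one backbone grain per
residue.  Grains are stored in a flat array ordered by (strand, position);
the :class:`SystemTopology` records how many strands (``S``) of how many
grains each (``SL``, the strand length) the system contains, and
:func:`partition_strands` maps flat grain indices to (strand, position)
pairs while respecting chain breaks.

All coordinates are in Angstrom throughout the package; trajectory readers
convert on input.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "SystemTopology",
    "BackboneFrame",
    "partition_strands",
]

UNASSIGNED = -1


@dataclass(frozen=True)
class SystemTopology:
    """Division of a grain sequence into S strands of length SL.

    Parameters
    ----------
    n_strands:
        Number of strands S (>= 1).
    strand_length:
        Backbone grains per strand SL (>= 3; the triplet heuristic and the
        template matching need at least three positions).
    strand_of_grain:
        Flat array mapping each grain index to its strand, ``-1`` for
        grains left out of the partition (trailing residues, leftovers at
        chain breaks).
    labels:
        Optional per-strand identifiers (e.g. chain id + residue range).
    """

    n_strands: int
    strand_length: int
    strand_of_grain: np.ndarray
    labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.n_strands < 1:
            raise ValueError(f"n_strands must be >= 1, got {self.n_strands}")
        if self.strand_length < 3:
            raise ValueError(
                f"strand_length must be >= 3, got {self.strand_length}"
            )
        strand_of_grain = np.asarray(self.strand_of_grain, dtype=np.intp)
        object.__setattr__(self, "strand_of_grain", strand_of_grain)
        assigned = strand_of_grain[strand_of_grain != UNASSIGNED]
        counts = np.bincount(assigned, minlength=self.n_strands)
        if len(counts) != self.n_strands or not np.all(
            counts == self.strand_length
        ):
            raise ValueError(
                "strand_of_grain does not describe "
                f"{self.n_strands} strands of {self.strand_length} grains"
            )
        if self.labels and len(self.labels) != self.n_strands:
            raise ValueError("one label per strand required")

    @property
    def n_grains(self) -> int:
        """Total grains in the flat array (assigned or not)."""
        return len(self.strand_of_grain)

    def grains_of_strand(self, s: int) -> np.ndarray:
        """Flat grain indices of strand ``s`` in in-strand order."""
        if not 0 <= s < self.n_strands:
            raise IndexError(f"strand index {s} out of range")
        return np.flatnonzero(self.strand_of_grain == s)

    @classmethod
    def regular(
        cls,
        n_strands: int,
        strand_length: int,
        labels: Sequence[str] = (),
    ) -> "SystemTopology":
        """Topology for exactly ``n_strands * strand_length`` grains with no
        chain breaks (the common case for synthetic systems)."""
        assignment = np.repeat(np.arange(n_strands), strand_length)
        return cls(n_strands, strand_length, assignment, tuple(labels))


@dataclass
class BackboneFrame:
    """Backbone-grain coordinates for one frame.

    ``coordinates`` is an (N, 3) float array in Angstrom, ordered by
    (strand, position).  ``box`` holds the three orthorhombic box lengths in
    Angstrom, or ``None`` for a non-periodic system.  ``time`` is the
    simulation time in ns when the frame comes from a trajectory.
    """

    coordinates: np.ndarray
    box: np.ndarray | None = None
    time: float | None = None

    def __post_init__(self) -> None:
        coords = np.asarray(self.coordinates, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        self.coordinates = coords
        if self.box is not None:
            box = np.asarray(self.box, dtype=float).reshape(3)
            if not np.all(box > 0):
                raise ValueError(f"box lengths must be positive, got {box}")
            self.box = box

    @property
    def n_grains(self) -> int:
        return len(self.coordinates)


def partition_strands(
    n_grains: int,
    n_strands: int,
    strand_length: int,
    chain_breaks: Sequence[int] = (),
) -> np.ndarray:
    """Assign grains to strands consecutively, restarting at chain breaks.

    Grains are taken in flat order and grouped into blocks of
    ``strand_length``; strand ``s`` covers the s-th complete block.  A
    strand is never allowed to span a chain break: at each break the
    block assembly restarts, and any incomplete block (at a break or at
    the end) is left unassigned.

    Parameters
    ----------
    n_grains:
        Total number of grains available.
    n_strands, strand_length:
        Target division (S, SL).
    chain_breaks:
        Grain indices at which a chain ends (inclusive: the named grain is
        the last one of its chain).

    Returns
    -------
    numpy.ndarray
        Length-``n_grains`` integer array; entry g is the strand index of
        grain g, or ``-1`` if the grain is not part of any strand.

    Raises
    ------
    ValueError
        If ``n_strands * strand_length > n_grains``, or if the chain breaks
        make it impossible to place all ``n_strands`` strands.
    """
    S, SL = n_strands, strand_length
    if S * SL > n_grains:
        raise ValueError(
            f"cannot partition {n_grains} grains into {S} strands "
            f"of length {SL} ({S * SL} grains needed)"
        )
    ends = sorted(set(int(b) for b in chain_breaks))
    for b in ends:
        if not 0 <= b < n_grains:
            raise ValueError(f"chain break {b} outside grain range")
    # segment boundaries: [start, stop) runs of unbroken chain
    stops = [b + 1 for b in ends if b + 1 < n_grains] + [n_grains]
    assignment = np.full(n_grains, UNASSIGNED, dtype=np.intp)
    strand = 0
    start = 0
    for stop in stops:
        pos = start
        while strand < S and stop - pos >= SL:
            assignment[pos : pos + SL] = strand
            strand += 1
            pos += SL
        start = stop
        if strand == S:
            break
    if strand < S:
        raise ValueError(
            f"chain breaks leave room for only {strand} of {S} strands of "
            f"length {SL}; strand {strand} would have to cross a break"
        )
    return assignment
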