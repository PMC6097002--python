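"""Synthetic coordinate generators with known ground truth.

Three families of fixtures cover the analysis stages:

* :func:`make_ideal_sheet` — flat or twisted beta-sheets with a prescribed
  orientation and shift per adjacent strand pair, optionally jittered;
* :func:`make_random_gas` — well-separated randomly oriented peptides
  (no contacts, no oligomers);
* :func:`make_clustered_aggregate` — peptide clusters with designed
  membership for oligomer-recovery tests.

Geometry defaults follow cross-beta structure: 3.4 A rise per residue
along a strand and 4.8 A spacing between hydrogen-bonded strands, inside
the 4.7-5.3 A contact window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .contacts import ContactRange, build_bb_matrix
from .shifts import Alignment
from .topology import BackboneFrame, SystemTopology

__all__ = [
    "SheetSpec",
    "make_ideal_sheet",
    "make_random_gas",
    "make_clustered_aggregate",
]

DEFAULT_RISE = 3.4  # A per residue along a strand
DEFAULT_SPACING = 4.8  # A between adjacent hydrogen-bonded strands


@dataclass(frozen=True)
class SheetSpec:
    """Blueprint for an ideal beta-sheet.

    ``orientations`` and ``shifts`` give the designed alignment of each
    adjacent strand pair (a single value is broadcast to all
    ``n_strands - 1`` pairs).  ``twist_deg`` rotates each successive
    strand's axis about the stacking direction, emulating the saddle-like
    twist of real sheets; ``jitter`` adds truncated Gaussian noise.
    """

    n_strands: int
    strand_length: int
    orientations: str | Sequence[str] = "parallel"
    shifts: int | Sequence[int] = 0
    spacing: float = DEFAULT_SPACING
    rise: float = DEFAULT_RISE
    twist_deg: float = 0.0
    jitter: float = 0.0
    seed: int | None = None

    def pair_alignments(self) -> list[Alignment]:
        n_pairs = self.n_strands - 1
        orientations = (
            [self.orientations] * n_pairs
            if isinstance(self.orientations, str)
            else list(self.orientations)
        )
        shifts = (
            [self.shifts] * n_pairs
            if isinstance(self.shifts, (int, np.integer))
            else list(self.shifts)
        )
        if len(orientations) != n_pairs or len(shifts) != n_pairs:
            raise ValueError(
                f"need one orientation and shift per adjacent pair ({n_pairs})"
            )
        for o in orientations:
            if o not in ("parallel", "antiparallel"):
                raise ValueError(f"unknown orientation {o!r}")
        for k in shifts:
            if abs(int(k)) > self.strand_length - 3:
                raise ValueError(
                    f"shift {k} leaves fewer than 3 overlapping positions"
                )
        return [Alignment(o, int(k)) for o, k in zip(orientations, shifts)]

    def validate(self) -> None:
        if self.n_strands < 1 or self.strand_length < 3:
            raise ValueError("need n_strands >= 1 and strand_length >= 3")
        if self.spacing <= 0 or self.rise <= 0:
            raise ValueError("spacing and rise must be positive")
        if self.jitter < 0:
            raise ValueError("jitter must be non-negative")
        self.pair_alignments()


def _rotation_about_y(theta: float) -> np.ndarray:
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def make_ideal_sheet(
    spec: SheetSpec,
    contact_range: ContactRange = ContactRange(),
) -> tuple[BackboneFrame, SystemTopology, list[Alignment]]:
    """Build an ideal sheet and return (frame, topology, ground truth).

    Strand 0 runs along x; each subsequent strand is stacked ``spacing``
    apart along y and slid/reversed so that its contact pattern with the
    previous strand is exactly the designed (orientation, k) template.
    Twist rotates each strand's axis by ``s * twist_deg`` about the
    stacking axis.  Jitter displacements are truncated (iteratively
    shrunk) so the designed contact pattern is preserved exactly.

    The ground-truth list holds the designed alignment of pair
    (s, s+1) for each s, in the P-matrix convention for p < q.
    """
    spec.validate()
    S, SL = spec.n_strands, spec.strand_length
    alignments = spec.pair_alignments()

    # 1-D registry: scalar coordinate of grain i of strand s along the
    # common strand direction, and the direction sign of each strand.
    offsets = np.zeros(S)
    signs = np.ones(S, dtype=int)
    for s, al in enumerate(alignments, start=1):
        d_prev = signs[s - 1]
        if al.orientation == "parallel":
            signs[s] = d_prev
            # contact (i, i+k): off_q + (i+k)*rise*d = off_p + i*rise*d
            offsets[s] = offsets[s - 1] - al.shift * spec.rise * d_prev
        else:
            signs[s] = -d_prev
            # contact (i, j) with i + j = SL-1+k
            offsets[s] = offsets[s - 1] + (SL - 1 + al.shift) * spec.rise * d_prev

    x = np.empty((S, SL))
    for s in range(S):
        x[s] = offsets[s] + signs[s] * spec.rise * np.arange(SL)
    mid = x.mean()

    coords = np.empty((S * SL, 3))
    twist = np.deg2rad(spec.twist_deg)
    for s in range(S):
        axis = _rotation_about_y(s * twist) @ np.array([1.0, 0.0, 0.0])
        center = np.array([mid, s * spec.spacing, 0.0])
        coords[s * SL : (s + 1) * SL] = center + np.outer(x[s] - mid, axis)

    topology = SystemTopology.regular(S, SL)
    frame = BackboneFrame(coords)

    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        target = build_bb_matrix(frame, topology, contact_range).entries
        noise = rng.normal(scale=spec.jitter, size=coords.shape)
        norms = np.linalg.norm(noise, axis=1, keepdims=True)
        over = norms > spec.jitter
        noise = np.where(over, noise * (spec.jitter / np.maximum(norms, 1e-300)), noise)
        # shrink the noise until the designed contact pattern survives
        for _ in range(60):
            trial = BackboneFrame(coords + noise)
            got = build_bb_matrix(trial, topology, contact_range).entries
            if np.array_equal(got, target):
                frame = trial
                break
            noise *= 0.5
        else:
            frame = BackboneFrame(coords)

    return frame, topology, alignments


def _straight_strand(SL: int, rise: float, axis: np.ndarray, center: np.ndarray) -> np.ndarray:
    t = (np.arange(SL) - (SL - 1) / 2) * rise
    return center + np.outer(t, axis)


def _random_unit_vectors(rng: np.random.Generator, n: int) -> np.ndarray:
    v = rng.normal(size=(n, 3))
    return v / np.linalg.norm(v, axis=1, keepdims=True)


def make_random_gas(
    n_peptides: int,
    strand_length: int,
    box: float | Sequence[float],
    min_separation: float,
    seed: int | None = None,
    rise: float = DEFAULT_RISE,
    max_tries: int = 10_000,
) -> tuple[BackboneFrame, SystemTopology]:
    """Randomly placed, randomly oriented straight peptides in a periodic
    box, with all inter-peptide centre distances >= ``min_separation``.

    Deterministic for a fixed seed; raises after ``max_tries`` failed
    placements when the packing is infeasible.
    """
    box_arr = np.broadcast_to(np.asarray(box, dtype=float), (3,)).copy()
    if np.any(box_arr <= 0):
        raise ValueError("box lengths must be positive")
    rng = np.random.default_rng(seed)
    centers: list[np.ndarray] = []
    tries = 0
    while len(centers) < n_peptides:
        candidate = rng.uniform(0.0, box_arr)
        if centers:
            diff = candidate - np.asarray(centers)
            diff -= box_arr * np.round(diff / box_arr)
            ok = bool(np.all(np.linalg.norm(diff, axis=1) >= min_separation))
        else:
            ok = True
        if ok:
            centers.append(candidate)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n_peptides} peptides with separation "
                f"{min_separation} A in box {box_arr} after {max_tries} tries"
            )
    axes = _random_unit_vectors(rng, n_peptides)
    coords = np.concatenate(
        [
            _straight_strand(strand_length, rise, axes[i], centers[i])
            for i in range(n_peptides)
        ]
    )
    topology = SystemTopology.regular(n_peptides, strand_length)
    return BackboneFrame(coords, box=box_arr), topology


def make_clustered_aggregate(
    cluster_sizes: Sequence[int],
    intra_com_distance: float,
    inter_cluster_distance: float,
    seed: int | None = None,
    strand_length: int = 10,
    rise: float = DEFAULT_RISE,
) -> tuple[BackboneFrame, SystemTopology, list[tuple[int, ...]]]:
    """Clusters of peptides with designed membership.

    Peptide centres form a chain within each cluster (consecutive centres
    ``intra_com_distance`` apart along y); clusters are offset along x so
    any two centres in different clusters are at least
    ``inter_cluster_distance`` apart.  Peptide orientations are random
    (seeded).  Returns the frame, topology and the designed partition as
    sorted peptide-index tuples.
    """
    if not cluster_sizes or any(s < 1 for s in cluster_sizes):
        raise ValueError("cluster_sizes must be positive")
    if intra_com_distance <= 0 or inter_cluster_distance <= intra_com_distance:
        raise ValueError(
            "need 0 < intra_com_distance < inter_cluster_distance"
        )
    rng = np.random.default_rng(seed)
    n_total = int(sum(cluster_sizes))
    axes = _random_unit_vectors(rng, n_total)
    centers = []
    ground_truth = []
    peptide = 0
    for ci, size in enumerate(cluster_sizes):
        base_x = ci * inter_cluster_distance
        members = []
        for j in range(size):
            centers.append(np.array([base_x, j * intra_com_distance, 0.0]))
            members.append(peptide)
            peptide += 1
        ground_truth.append(tuple(members))
    coords = np.concatenate(
        [
            _straight_strand(strand_length, rise, axes[i], centers[i])
            for i in range(n_total)
        ]
    )
    topology = SystemTopology.regular(n_total, strand_length)
    return BackboneFrame(coords), topology, ground_truth
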