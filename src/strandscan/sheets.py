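"""Beta-sheet reconstruction via the triplet continuity heuristic.

A beta-sheet is recognised when three strands (a, b, c) are consecutively
adjacent — both pairs (a, b) and (b, c) carry a matched alignment in the P
matrix — and the *same portion* of the central strand b makes at least
three beta-contacts with each neighbour.  The "same portion" condition is
evaluated by reducing the two contact submatrices to per-residue contact
count vectors along b, multiplying them elementwise, and requiring the
span between the first and last non-zero product to cover at least
``min_contacts`` residues.  Qualifying triplets sharing a strand are merged
into sheets, and the fraction of strands belonging to any sheet is
reported as the beta-strand percentage %Ms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np

from .contacts import BBMatrix, pair_submatrix
from .shifts import DEFAULT_MIN_CONTACTS, PMatrix

__all__ = [
    "BetaSheet",
    "SheetReport",
    "pair_reduction_vectors",
    "triplet_projection",
    "qualify_triplet",
    "reconstruct_sheets",
    "percent_ms",
]


@dataclass
class BetaSheet:
    """One reconstructed sheet: its strands, the qualifying triplets that
    built it, and the largest central-strand residue span among them."""

    strands: tuple[int, ...]
    extent: int
    qualifying_triplets: tuple[tuple[int, int, int], ...]

    @property
    def n_strands(self) -> int:
        return len(self.strands)


@dataclass
class SheetReport:
    """Sheet reconstruction summary for one frame/structure."""

    sheets: list[BetaSheet]
    n_strands_total: int

    @property
    def n_beta_strands(self) -> int:
        strands: set[int] = set()
        for sheet in self.sheets:
            strands.update(sheet.strands)
        return len(strands)

    @property
    def percent_ms(self) -> int:
        return percent_ms(self.n_beta_strands, self.n_strands_total)


def pair_reduction_vectors(
    bb: BBMatrix,
    a: int,
    b: int,
    c: int,
    p: PMatrix | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-residue contact counts of central strand b against a and c.

    ``v_r[j]`` counts beta-contacts between grain j of b and any grain of
    a; ``v_c[j]`` the same against c.  Both vectors are indexed along b.
    When a P matrix is supplied, both pairs must hold a matched alignment.
    """
    if p is not None:
        if p.get(a, b) is None or p.get(b, c) is None:
            raise ValueError(
                f"triplet ({a},{b},{c}) requires non-null P entries for "
                f"({a},{b}) and ({b},{c})"
            )
    v_r = pair_submatrix(bb, b, a).sum(axis=1)
    v_c = pair_submatrix(bb, b, c).sum(axis=1)
    return v_r, v_c


def triplet_projection(v_r: np.ndarray, v_c: np.ndarray) -> tuple[np.ndarray, int]:
    """Elementwise product of the reduction vectors and its residue span.

    The extent is the number of residues from the first to the last
    non-zero element of the product, inclusive — a span, not a non-zero
    count — and 0 when the two contact regions are disjoint.
    """
    v_r = np.asarray(v_r)
    v_c = np.asarray(v_c)
    if v_r.shape != v_c.shape:
        raise ValueError(f"length mismatch: {v_r.shape} vs {v_c.shape}")
    v_p = v_r * v_c
    nz = np.flatnonzero(v_p)
    extent = int(nz[-1] - nz[0] + 1) if nz.size else 0
    return v_p, extent


def qualify_triplet(
    bb: BBMatrix,
    p: PMatrix,
    a: int,
    b: int,
    c: int,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
) -> bool:
    """Does (a, b, c) satisfy the sheet continuity criteria?

    Requires at least ``min_contacts`` contacts of b against each of a and
    c, and a shared contact region on b spanning at least ``min_contacts``
    residues.
    """
    v_r, v_c = pair_reduction_vectors(bb, a, b, c, p)
    if int(v_r.sum()) < min_contacts or int(v_c.sum()) < min_contacts:
        return False
    _, extent = triplet_projection(v_r, v_c)
    return extent >= min_contacts


def reconstruct_sheets(
    bb: BBMatrix,
    p: PMatrix,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
) -> SheetReport:
    """Enumerate qualifying triplets and merge them into sheets.

    Every ordered triplet with central strand b and neighbours a < c whose
    two pairs are matched in the P matrix is tested; qualifying triplets
    sharing at least one strand end up in the same sheet (connected
    components over shared strands).  Two-strand pairings that never join
    a qualifying triplet are beta-interactions but not sheets, and do not
    count toward %Ms.
    """
    S = p.n_strands
    qualifying: list[tuple[int, int, int]] = []
    for b in range(S):
        partners = p.partners_of(b)
        for ia, a in enumerate(partners):
            for c in partners[ia + 1 :]:
                if qualify_triplet(bb, p, a, b, c, min_contacts):
                    qualifying.append((a, b, c))

    graph = nx.Graph()
    extents: dict[tuple[int, int, int], int] = {}
    for a, b, c in qualifying:
        v_r, v_c = pair_reduction_vectors(bb, a, b, c)
        _, extents[(a, b, c)] = triplet_projection(v_r, v_c)
        graph.add_edge(a, b)
        graph.add_edge(b, c)

    sheets: list[BetaSheet] = []
    for component in nx.connected_components(graph):
        strands = tuple(sorted(component))
        triplets = tuple(
            t for t in qualifying if set(t) <= component
        )
        extent = max(extents[t] for t in triplets)
        sheets.append(BetaSheet(strands, extent, triplets))
    sheets.sort(key=lambda sh: sh.strands)
    return SheetReport(sheets, S)


def percent_ms(n_beta_strands: int, n_strands: int) -> int:
    """Beta-strand percentage: 100 * n / S rounded to the nearest integer
    (ties rounded up)."""
    if n_strands <= 0:
        raise ValueError(f"n_strands must be positive, got {n_strands}")
    if not 0 <= n_beta_strands <= n_strands:
        raise ValueError(
            f"n_beta_strands must be in [0, {n_strands}], got {n_beta_strands}"
        )
    return int(math.floor(100 * n_beta_strands / n_strands + 0.5))
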