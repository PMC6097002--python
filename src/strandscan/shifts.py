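"""Strand-registry assignment by shift-matrix template matching.

Two beta-strands in contact can pair parallel or antiparallel, in register
or slid along each other by a signed number of residues k (the *shift*).
Each (orientation, k) alignment has a characteristic binary contact
pattern over an SL x SL strand-pair submatrix:

* parallel, shift k:       template[i, j] = 1  iff  j = i + k
* antiparallel, shift k:   template[i, j] = 1  iff  j = (SL - 1 - i) + k

(0-based; parallel k=0 is the identity pattern — "in register" — and
antiparallel k=0 is the exact reversal, the anti-diagonal).  The library of
all such templates is matched against each observed strand-pair submatrix
with the normalized cross-correlation

    NCC(B, L) = sum(B * L) / sqrt(sum(B) * sum(L))

which is 1 exactly when the observed contacts equal the template and 0 when
their supports are disjoint.  The best-scoring template, provided it
explains at least ``min_contacts`` observed contacts (default 3, the
minimum hydrogen-bond support for a beta-pairing), becomes the strand
pair's entry in the potential beta-interaction matrix (P matrix).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterator, Literal, NamedTuple

import numpy as np

from .contacts import BBMatrix, pair_submatrix

__all__ = [
    "Alignment",
    "MatchResult",
    "ShiftMatrixLibrary",
    "PMatrix",
    "ShiftProfile",
    "build_shift_library",
    "ncc",
    "match_alignment",
    "build_p_matrix",
    "shift_profile",
]

Orientation = Literal["parallel", "antiparallel"]

DEFAULT_MIN_CONTACTS = 3


class Alignment(NamedTuple):
    """One mutual strand arrangement: orientation plus signed shift k."""

    orientation: Orientation
    shift: int

    @property
    def label(self) -> str:
        """Compact label as used in shift profiles: P0, P+1, A-2, ..."""
        prefix = "P" if self.orientation == "parallel" else "A"
        return f"{prefix}{self.shift:+d}" if self.shift else f"{prefix}0"

    def reverse(self) -> "Alignment":
        """The same physical arrangement seen from the other strand.

        Transposing a parallel template negates k; antiparallel templates
        are symmetric, so their shift is unchanged.
        """
        if self.orientation == "parallel":
            return Alignment("parallel", -self.shift)
        return self


def shift_template(SL: int, alignment: Alignment) -> np.ndarray:
    """Binary SL x SL template for one alignment."""
    i = np.arange(SL)
    t = np.zeros((SL, SL), dtype=np.uint8)
    if alignment.orientation == "parallel":
        j = i + alignment.shift
    else:
        j = (SL - 1 - i) + alignment.shift
    ok = (j >= 0) & (j < SL)
    t[i[ok], j[ok]] = 1
    return t


@dataclass(frozen=True)
class ShiftMatrixLibrary:
    """All alignment templates for one strand length, |k| <= k_max.

    Alignments are stored in the fixed tie-break order used throughout:
    ascending |k|, parallel before antiparallel, positive k before
    negative.  ``match_alignment`` relies on this order being stable.
    """

    SL: int
    k_max: int
    templates: dict[Alignment, np.ndarray] = field(repr=False)

    def __iter__(self) -> Iterator[tuple[Alignment, np.ndarray]]:
        return iter(self.templates.items())

    def __len__(self) -> int:
        return len(self.templates)

    def __getitem__(self, alignment: Alignment) -> np.ndarray:
        return self.templates[alignment]


def build_shift_library(SL: int, k_max: int | None = None) -> ShiftMatrixLibrary:
    """Enumerate shift templates for both orientations and all |k| <= k_max.

    ``k_max`` defaults to SL - 3 so every template keeps at least three
    overlapping positions (fewer cannot satisfy the contact minimum).
    """
    if SL < 3:
        raise ValueError(f"SL must be >= 3, got {SL}")
    if k_max is None:
        k_max = SL - 3
    if not 0 <= k_max <= SL - 3:
        raise ValueError(f"k_max must be in [0, SL-3] = [0, {SL - 3}], got {k_max}")
    templates: dict[Alignment, np.ndarray] = {}
    for a in np.arange(k_max + 1):
        for k in ([a, -a] if a else [0]):
            for orientation in ("parallel", "antiparallel"):
                alignment = Alignment(orientation, int(k))
                templates[alignment] = shift_template(SL, alignment)
    # re-sort into the documented tie-break order
    ordered = sorted(
        templates,
        key=lambda al: (abs(al.shift), al.orientation != "parallel", al.shift < 0),
    )
    return ShiftMatrixLibrary(SL, k_max, {al: templates[al] for al in ordered})


def ncc(sub: np.ndarray, template: np.ndarray) -> float | None:
    """Normalized cross-correlation of two binary matrices.

    Returns ``sum(sub * template) / sqrt(sum(sub) * sum(template))``, a
    value in [0, 1]; ``None`` when either matrix is all-zero (the score is
    undefined).
    """
    sub = np.asarray(sub)
    template = np.asarray(template)
    if sub.shape != template.shape:
        raise ValueError(f"shape mismatch: {sub.shape} vs {template.shape}")
    s, t = int(sub.sum()), int(template.sum())
    if s == 0 or t == 0:
        return None
    overlap = int((sub * template).sum())
    return overlap / np.sqrt(s * t)


class MatchResult(NamedTuple):
    alignment: Alignment
    score: float
    contact_count: int


def match_alignment(
    sub: np.ndarray,
    library: ShiftMatrixLibrary,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
) -> MatchResult | None:
    """Best-matching alignment of an observed strand-pair submatrix.

    Scans the whole library and keeps the template maximizing the NCC;
    ties go to the alignment occurring first in the library's fixed order
    (smaller |k|, parallel before antiparallel, positive before negative
    k).  Returns ``None`` when the submatrix has no contacts at all, or
    when the winner explains fewer than ``min_contacts`` contacts — a
    pairing with under three consistent contacts is not a credible
    beta-interaction.
    """
    sub = np.asarray(sub)
    if sub.shape != (library.SL, library.SL):
        raise ValueError(
            f"submatrix shape {sub.shape} does not match library SL={library.SL}"
        )
    if not sub.any():
        return None
    best: MatchResult | None = None
    for alignment, template in library:
        score = ncc(sub, template)
        if score is None:
            continue
        if best is None or score > best.score:
            overlap = int((sub * template).sum())
            best = MatchResult(alignment, float(score), overlap)
    if best is None or best.contact_count < min_contacts:
        return None
    return best


@dataclass
class PMatrix:
    """Strand-level potential beta-interaction matrix.

    Holds one :class:`MatchResult` per matched unordered strand pair
    (p < q); unmatched pairs are null.  The total beta-interaction count of
    a system is the number of non-null entries.
    """

    n_strands: int
    entries: dict[tuple[int, int], MatchResult]

    def get(self, p: int, q: int) -> MatchResult | None:
        """Entry for the ordered pair (p, q); orientation bookkeeping is
        applied when p > q (parallel shift negated, antiparallel kept)."""
        if p == q:
            return None
        if p < q:
            return self.entries.get((p, q))
        m = self.entries.get((q, p))
        if m is None:
            return None
        return MatchResult(m.alignment.reverse(), m.score, m.contact_count)

    @property
    def n_beta_interactions(self) -> int:
        return len(self.entries)

    def partners_of(self, s: int) -> list[int]:
        """Strands with a non-null entry against strand s."""
        return sorted(
            q if p == s else p for (p, q) in self.entries if s in (p, q)
        )


def build_p_matrix(
    bb: BBMatrix,
    library: ShiftMatrixLibrary,
    min_contacts: int = DEFAULT_MIN_CONTACTS,
) -> PMatrix:
    """Coarsen the BB matrix to strand level by matching every pair."""
    if library.SL != bb.topology.strand_length:
        raise ValueError(
            f"library SL={library.SL} does not match topology "
            f"SL={bb.topology.strand_length}"
        )
    S = bb.topology.n_strands
    entries: dict[tuple[int, int], MatchResult] = {}
    for p in range(S):
        for q in range(p + 1, S):
            sub = pair_submatrix(bb, p, q)
            m = match_alignment(sub, library, min_contacts)
            if m is not None:
                entries[(p, q)] = m
    return PMatrix(S, entries)


@dataclass
class ShiftProfile:
    """Histogram of matched alignments over (orientation, shift) bins."""

    bins: Counter
    total: int

    def fraction(self, alignment: Alignment) -> float:
        return self.bins[alignment] / self.total if self.total else 0.0

    def dominant_orientation(self) -> Orientation | None:
        """Orientation carrying the majority of matched pairs, or None for
        an empty profile (parallel wins exact ties, for determinism)."""
        if not self.total:
            return None
        par = sum(n for al, n in self.bins.items() if al.orientation == "parallel")
        return "parallel" if par * 2 >= self.total else "antiparallel"

    def as_rows(self) -> list[tuple[str, int, int, float]]:
        """(orientation, shift, count, fraction) rows in tie-break order."""
        ordered = sorted(
            self.bins,
            key=lambda al: (abs(al.shift), al.orientation != "parallel", al.shift < 0),
        )
        return [
            (al.orientation, al.shift, self.bins[al], self.fraction(al))
            for al in ordered
        ]


def shift_profile(p: PMatrix) -> ShiftProfile:
    """Bin the non-null P entries by (orientation, shift)."""
    bins: Counter = Counter(m.alignment for m in p.entries.values())
    return ShiftProfile(bins, sum(bins.values()))
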