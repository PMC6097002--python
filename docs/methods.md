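# Methods

This note records the model implemented by `strandscan`, the choices made
where the design was genuinely open, and what the test fixtures do and do
not demonstrate.

## Representation

A peptide system is a flat sequence of backbone grains (one per residue,
coordinates in Å) divided into S strands of SL grains each. Strands are
assigned consecutively in flat order; the assignment restarts at every
chain break (chain changes and residue-numbering gaps both count as
breaks, so a "strand" can never bridge missing residues), and grains left
over at a break or at the end of the sequence are excluded from analysis.
Indexing is 0-based and half-open internally; user-facing reports are
1-based only where a format demands it.

PDB structures are coarse-grained on read: each residue becomes one grain
at the mass-weighted centre of its backbone heavy atoms N, CA, C, O
(standard atomic masses), matching the conventional placement of a CG
backbone bead. A `ca_only` mapping is available for CA-only depositions.
Multi-model files use the first model unless another is requested.
Trajectories (GRO/XTC/TRR) are read through MDAnalysis by bead name
(default `BB`) and converted from nm to Å on input.

## β-contacts

Two grains on different strands are in β-contact when their distance lies
in the closed interval [r_min, r_max] = [4.7, 5.3] Å, the typical
inter-strand spacing of cross-β structures. Both bounds are configurable.
Distances below r_min score 0: the indicator is read literally as a
window, and CG excluded volume makes sub-4.7 Å backbone-backbone
distances rare in practice. With a periodic box the minimum-image
convention is applied (orthorhombic boxes only, which covers the cubic
simulation boxes this tool targets). The implementation is a vectorised
all-pairs computation; the contract — bit-identical agreement with a
naive double-loop oracle, including explicit image enumeration — is
enforced by test.

## Registry matching

The template for parallel shift k has ones at j = i + k; for antiparallel
shift k at j = (SL−1−i) + k. The antiparallel k = 0 template is thereby
the exact reversal map (anti-diagonal) and the parallel k = 0 template the
identity; positive k always slides toward higher column index. Every
template with |k| ≤ k_max (default SL − 3, below which fewer than three
positions overlap) enters the library, 2·(2·k_max + 1) templates in all.

Similarity is the normalized cross-correlation for binary matrices,
NCC = Σ(B∘L)/√(ΣB·ΣL) ∈ [0, 1], undefined (null) for an empty submatrix.
The normalisation by the geometric mean of the two supports is the
standard form that makes NCC = 1 equivalent to exact equality of the
supports.

A pair's match is the library argmax; ties are broken deterministically by
smaller |k|, then parallel before antiparallel, then positive before
negative k. A winner explaining fewer than `min_contacts = 3`
template-consistent contacts is discarded — three inter-strand H-bond
equivalents being the minimum credible support for a β-pairing — so a
"β-interaction" is precisely a strand pair with ≥ 3 template-consistent
contacts. Viewed from the other strand (entry (q, p) of the P matrix),
a parallel shift negates and an antiparallel shift is unchanged
(antiparallel templates are symmetric). Strand lengths are homogeneous
within one analysis run; heterogeneous systems are out of scope.

Whole submatrices are matched; windowed matching of partial-strand
sub-regions was considered and not implemented — the contact-count
minimum plus the sheet-stage span test cover the partial-overlap cases
the whole-matrix NCC might dilute.

## Sheet reconstruction

For a triplet (a, b, c) with both pairs matched in P, the two submatrices
are reduced along the central strand b to contact-count vectors v_r
(vs a) and v_c (vs c). The triplet qualifies when Σv_r ≥ 3, Σv_c ≥ 3, and
the extent of v_p = v_r ∘ v_c — the inclusive index span from its first
to its last non-zero element — is ≥ 3. The span (rather than the count of
non-zeros) is deliberate: the criterion asks for a *consecutive* stretch
of residues engaging both neighbours.

"Consecutively adjacent" means adjacency in the P matrix, not sequence
adjacency: in an aggregate, sheet neighbours are rarely sequence
neighbours, so all strand orderings (a, b, c) with b central are
enumerated. Qualifying triplets sharing ≥ 1 strand are merged into sheets
(connected components; merging by shared pair instead was considered and
rejected as it can split a physically contiguous sheet whose triplets
overlap only in one strand). A sheet's reported extent is the maximum
triplet extent within it.

%Ms = 100 · n_β-strands / S, rounded to the nearest integer (ties up).
Two-strand pairings are reported as β-interactions but never counted in
%Ms: the heuristic is triplet-based, so an isolated pair is not a sheet.

## Oligomers and order

Peptide centres are unweighted means of backbone grains (only backbone
beads are guaranteed to exist at this coarsening). Oligomers are
connected components of the centre-distance graph at cutoff 11 Å (1.1 nm,
the cross-β equatorial spacing); components are found with a sparse-graph
connected-components routine and verified against an all-pairs BFS oracle
by test. Components of size ≥ 2 are oligomers; singletons are reported
separately, and a `min_size` filter (default 2) trims reports.

P2 uses the standard nematic order tensor: molecular axis u_m is the unit
vector from a peptide's first to last grain, Q = (1/N)Σ(3/2 u⊗u − ½I),
P2 = largest eigenvalue of Q. This definition is invariant under head-tail
flips of any axes and under global rotation, equals 1 for perfect
alignment and tends to 0 (at rate ~N^-1/2) for isotropic axes. The radius
of gyration is the RMS grain distance from the unweighted centroid.

## Synthetic study systems

The generators define the conditions under which the pipeline is
validated:

- **Ideal sheets** place straight strands along a common axis with a
  3.4 Å per-residue rise and 4.8 Å inter-strand spacing (both inside the
  contact window, both configurable), slid and/or reversed so each
  adjacent pair realises a designed (orientation, k) exactly. The twist
  option rotates each successive strand's axis about the stacking
  direction (default grids test 5°/strand), emulating the saddle shape of
  real sheets; jitter adds isotropic Gaussian noise truncated to the
  requested amplitude and then shrunk (halved, iteratively) until the
  designed contact pattern is exactly preserved, so ground truth remains
  exact by construction.
- **Random gases** place straight peptides with uniform random positions
  and orientations under a minimum centre separation (rejection sampling,
  seeded, bounded retries).
- **Clustered aggregates** lay peptide centres in chains at a designed
  intra-cluster spacing, offset clusters beyond the cutoff, and randomise
  orientations; the designed partition is the ground truth. The default
  test sizes (8- and 25-mers) span the oligomer range the method is meant
  to resolve.

What these fixtures do **not** emulate: real backbone dihedral geometry,
side chains, sequence-dependent interactions, thermal contact breakage at
the window boundary, and the slow aggregation kinetics of μs-scale CG-MD.
Passing fixture tests therefore demonstrates the *recognition* machinery
(contacts → registry → sheets → oligomers) is correct, not that any
particular peptide sequence aggregates; trajectory-level aggregate
statistics of real systems (hundreds of β-interactions in 100-peptide
μs simulations) require actual MD input and are covered only
qualitatively by the end-to-end fixture path.

## Numerical and reporting choices

- Contact bounds are compared inclusively with plain floating-point
  comparison; fixtures keep distances ≥ 0.05 Å away from the bounds where
  a test depends on classification stability under rigid motion.
- NCC ties are impossible to hit in float arithmetic for distinct scores;
  equal scores fall back to the fixed library order (documented above).
- Reports use comma-separated CSV, UTF-8, "." decimal, floats at 6
  significant digits; identical inputs yield byte-identical reports.
- Trajectory frames that fail to analyse are logged and written as
  missing rows rather than aborting the series.
- The four reference structures (2mxu, 2fkg, 1d2s, 3bep) are analysed at
  the published strand divisions (SL, S) = (32, 12), (9, 35), (10, 34),
  (6, 122). Resolved-residue ranges differ per deposition; grains beyond
  S·SL in flat order are excluded by the partition rule above, and
  `analyze_structure` logs the division it used. The entries are fetched
  by `scripts/fetch_validation_data.py` rather than redistributed.

## Problem sizes

Synthetic validation uses 12×32 and 3×10 sheets, gases of 30 peptides,
clusters of up to ~60 peptides, 1000-matrix/1000-configuration oracle
sweeps and 100-seed isotropy checks; these sizes give stable statistics
(isotropic P2 maxima ≈ 0.05, well under the 0.15 bound) while keeping the
full suite and the acceptance script fast.
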