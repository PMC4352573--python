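# Methods

## Through-space atom-pair fingerprints

All schemes consume only heavy atoms (hydrogens are folded into per-atom
counts at parse time) and are functions of elements, bonds, formal charges
and — for the 3D schemes — coordinates.  Pairwise distances are invariant
under rotation, translation, reflection and atom relabeling, so every
scheme inherits those invariances exactly; conversely no scheme carries
chiral sense, and enantiomeric conformers are indistinguishable by design.
Diastereomers and distinct conformers of one molecule generally have
different pair-distance multisets and therefore different 3D fingerprints,
while their topological fingerprints coincide — this is the property that
makes LBVS with the 3D schemes stereoselective.

### Gaussian/exponential sampling (3DAPfp, 3DXfp)

Each pair at distance d_AB defines a gaussian centred at d_AB.  The
published construction says "width of 0.18 × d_AB" without fixing the
convention; we read width as the standard deviation σ, the simplest
interpretation, with peak amplitude 1 (any constant amplitude cancels into
the overall normalization scale).  The gaussian is evaluated at all 16
sampling points for every pair with no truncation cutoff: the cost is
negligible and a truncation threshold would be a hidden parameter.

The 16 sampling distances form the geometric series d₁ = 1.45 Å,
d₍ₙ₊₁₎ = 1.18·dₙ, ending at 17.36 Å.  Because σ grows linearly with d_AB,
resolution is roughly constant in *relative* distance, matching the
geometric spacing: the scheme is deliberately fuzzier at long range.  A
consequence worth noting is that the far tail does not vanish — as
d_AB → ∞ every sampled value approaches exp(−1/(2·0.18²)) ≈ 2·10⁻⁷ — but
this asymptote is orders of magnitude below the percent-scale rounding
threshold and never reaches a rounded bit.

Bit n is round(100 · Σ_pairs g(sₙ) / HAC^1.5).  The 1.5 exponent damps the
quadratic growth of the pair count with molecular size.  Rounding is
half-away-from-zero (values are non-negative, so this is simply
floor(x + 0.5)); the convention is fixed here because "rounded to the
integer value" does not specify one.

### Regular binning (R3DAPfp, R3DXfp)

Forty half-open 0.5-Å bins [0.5(k−1), 0.5k) cover 0–20 Å.  The half-open
convention places a distance lying exactly on a boundary in the upper bin,
consistent with 8.51 Å → R18 and chosen so that exactly 8.50 Å also → R18.
Pairs at d ≥ 20 Å are dropped with a logged count; coincident atoms
(d = 0) fall in R1 for the regular schemes and contribute nothing to the
gaussian schemes (the degenerate gaussian is suppressed).  Bit k is
round(100 · count_k / HAC).

### Category-extended schemes

The X variants compute the parent construction inside five blocks in fixed
order [Hyb–Hyb, HBA–HBA, HBD–HBD, sp2–sp2, HBA–HBD].  Same-category blocks
restrict the pair set to atoms carrying that flag and normalize by the
category atom count — raised to 1.5 for the gaussian family, linear for
the regular/topological families — in direct analogy to the parent's HAC
normalization.  The cross block takes unordered pairs with one HBA and one
HBD member and normalizes to the HBA count alone.  A block whose category
holds fewer than two atoms (or, for the cross block, zero HBA or zero HBD
atoms) is all-zero.  Topological distances for Xfp blocks are measured on
the full molecular graph; only the pair selection is restricted.

The 55-bit Xfp is laid out as 5 blocks × 11 topological distances
(1–11 bonds): the total length is documented but not its internal layout,
and 5 × 11 is the unique block-uniform factorization over the five
categories.  APfp itself spans 1–20 bonds; pairs beyond the range of
either scheme contribute nowhere.

### Pharmacophore atom typing

The category definitions are conventional pharmacophore rules fixed by
this package (reference implementations of the published browsers use
proprietary typing, so bit-level identity with them is not claimed):

* HBD — N or O bearing ≥ 1 hydrogen (explicit or implicit);
* HBA — N or O with formal charge ≤ 0, excluding aromatic N bonded to H
  (pyrrole-type) and non-aromatic N attached to an aromatic atom or to a
  carbon doubly bonded to O/N/S (aniline/amide-type, lone pair donated
  into the π system); quaternary N is neither donor nor acceptor,
  carboxylate oxygens are acceptors;
* sp2 — aromatic atoms plus atoms in a double bond;
* Hyb — C, S or halogen with no bonded N or O neighbor.

Flags depend only on the 2D graph, never on coordinates, and an atom may
carry several flags (a hydroxyl oxygen is both HBA and HBD).

### Shape descriptors

nPMI/PMIfp: principal moments of inertia I1 ≤ I2 ≤ I3 of the heavy-atom
point set with standard atomic masses, each divided by the summed
heavy-atom mass ("scaled to molecular weight" is read as heavy-atom mass
since hydrogens are not retained).  The normalized pair (I1/I3, I2/I3)
locates the molecule in the triangle rod (0, 1) – disc (0.5, 0.5) –
sphere (1, 1); a collinear molecule sits at the rod corner (I1 = 0) and a
fully degenerate point set is assigned the sphere corner.

USR: distances from all heavy atoms to four reference points — centroid,
atom closest to it, atom farthest from it, atom farthest from that —
summarized by mean, standard deviation (population) and *excess kurtosis*.
The original USR formulation uses skewness as the third moment; the
kurtosis variant is implemented here deliberately, matching the descriptor
this package is benchmarked against, and the divergence is documented
rather than silently reconciled.  Zero-variance distributions get kurtosis
0.  USRCAT repeats the 12 moments over the subsets all / Hyb / aromatic /
HBA / HBD, always taking reference points from the full molecule; empty
subsets give zero blocks.

## Sum-hash similarity search

Fingerprints are compared by city-block distance.  The database is stored
sorted by (total bit sum, molecule id); for a query with sum S, search
expands outward from the insertion position of S with two pointers, and a
side terminates once its sum-difference lower bound |S − Σentry| exceeds
the current k-th best distance (or the range radius).  The bound is exact,
so results equal an exhaustive scan; ties at the k-th distance are broken
by ascending molecule id, making results reproducible across runs,
platforms and insertion orders.  The published browsers name only the hash
principle; the sum-sorted array with outward expansion is the minimal
structure realizing it.

## Evaluation toolkit

ROC AUC is the rank statistic (probability that a random active outranks a
random inactive), with ties contributing ½ — the Mann–Whitney convention,
fixed here because ranked similarity lists can carry heavy ties.
Enrichment at fraction f uses a top set of ⌈f·N⌉ entries:
EF_f = (recovered actives / total actives) / f, bounded by 1/f.  For
analog-recovery experiments without an external 3D-overlay reference
scorer, "actives" for a query are defined as its top-k list under a
*different* fingerprint scheme than the one evaluated, so cross-scheme
recovery remains a self-contained experiment; size-constrained subsets
(database entries within HAC ± 2 of the query) reproduce the standard
size-matched search setting.  Stereoselectivity of a scheme is quantified
by the seven-way Venn partition of three nearest-neighbor lists (two
diastereomers under a 3D scheme plus the shared-topology search).

## Synthetic fixtures

The generator module produces exactly-specified point-set molecules:
bonded pairs at a chosen distance, linear and helical chains, uniform
random chains in a box (seeded), rigid-motion/mirror/permutation
transforms, and a diastereomer-like pair — two embeddings of one 4-atom
chain with identical bond lengths (1.5 Å) and valence angles (109.47°)
differing only in the central dihedral (anti vs gauche), the minimal
construction with equal topology but distinct pair-distance multisets.
Geometries are deliberately chemically naive: the fingerprint formulas
consume only elements, flags, bonds and coordinates, so exact arithmetic
is more valuable for correctness testing than realistic valences.
Consequently, passing tests demonstrate the correctness of the
constructions and the search, not screening performance on real compound
databases, whose size, conformer quality and chemistry the fixtures do not
emulate.  Problem sizes in the test suite (500-molecule databases for the
search-vs-exhaustive-scan checks, ≤ 6-atom fixtures for literal-formula
oracles) are chosen as the smallest scales at which the checked properties
are non-trivial.

## Known limitations

* Ionization-state adjustment (pH 7.4 protonation) is not performed;
  formal charges are taken from the input file.
* One conformer per record; no conformer generation from SMILES (2D input
  is read but 3D schemes require coordinates).
* Atom typing is an acknowledged approximation; published browser bit
  values are not reproduced bit-for-bit.
* The gaussian "width" convention (σ vs FWHM) is fixed as σ here; an
  implementation using FWHM would differ by a constant factor 2.355 in
  spread.
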