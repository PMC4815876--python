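# Methods

## Problem and model

A far-field diffraction experiment on a polycrystal yields, after spot
harvesting, a pooled set of scattering vectors ("g-vectors") in a Cartesian
frame fixed to the sample, each of length 1/d (Å⁻¹, crystallographic
convention, no 2π).  Every grain is a single crystal: its reflections lie on
the nodes of one rotated reciprocal lattice, so the pool is a superposition
of many interpenetrating point lattices plus position noise.  `mgindex`
recovers, grain by grain and with no phase information, a direct-lattice
basis A (rows a, b, c, Å) and the set of reflections indexed by it.  The
only assumptions are a usable band q_min ≤ |g| ≤ q_max and a noise scale
well below the node spacing.

Bases are stored as rows; a reciprocal point is g = h·B with h an integer
row triplet and B = A⁻ᵀ.  All angles are degrees at interfaces, radians
internally.

## Detection: the 1-D comb filter

For a candidate plane-normal direction û the projections x_i = g_i·û of a
grain's reflections onto û are integer multiples of some spacing d*
whenever û points along a direct-lattice vector v (then d* = 1/|v|).  The
detector is a comb of acceptance boxes of half-width ε centred on the
nonzero nodes ±d*, ±2d*, … ±⌊q_max/d*⌋d*: the score of (û, d*) is the
number of projections inside boxes minus the expected number for
structureless data.  The background expectation is analytic: a point
uniform in the shell [q_min, q_max] projects onto a line with density
p(x) = 3[(q_max²−x²)₊ − (q_min²−x²)₊] / [4(q_max³−q_min³)], and the
expectation is N Σ_nodes ∫_box p.  Because 2ε < d*_min the boxes are
disjoint and membership ("nearest node within ε") equals per-box interval
counting, which is done with a single sort plus vectorized binary searches.

d* is scanned over an adaptive grid d*_{k+1} = d*_k + ε/⌊q_max/d*_k⌋ from
d*_min to d*_max = q_max/2, so the outermost node moves at most ε per step
and no 1-D lattice can be stepped over.  Ties in the score break toward
larger d* (a sub-multiple d*/k indexes the same members against more
background).  The best (û, d*) is refined by an exhaustive 9×9×9 local
grid: tilts of û about two orthogonal axes over ±2ε⌊q_max/d*⌋/q_max rad
(the tilt that displaces the outermost node by 2ε) and d* over ± one
adaptive step.  The refinement never returns a worse score than its input.

An important empirical property: a high-scoring direction need not point
along a lattice vector.  When all three components of t = B·û are close to
multiples of a common d* ("coincidence comb"), the low-|h| core of a grain
fits the comb too.  Such candidates are still useful — their member sets
are grain-pure — but they cover only part of the grain, which drives two
design choices below (origin-box counting and basis re-derivation).

## Candidate subsets: two-pass random search

Pass 1 draws N_u1 directions uniformly on the hemisphere (antipodal
directions are equivalent for the symmetric comb), scans each, keeps the
top 10 scores and refines them locally.  Pass 2 cleans each of the N_j
best subsets: N_u2 directions at more than 10° from the first-pass normal
are scanned against the subset alone with box half-width 2ε, and the best
refined comb's members become the cleaned subset.  A reflection surviving
two independent combs almost surely belongs to the dominant grain, so
cleaned subsets are nearly pure.  They are, however, often partial: a comb
along a lattice direction v necessarily excludes the grain's h_v = 0
plane, and coincidence combs keep only the low-|h| core.  Completeness is
restored later by matching against the full pool.

Both passes rank by the background-subtracted score.  The second-pass box
widening (factor 2) and the 10° exclusion cone operationalize "a larger ε"
and "not parallel"; the factor keeps 2ε₂ well below d*_min.

## Basis determination

Differences of a grain's g-vectors are reciprocal-lattice vectors, so the
normal of a plane through three reflections points along a direct-lattice
direction.  All C(50,3) triples of the 50 reflections closest to the
origin are enumerated; triples whose cross product is below 1% of the
product of the two difference lengths are discarded, and the surviving
normals are merged within 1° (grid bucketing at 0.5° collapses the large
exact-duplicate families first, then a greedy angular merge runs on the
few hundred representatives).

Along each direction the candidate spacings are the projected values
themselves (between d*_min and d*_max).  Each candidate is scored by a
comb count that *includes the origin box*: a reflection projecting to ~0
lies on the central plane of the family and is evidence for the direction.
Without the origin box, counts along short axes (whose central plane holds
15–25% of a grain) are systematically depressed relative to long
many-node vectors, and the 80% cut below then deletes every short axis —
the three shortest survivors become face diagonals {a+b, a+c, b+c}, which
generate an index-2 sublattice, i.e. a doubled cell.  The no-origin comb
remains the right tool in the detection step, where background rejection
is what matters.

Per direction, the returned d* is the largest candidate whose count
reaches 80% of that direction's maximum (sub-multiples index the same
reflections, so the largest qualifying spacing is the physical one); each
surviving axis is then sharpened by linear least squares on the members'
implied plane indices (g_i·v ≈ n_i — triple normals are noise-limited to
~0.05–0.1°, enough to smear the outer nodes beyond ε and destabilize
count comparisons).  Across directions, entries below 80% of the best
count are dropped; the survivors map to direct vectors û/d*, and the three
shortest linearly independent ones (sine and scalar-triple-product
thresholds 0.01, right-handed by a sign flip of the third vector) form the
candidate basis.  Each candidate grain's basis is validated by matching
its reciprocal lattice against the *full* active pool: every lattice point
with |h·B| ≤ q_max + 5ε claims the nearest active reflection within 5ε,
conflicts resolved greedily by ascending distance (at 5ε far below typical
node spacings, conflicts are rare and optimal matching is unnecessary).
The candidate with the most matches wins if it reaches min_reflections
(default 20, conservative against the smallest per-grain count in the
study materials).

## Cell optimization and peeling

Shortest-vector selection can land on a sub-cell whose reciprocal lattice
indexes only a fraction of the grain.  Enlargements of index 2 and 3 are
enumerated as the 7 + 13 distinct sublattices of Z³ via upper-triangular
Hermite normal forms (any integer matrix with the same determinant and the
same row lattice is a unimodular multiple of one of these, so the HNF set
covers every "simple linear combination" of the basis at ~10⁻⁴ of the
cost) and accepted when they match > 20% more reflections; up to two
rounds allow an index-4 correction.

The basis is then refined: the reciprocal basis minimizing Σ|h_i·B − g_i|²
is the closed-form least-squares solution of H·B = G, and one
refine → re-index → refine cycle lets late-joining reflections inform the
final basis.  Because first-pass subsets can be biased cores (above), the
whole basis-determination chain is run once more on the completed
assignment set; the re-derived cell replaces the current one unless the
current (larger) cell matches more than 1.2× its reflections — the same
20% criterion applied symmetrically, so a doubled cell whose extra empty
nodes catch a couple of stray coincidences cannot outvote the compact
cell.  Sub-cell (too-large-cell) integer transformations are never
attempted.

An accepted grain's reflections are deactivated ("peeled") and the search
repeats on the remainder.  The run stops after N_t consecutive failed
tries or when fewer than min_reflections remain active.  All randomness
flows from one seeded generator, so runs are byte-reproducible.

## Synthetic data

The simulator emulates reflection-level output of a polycrystal
diffraction simulation: each grain is a Haar-uniform rotation of its
phase's lattice contributing every integer h ≠ 0 with q_min ≤ |h·B| ≤
q_max (both Friedel mates), plus i.i.d. Gaussian noise of standard
deviation σ per Cartesian component.  Noise displacement vectors with norm
beyond 4σ are redrawn so no reflection strays arbitrarily far from its
node; at the study σ this truncation changes the per-component standard
deviation by under 0.2%.  Reflection conditions default to none
(primitive lattice); predicates such as C-centering are available for
robustness studies.  Not emulated: detector geometry and rotation-range
blind regions (the reference per-grain reflection counts of the original
simulation tool depend on these and are treated as descriptive),
intensities and structure factors, spot overlap, grain-size spread.
Consequently, passing tests show the algorithm's behaviour on complete
shells with isotropic noise; real data adds harvesting losses and
systematic position errors that the tests do not exercise.

## Study presets and problem sizes

The packaged studies use the reference parameterization: ε = 0.0005 Å⁻¹,
σ = 0.0001 Å⁻¹, N_j = 5, N_t = 20; cementite (orthorhombic, V = 153 Å³)
with q_max = 0.6, d*_min = q_min = 0.1; and a granite mixture — quartz
(trigonal), biotite and orthoclase (monoclinic), plagioclase (triclinic) —
with q_max = 0.5, d*_min = q_min = 0.05.  The full-scale ensembles (500
and 200 grains) are desk-scaled to 25 cementite grains and 4 × 5 granite
grains with N_u1 = 3000 and N_u2 = 1500, three seeded repetitions each;
per-grain reflection counts (134 for cementite; 59/258/376/699 for the
granite minerals) keep every material well above the min_reflections
acceptance floor.  At these sizes one indexing run takes on the order of a
minute (cementite) to a few minutes (granite) on a single core.

The multiphase-indifference control is a single-phase scene of 20 cubic
grains whose cell edge is chosen so the total reflection count matches the
granite scene within a few percent.

## Numerical choices and degenerate inputs

* Scores for direction ranking are computed on float32 projections (6e-8
  resolution against ε = 5e-4); all member sets and refinements use float64.
* Grid/node tables and background integrals are cached per parameter set.
* Zero-length cross products, rank-deficient hkl sets, singular bases and
  empty pools raise or return None and count as failed tries; they never
  abort a run.
* comb_count caps node indices at ⌊q_max/d*⌋; projections beyond the last
  node are non-members by construction.
* The g-vector text format stores 17 significant digits and is read with
  round-trip float parsing, so write → read is bit-identical.

## Known limitations

* Spot overlap and intensity thresholds — the dominant real-world failure
  modes — are out of scope of the simulator, so measured robustness is an
  upper bound.
* The success criterion (volume within 1%, completeness above 0.9) does not
  test orientation or strain accuracy.
* Cells more than 3× too small in volume (index > 3 sublattices, or several
  independent half-vectors at once beyond two correction rounds) are not
  recoverable by the enlargement search.
* d*_min bounds the longest recoverable direct vector at 1/d*_min;
  lattices with a longer shortest axis are found as sub-cells (and then
  enlarged) or missed.
* Rarely, a partially commensurate oblique cell shares enough reciprocal
  points with a true grain to pass the minimum-match gate and is accepted
  as a (spurious) grain, costing that grain's success; the observed rate
  (well under 1% of grains) matches the full-scale reference studies'
  reported imperfection.
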