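# mgindex

Multigrain indexing of multiphase polycrystals from pooled scattering
vectors.

## The problem

Far-field diffraction microscopy (3DXRD-type experiments: monochromatic
beam, rotary table, 2-D detector) records, in one scan, the reflections of
every grain inside a polycrystalline specimen.  After spot harvesting the
data is a single pool of scattering vectors **g** in a Cartesian sample
frame, |g| = 1/d in Å⁻¹, with no record of which grain — or which *phase* —
each reflection belongs to.  Standard multigrain indexing programs assume a
known unit cell and index one phase at a time.  `mgindex` is for the
harder setting: an arbitrary mixture of grains of unknown phases, indexed
with no crystallographic input beyond the usable band
q_min ≤ |g| ≤ q_max.  Intended users are 3DXRD/diffraction-microscopy
practitioners and anyone building pipelines for mineralogical or
minority-phase screening of polycrystals.

## The algorithm

Each grain's reflections lie on one rotated reciprocal lattice
g = h·B, h ∈ Z³.  The search runs in 3-D, not 9-D:

1. **Comb detection.**  For a random unit direction û, project the whole
   pool: x_i = g_i·û.  A grain whose direct lattice contains a vector
   v ∥ û projects onto exact multiples of d\* = 1/|v|.  A comb of boxes of
   half-width ε at ±d\*, ±2d\*, … counts members; the expected count for
   uniform shell data, N Σ_nodes ∫ p(x) dx with
   p(x) = 3[(q_max²−x²)₊ − (q_min²−x²)₊]/[4(q_max³−q_min³)], is
   subtracted.  d\* is scanned on an adaptive grid (outermost node moves
   ≤ ε per step) and the best (û, d\*) pairs are refined by local grid
   search.  Repeated over N_u1 directions; top subsets are cleaned by a
   second comb pass restricted to each subset.
2. **Basis assembly.**  Within a cleaned subset, normals of planes through
   reflection triples point along direct-lattice directions; projected
   values supply candidate spacings, 80% count rules select the credible
   (direction, d\*) pairs, and the three shortest independent vectors
   û/d\* form a trial basis A.
3. **Validation, refinement, peeling.**  The trial reciprocal lattice is
   matched against the full pool (nearest reflection within 5ε per lattice
   point, one-to-one).  Cells that index too little are enlarged (integer
   sublattices of index 2–3) when that gains > 20% more matches; the basis
   is refined by least squares on the hkl↔g assignments; the grain's
   reflections are removed and the search repeats until N_t consecutive
   failures.

Grains are indexed independently, so the cost and quality do not depend on
how many phases are present.

## Worked example

Simulate five cementite grains (orthorhombic, a = 4.51, b = 5.05,
c = 6.73 Å), index the pool with no phase information, and score against
the labels:

```bash
mgindex simulate -c examples/cementite5.yml -o gvectors.tsv
# wrote 670 g-vectors from 5 grains to gvectors.tsv
mgindex index -c examples/cementite5.yml -i gvectors.tsv -o grains.json
# indexed 5 grains; 0 reflections left unassigned
mgindex evaluate -c examples/cementite5.yml -i grains.json -g gvectors.tsv -o report.json
# True grains                          : 5
# Indexed grains                       : 5
# Fraction of grains identified        : 1.0000
# Mean rel. volume deviation (success) : 3.199e-05
# Mean fraction correct per grain      : 1.0000
# Mean fraction false per grain        : 0.000e+00
```

Reading the report: all five grains were recovered (a grain counts as
identified when its cell volume is within 1% of nominal and more than 90%
of its reflections were assigned to it); the recovered cell volumes are
within ~3×10⁻⁵ relative of the true 153.28 Å³; every true reflection was
assigned to its own grain and none to a wrong grain.  The g-vector file is
plain TSV (columns gx, gy, gz plus truth labels when simulated), grain
records are JSON with the direct basis, derived cell, and the
(h, k, l) ↔ reflection assignment list.

The same library surface is available in Python:

```python
from mgindex.studies import cementite_study, run_study
sim, idx = cementite_study(n_grains=25, n_u1=3000, n_u2=1500, sim_seed=1, index_seed=2)
pool, grains, report = run_study(sim, idx)
print(report.table())
```

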