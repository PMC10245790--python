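# Methods

## Scope and model

`multifold` assembles multi-subunit protein complexes from predicted
models of subunit pairs and small subunit groups. The package does not run
a structure predictor; it consumes predictor outputs (coordinates with
per-residue plDDT, plus PAE matrices) or synthetic stand-ins from its own
generator. Its core assumptions:

* **Rigid subunits.** Each subunit has one representative structure used
  for every placement; conformational change between interfaces is not
  modelled. A subunit whose domains move relative to each other should be
  split into domain-level subunits by the user (the job planner's
  `divide_chain` helps with length-based splitting; identifying domain
  boundaries is out of scope).
* **Pairwise decomposability.** The complex is reachable by a tree of
  pairwise placements taken from predicted interfaces. Interfaces that no
  pair/group model predicted cannot be recovered; the
  `pairwise_connectivity` diagnostic quantifies this gap before any
  assembly is attempted.
* **PAE as interface confidence.** The mean predicted aligned error over
  the two inter-subunit blocks is the sole interface quality signal,
  mapped to a score by `max(1, 100 − P²/4)`. The quadratic shape keeps
  resolution where PAE is informative (low values) and flattens the
  uninformative high range. Intra-subunit PAE blocks are excluded; a
  `pae_mode="min"` aggregation exists as a config switch. Re-ranking by
  interface plDDT is deliberately not implemented.

## Stage 1 — job planning (`job_planner`)

Chains longer than the predictor cap (default 1800 residues total per
job) are divided evenly into the minimal number of segments (lengths
differing by ≤ 1); segments of one chain carry linker lengths that later
feed the connectivity constraint. One prediction job is emitted per
unordered subunit pair (homodimer jobs when a subunit has ≥ 2 copies);
over-cap jobs are flagged rather than dropped so the user can split
subunits instead of silently losing an interface. Given pair scores, up to
three group jobs (sizes 3, 4, 5) per subunit are grown greedily by best
partner score against any current member, ties lexicographic. The sizes
3/4/5 policy over a single greedy ranking is our reading of an
underdetermined design point; it maximizes coverage diversity per job
budget.

## Stage 2 — the transform library (`transform_library`)

* **Representatives**: argmax of mean plDDT over all model copies of a
  subunit; ties broken by (model id, copy label). Alternatives (average
  PAE, maximal plDDT) perform comparably; mean plDDT is the simplest.
* **Interaction rule**: two instances interact when any Cα–Cα distance is
  strictly below 8 Å.
* **Alignment subset**: residues with plDDT > 80; when fewer than ⌈n/2⌉
  qualify, the best half is used. This keeps disordered regions — folded
  differently in every model — from steering the superposition.
* **Extraction**: T1 superposes representative A′ onto the model's A, T2
  does B′ onto B (least-squares rigid fits, Kabsch via SVD; reflections
  excluded). The stored transform is T1⁻¹∘T2 under the fixed anchor
  convention "A′ at identity, the transform places B′". Homotypic pairs
  are extracted in both directions (identical chains can form asymmetric
  interfaces); heterotypic transforms are inverted on demand.
* **Deduplication**: two transforms of one direction are duplicates below
  5° rotation and 1 Å translation difference; the better-scoring one
  survives. Without this, homomeric libraries grow combinatorially with
  the number of models.

## Stage 3 — assembly (`assembler`, `constraints`)

N iterations (N = Σ copies). Size-i candidates come from all splits
(k, i−k), all stored subcomplex pairs with disjoint copy budgets, all
cross-instance anchors, and all applicable transforms. Filters:

| filter | rule | default |
|---|---|---|
| steric | backbone atom (N/CA/C/O, residue plDDT > 80) penetrating a partner atom's vdW sphere by > `clash_penetration`; discard when > `clash_fraction` of an instance's probe atoms clash with one partner | 1.0 Å, 5% |
| connectivity | Cα gap between consecutive segments of one chain ≤ linker × 3 Å (floor 4 Å — a zero-length linker must still span a peptide bond); copies matched greedily by distance | 3 Å/res |
| restraints | restraint satisfied if the minimum Cα–Cα distance over copy pairings is within its bound; discard at ≥ `restraint_violation_fraction` violated | 70% |

vdW radii are Bondi values (C 1.70, N 1.55, O 1.52 Å; Cα as carbon).
Clash checks run only across the two newly merged sides; within-side pairs
passed the filter when their side was built. The 5% rule is evaluated per
(instance, partner) pair, not pooled over partners.

Survivors are deduplicated by a canonical geometry fingerprint, clustered
by copy-aware Cα RMSD at 1 Å (greedy leader, best score first), and the
K = 100 best per exact subunit composition are stored. Retention per
composition (not per size) keeps compositional diversity available for
later merges. If the full size is unreachable, the largest assembled
subcomplexes are returned, score-sorted.

**Scores.** A subcomplex's score is the weighted mean of its usage
(transform) scores with weights `n_res_left + n_res_right`, the residue
counts of the two merged subsets (`min` and `product` weight modes are
config options). Monomers score 100. The symmetry reward — more than five
copies of one subunit all placed by the same transform id — replaces each
such usage score S by S + S(100−S)/100, and applies from the first
iteration at which its condition holds. Identity of the transform id (not
geometric symmetry detection) is the criterion. One score definition
serves intermediate ranking and final confidence.

**Groups.** Known subcomplexes (e.g., from a partial experimental
structure) are assembled to completion first; their K-best results enter
the final stage as frozen building blocks alongside the remaining
subunits, enforcing the assembly order without any other change to the
search.

## Determinism and tie-breaking

No stage uses randomness. Ranking is by (score, number of distinct
transform ids, sorted ids, canonical fingerprint): on *exact* score ties,
trees built from fewer distinct transforms are preferred. This secondary
key matters in synthetic data where transform scores tie exactly — without
it, clustering may keep an arbitrary mixed-transform tree at sizes below
six, and no pure tree survives for the symmetry reward to reward. With
real (generic) scores the key almost never activates.

The canonical fingerprint is label- and rigid-motion-invariant: each
instance contributes its type and the sorted, 0.1 Å-quantized distances
from its centroid to all other instance centroids. Quantized raw
placements would be frame-dependent and break the package's own
invariance guarantees. Mirror-image assemblies can in principle collide
on this fingerprint; clustering compares full coordinates and keeps
mirror pairs apart, so a collision can at most merge a mirror duplicate
out of the candidate pool.

## Copy-aware RMSD

Comparing two same-composition assemblies requires a correspondence
between identical copies (p copies ⇒ p! labelings). The correspondence is
found on subunit centroids: superpose under the current mapping, reassign
optimally per type (Hungarian algorithm), repeat to convergence; when this
stalls away from zero, a triple-anchored restart matches three reference
instances against every distance-consistent ordered triple of the other
complex and refines the implied assignments. Centroid-perfect
correspondences are not unique for symmetric arrangements — a ring admits
cyclic shifts *and* flips, and the flip is wrong for chiral subunits — so
all near-optimal centroid mappings are discriminated by full-Cα RMSD, and
a pairwise-swap descent polishes the winner. A plain swap-only descent
demonstrably sticks in cyclic-relabelling local minima on exact rings,
which is why the assignment machinery exists. For equal-size copies the
centroid RMSD provably lower-bounds the Cα RMSD (Jensen), which the
clustering stage uses to skip hopeless comparisons.

## Evaluation (`evaluation`)

* **Backbone DockQ**: (Fnat + 1/(1+(iRMS/1.5)²) + 1/(1+(LRMS/8.5)²))/3
  with contacts at 5 Å, interface neighbourhood 10 Å, computed over
  backbone atoms only (the pipeline does not carry guaranteed side
  chains). The constants are the published DockQ ones. The backbone
  restriction shifts absolute values slightly; here the score only gates
  connectivity edges at 0.23, where the distinction is immaterial.
* **Pairwise connectivity**: nodes are reference subunit instances; an
  edge exists when some library transform, anchored either way at the
  representatives, reproduces the reference pair above the gate. The
  ratio is residue-weighted: residues in the largest connected component
  over all residues. 1.0 means the library can in principle assemble the
  complex.
* **compare_assembly**: copy-aware Cα RMSD of an assembled model against
  a placed reference, returning the correspondence it used.

## Stoichiometry scan (`stoichiometry`)

One independent assembly run per candidate copy count over the same
library (the expensive prediction work is done once). The profile reports
whether a full-size complex survived filtering and the best confidence.
Both signals matter: geometrically impossible counts fail to assemble
outright, and counts that only assemble through low-confidence transforms
show a confidence collapse. The output is the full profile, not an
argmax, because real profiles can spike at more than one count.

## The synthetic-data generator (`fixtures`)

The generator emulates the predictor outputs the pipeline consumes:

* **Subunits**: idealized helical (2.3 Å radius, 1.5 Å rise, 100°/turn)
  or compact random-walk backbone traces, Cα spacing ~3.8 Å, with
  N/C/O placed from local frames; optional low-plDDT tails.
* **Architectures**: Cn rings and linear chains, built at the tightest
  packing that leaves *zero* clashing atoms plus a 1.0 Å margin, then
  verified against the package's own clash filter and interaction rule.
  The margin is essential: a ground truth sitting exactly on the clash
  boundary makes legitimate merges flip to rejections under small pose
  noise, which is a degenerate test condition rather than a hard one.
* **Pair models**: one per interacting ground-truth pair; the second
  subunit's pose is perturbed by a half-normal rotation (σ =
  `rot_sigma`) about its centroid plus Gaussian translation. Inter-subunit
  PAE blocks are `pae_base + pae_per_deg × angle` (clipped to [0, 31.75],
  independent noise per direction, hence asymmetric like real PAE), so
  PAE magnitude correlates with pose error *by construction*. Noise acts
  on the relative pose, not per atom, so the assembler's rigid-body
  assumption holds exactly; `atom_jitter` adds per-atom noise for
  robustness tests. Non-adjacent pairs optionally get decoy models:
  touching but wrong poses at near-maximal PAE (default 28 Å → score 1).
* **Crosslinks**: sampled from residue pairs truly within the bound
  (default 25 Å, a DSS-like Cα–Cα length), with a controllable decoy
  fraction sampled beyond it.

What passing on these fixtures does *not* show: performance on real
predictor outputs, where subunits deform between interfaces, PAE is only
statistically related to pose error, and interfaces can be missed
entirely. The fixtures validate the machinery — bookkeeping, geometry,
search, filtering, scoring — not the upstream predictor.

## Problem sizes and parameters used in the shipped checks

The test suite exercises hetero chains of 2–6 subunits (18–30 residues
each) and C3/C8 rings (24/32 residues). The hierarchical-vs-exhaustive
equivalence check runs at N ≤ 4 with at most 3 transforms per pair,
K = 100 000 and a 10⁻⁶ Å clustering radius (retention and clustering
effectively disabled, as the equivalence statement requires). The C8
noise-recovery study runs 20 seeds at 2° rotation / 0.5 Å translation
noise with K = 8: a single-composition homomer carries only a handful of
distinct pose classes, so small K trades no accuracy, and the
zero-noise/noisy comparison uses the same K on both sides. The
stoichiometry profile scans 2–12 copies at the default K = 100. On one
CPU the pure-Python search handles these sizes in seconds to a few
minutes; for much larger homomeric scans, reducing `k_best` is the
recommended lever since composition diversity, not pose diversity, is
what later merges need.

## Known limitations

* Rigid representatives: a wrongly-oriented domain in the chosen
  representative propagates into every placement (the known failure mode
  of representative-based assembly).
* Cyclic symmetry is assembled from repeated pairwise transforms and is
  not idealized afterwards; accumulated per-step error can leave rings
  slightly non-ideal.
* The clash filter's 5% rule is evaluated per partner pair; an instance
  clashing 4% with each of three partners passes.
* Distance restraints are hard filters at the violation fraction, not
  score terms; no FDR model for crosslink identifications.
* Backbone-only DockQ and clash probes; side chains, ligands and nucleic
  acids are carried through I/O untouched but never participate in
  algorithms.
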