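# Methods

## The model and its assumptions

`ensemblemap` treats an RNA's secondary structure as a Boltzmann ensemble
over pseudoknot-free (nested) structures.  Everything downstream — the
nestedness abstraction, clustering, and the 2D map — presumes nesting:
pseudoknotted inputs are rejected rather than silently flattened.

The pipeline's central assumption is that the conformational space worth
visualizing for a sequence is well approximated by the union of Boltzmann
ensembles of its maximally disruptive single point mutants.  Swapping a
base for its Watson–Crick complement removes every pairing partner the
original base had while creating the complementary potential, so each
mutant redistributes probability mass onto alternative architectures the
wild type can reach but rarely visits.  The map is therefore a property of
the *sequence neighborhood*, not of any single ensemble, which is what
makes it a stable target for projecting different conditions.

## The reference energy model

The reference engine exists so that every numerical claim in the package
can be checked against exhaustive enumeration on short RNAs.  Its energy
function is deliberately minimal (all values kcal/mol at 37 °C,
RT = 0.616):

| term | default | meaning |
|---|---|---|
| GC/CG pair | −2.0 | strongest pair |
| AU/UA pair | −1.1 | intermediate |
| GU/UG pair | −0.7 | wobble, weakest |
| stack bonus | −0.9 | per contiguously stacked pair of pairs |
| hairpin-loop initiation | +3.0 | entropic cost, charged once per hairpin loop |
| minimum hairpin loop | 3 nt | sterics |
| minimum helix length | 2 pairs | no isolated (lonely) pairs |

The magnitudes track the GC > AU > GU stability order with values small
enough that 10–25-nt fixtures populate genuinely mixed ensembles — a
sharper model would make the toy ensembles trivially single-structured and
the selection machinery untestable.  Internal and multibranch loops carry
no explicit penalty (a simplification; the hairpin initiation term is the
one loop-entropy contribution kept, because without it the unfolded and
weakly-folded states of disrupted mutants are unrealistically rare).
Isolated base pairs are excluded by default for the standard reason —
an unstacked pair is not a stable structural element — and because a
"helix" of one pair has no meaningful stem identity under the nestedness
abstraction; `EnergyModel(min_helix_length=1)` restores them where the
full enumeration including lonely pairs is wanted.

Partition functions use a helix-grammar inside recursion (exact for the
model above, including the stacking and loop terms), pair probabilities an
outside pass over direct parent helices, and sampling an exact stochastic
traceback of the inside tables.  All three are validated against
exhaustive enumeration (≤ 1e-9 on ≤ 12-nt fixtures; the enumeration guard
refuses N > 25).  Weights are kept in linear space, which is ample for the
short sequences the reference engine targets; the ViennaRNA adapter is the
engine intended for realistic lengths.  SHAPE reactivities enter as the
standard log-linear pseudo-energy ΔG(r) = m·ln(r+1) + b per paired
nucleotide (defaults m = 1.8, b = −0.6 kcal/mol, the field's conventional
values); the −999 sentinel marks missing data and contributes nothing.

## Pipeline parameters

* `n_samples` (default 1000) — structures drawn per selected RNA; the
  conventional stochastic-sampling depth.
* `retain_frac` (default 0.75) — fraction of the panel kept by the
  entropy filter, as retain ⌈0.75·M⌉ (ties broken lexicographically for
  determinism).
* linkage (default complete) — hierarchical clustering of pairing-
  probability vectors; complete linkage emphasizes between-cluster
  separation, and under it the pair of maximum cophenetic separation
  coincides with the globally most distant pair, so "the two most
  divergent partition functions" is well defined.  Subsequent additions
  follow farthest-point (max–min) ordering.
* `window` = 3, `tol` = 0 — convergence: stop when three consecutive
  ensemble additions create no new cluster; a hard cap (`max_added` = 50)
  guards against non-convergence and warns.
* `min_helix` (default 1) — helices shorter than this are ignored by the
  abstraction; 3 reproduces the optional simplification for complex
  ensembles.
* `seed` — one master seed; per-RNA sampling seeds are derived through
  `numpy.random.SeedSequence`, so runs are reproducible byte for byte and
  engines receive independent streams.

The wild type runs through the same pipeline as its mutants but is exempt
from the entropy elimination and is sampled at the end if convergence
arrived before its turn: a map that could not even represent the
wild-type's own reachable clusters would be useless as a projection
target.

## Nestedness encoding

A structure is decomposed into maximal helices (contiguously stacked
pairs) forming a forest.  For each outermost helix the feature vector
holds, at the helix's 5′-start position, the count of helices in its
subtree plus the count of internal loops/bulges (single-child junctions)
inside it.  Hairpin and multibranch loops are not counted: in a nested
helix tree they are determined by the helix counts and add no
discrimination, whereas internal loops mark genuine interruptions of a
stem.  The encoding is invariant to helix elongation on the 3′-interior
side and to loop sizes — exactly the "does this stem element exist, and
where" abstraction.  Cluster identity requires exact vector equality;
nearest-vector assignment happens only at projection time and every such
fallback is logged with its distance so an inadequate map is visible.

Cluster diversity reports three numbers: the modal full-structure share
(max frequency), the mean pairwise Jaccard similarity of binary
paired/unpaired vectors, and u/n with u the number of distinct full
structures (1 when every member is unique).  All three are reported
because a single scalar conflates "many copies of one structure" with
"many slight variants".

## MDS

Embedding minimizes the normalized residual stress between the cluster
vectors' Euclidean distances and the embedded 2D distances.  Coordinates
start from classical scaling (top two eigenvectors of the double-centered
squared-distance matrix, negative eigenvalues clipped) and descend along
the analytic stress gradient with a backtracking line search (stress is
monotonically non-increasing by construction; stop at improvement < 1e-9
or 300 iterations).  Coincident starting points with nonzero target
distance receive a seeded 1e-9 jitter so the gradient is defined.
Coordinates are meaningful only up to rigid motion; all tests compare
distances, never raw coordinates.

## SHAPE analytics

Windowed correlation slides windows of 40–140 nt (step 5 in size, step 1
in start) and reports the Pearson r of the two profiles per window;
windows with under 80 % non-missing coverage in either profile, or with a
constant profile, are masked rather than reported.  The start-step of 1
and the 80 % mask are this package's choices.  The median-deviation track
is the windowed *mean* reactivity minus the profile's global median
(50-nt default); positive values flag segments less structured than the
RNA overall.

## What the synthetic fixtures emulate — and what they do not

The fixtures are 12–23-nt sequences whose complete structure spaces
(≤ ~200 structures) the enumeration oracle can list: a stem-loop, two
independent stem-loops, and a riboswitch-like toggle whose central strand
pairs with either flank.  The SHAPE pair emulates two probing conditions
that agree except over one divergent block, with realistic
exponential-tailed reactivities and missing-data sentinels.  Passing tests
on these fixtures demonstrates algorithmic correctness — exact partition
functions, unbiased sampling, correct clustering and embedding — not
biological realism: real mRNAs have vastly larger structure spaces, loop
entropies the reference model simplifies, and probing noise that is
neither i.i.d. nor exponential.  Conclusions about real RNAs should use
the ViennaRNA engine, and cluster counts are engine-dependent (the engine
identity is recorded in every map's provenance for this reason).

## Numerical and determinism choices

Ties are broken deterministically everywhere: lexicographic ids in the
entropy filter and divergence ordering, lowest input index for medoids,
lowest cluster id for projection fallbacks.  Map serialization is JSON
with sorted keys and shortest-round-trip floats, so a fixed seed
reproduces the file byte for byte and save/load round-trips are lossless.
Sampling-accuracy checks run at n = 10 000 on ≤ 12-nt fixtures and the
map pipeline at the default n = 1000 on the 12–20-nt fixtures — sizes at
which the full analysis completes in seconds while the oracles stay
exact.

## Known limitations

* The reference model's loop treatment is minimal (single hairpin term);
  it is a verification vehicle, not a thermodynamic parameterization.
* No pseudoknots anywhere in the pipeline.
* The unique-cluster set of a map is, in general, a random variable of
  the sampling: architectures whose probability is of order 1/n_samples
  in every selected ensemble may or may not be observed.  On the toy
  fixtures the class probabilities are well separated (verified by
  enumeration), so maps are seed-robust there; for large RNAs the
  convergence window bounds, but does not eliminate, this effect.
* ViennaRNA's stochastic backtracking uses a process-global random state;
  the adapter seeds it per call, but interleaving other ViennaRNA users
  in the same process can perturb reproducibility.
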