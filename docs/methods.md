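# Methods

## Scope and model

`topoptm` encodes the 3D neighborhood of a candidate sumoylation site as a
vector of persistent-homology summaries and evaluates how well those
summaries separate modified from unmodified lysines. The unit of analysis
is the 41-residue window `P` (central lysine ± 20 residues); its heavy-atom
point cloud (hydrogens excluded) is the object whose topology is measured.
Atoms are treated as unweighted points with an element label; no charges,
radii or energies enter the model.

## Filtrations and the persistence engine

**Vietoris–Rips.** A simplex joins the filtration when its largest pairwise
distance reaches the filtration value (the *distance* scale). The bin edges
used by the feature blocks (1.2–2.0 Å for 0-bars) are covalent bond
lengths on this scale, which is why it is the default; the half-distance
(*radius*) convention is available via `FiltrationSpec(scale="radius")`.
Simplices are enumerated up to dimension 3 (homology up to dimension 2)
below a cap `r_f`. Cliques are found by neighbor-list intersection, and
persistence pairs come from GF(2) boundary-matrix column reduction
processed one dimension at a time from the top down, so that columns paired
in dimension d+1 are cleared before the dimension-d reduction; dimension-0
pairs are the Kruskal spanning-forest edges. The reduction kernel keeps
reduced columns in a flat append-only buffer (numba-compiled,
allocation-free inner loop).

**Right-censoring.** A class still alive at `r_f` is reported as a bar
dying at `r_f` and flagged `censored`; the infinite dimension-0 bars (one
per connected component) are excluded from every count and statistic.
`r_f` defaults: 7 Å for whole-window and local-region runs, 6 Å for
per-residue runs, 12 Å for the nitrogen-only run whose feature needs deaths
up to 10 Å — the smallest values that leave every binned feature
uncensored. Zero-persistence pairs are discarded.

**Alpha.** The Delaunay triangulation (scipy/Qhull) is decorated with
squared circumradii top-down; a face that is not Gabriel with respect to a
cofacet inherits the cofacet's value, otherwise it keeps its own
circumradius. Reported filtration values are radii in Å. Degenerate inputs
are handled in three layers: (i) clouds of affine rank < 3 are isometrically
projected to their affine hull (rank 1 uses consecutive-neighbor edges
directly); (ii) points are processed in a canonical lexicographic order so
the barcode cannot depend on atom order; (iii) if Qhull fails or a simplex
is catastrophically near-singular (condition number > 1e13), the cloud is
perturbed by a deterministic Gaussian jitter of 1e-6 Å (escalating tenfold
per retry, at most 4 attempts) — far below any feature bin width. Alpha
bars shorter than 1e-4 Å are discarded as numerically zero-length artifacts
of such degeneracies; genuine atomic-scale persistence is orders of
magnitude larger.

**Oracles.** Two enumerative implementations — VR with max-pairwise-distance
values and Čech with exact minimum-enclosing-ball radii, both reduced by
the textbook column algorithm over all simplices — serve as test oracles
(≤ 10 and ≤ 8 points). Alpha persistence must equal Čech persistence; the
test suite and the acceptance script verify both equalities on dozens of
random clouds.

## Feature vector (356 entries)

All bins are half-open `(lo, hi]` on death times; "barcode statistics" are
max/min/mean/sum/population-SD of BTs, DTs, BLs in that fixed order, with
an empty bar set contributing zeros and n = 1 giving SD 0.

* **TF1 (48)** — whole-window VR: 0-bar death bins with edges
  [1.2, 1.3, 1.4, 1.5, 1.6, 2.0], 1-bar bins [1.5, 2.7, 3.5, 4.5, 5, 6.7],
  2-bar bins [2.4, 2.9, 5.5, 6.7]; the 2nd and 3rd longest 0-bar lengths
  (ranked among finite bars, ties by earlier birth then input order;
  missing ⇒ 0); sum and mean of 0-bar lengths; birth of the longest 1-bar
  (0 if none); statistics of 1- and 2-bars.
* **TF2 (30)** — whole-window Alpha: statistics of 1- and 2-bars.
* **TF3 (240)** — for each flanking residue (positions −20…−1, +1…+20), a
  VR barcode of that residue's own heavy atoms: 0-bar death counts in
  (1.25, 1.5] and (1.5, 1.75], the total 0-bar count (equal to the
  residue's heavy-atom count), and the BL sums of dimensions 0/1/2;
  dummy-X residues contribute six zeros.
* **TF4 (38)** — the local region (central lysine ± 2 residues): all-atom
  VR with 0-bar bins (1.2, 1.6] in 0.1 Å steps plus 1-bar statistics;
  carbon-only VR with 0-bar bins (1.5, 3.0] in 0.5 Å steps plus 1-bar
  statistics; nitrogen-only count of finite 0-bars dying before 10 Å.
  The low-Å bins count 0-bars: in that covalent range 1-bars do not yet
  die (observed 1-bar deaths start ≥ 2.4 Å), so the statistics clause is
  the only part of those analyses that reads 1-bars. An alternative
  both-endpoints-in-bin reading of the binning is not implemented.

Feature identifiers (`tf1_d0_count_(1.2,1.3]`, `tf3_res-07_d1_bl_sum`, …)
are stable and exported alongside matrices as a sidecar JSON.

## Windows and redundancy

Windows are compared by positionwise identity over the 41 aligned
positions (they share a center, so no alignment is needed); `X` matches
`X` but not a residue. The de-redundancy pass pools both classes, walks
the windows in (protein_id, center) order and keeps a window iff its
identity with every kept window is ≤ 0.40 — greedy keep-first, so the
result is deterministic; survivors are then re-split by label. Negative
windows default to all non-annotated lysines of annotated proteins.
Structures must be single-chain (multi-chain files are an error, not a
silent pick); alternate locations keep the highest occupancy; nonstandard
residues are skipped with a warning.

## Classification stage

* **NearMiss (version 1)**: keep all minority samples and the |minority|
  majority samples with the smallest mean Euclidean distance to their 3
  nearest minority neighbors, on raw (unstandardized) features;
  deterministic index tie-break.
* **F-score**: per-feature between-class deviation over summed
  within-class sample variances (n−1 divisor); zero denominator ⇒ 0;
  ties in the ranking break by ascending feature index.
* **Classifiers**: gradient boosting (500 estimators), random forest
  (370 estimators, OOB scoring, sqrt feature subsampling), RBF SVC
  (gamma="auto", probability outputs) — scikit-learn, all other
  parameters default. Features are standardized inside the training fold
  for the SVC only; tree models are scale-invariant.
* **Evaluation**: stratified seeded k-fold CV with confusion counts pooled
  over folds and AUC computed on pooled out-of-fold probabilities (one
  ROC per run rather than a per-fold mean); repeated stratified splits
  for independent testing, summarized as mean ± SD. MCC is 0 by
  convention when a denominator factor vanishes; AUC is the rank
  (Mann–Whitney) statistic with ties counting ½.
* **Incremental selection** retrains from scratch at each prefix of the
  F-score ranking and returns the smallest prefix attaining the maximal
  CV MCC (first-max tie-break); a stride option exists for cheap scans.
  Selecting and reporting on the same CV is the default; nested
  evaluation can be assembled from the primitives.

## Synthetic structures

The generator emulates 41-residue peptides with realistic covalent
geometry: CA atoms along an α-helix-like spiral (radius ≈ 2.29 Å, rise
1.5 Å, 100°/residue; the `compact` class) or a straight strand 3.8 Å per
residue (`extended`); backbone N–CA 1.46, CA–C 1.52, C–O 1.23 Å and an
exact 1.33 Å inter-residue peptide bond; side chains grown from templates
with element-typed bond lengths (C–C 1.53, C–N 1.47, C–O 1.43, C–S 1.55 Å)
and closed planar rings for His/Phe/Tyr/Trp. Because CA spacing and the
peptide bond over-determine the backbone on a tightly curling trace, the
tilt azimuth of each C(i)/N(i+1) pair — to which the peptide-bond length is
invariant — is chosen by a deterministic per-segment grid search that
maximizes clearance from the residue's own N and side-chain attachment;
the carbonyl O likewise picks the clearest out-of-plane direction.
Noise-free structures have every bonded distance in [1.2, 1.6] Å (the
covalent band probed by the 0-bar bins) and no nonbonded contact below
1.7 Å. Gaussian coordinate noise (default SD 0.05 Å) and flanking-sequence
sampling are seeded, so identical specs reproduce bit-for-bit.

What the generator does **not** model: torsional preferences, rotamers,
sterics beyond the construction, proline ring closure, hydrogen atoms,
or any sequence–structure coupling. The two synthetic classes differ
*only* in conformation, with sequences drawn from the same distribution —
so a separable pipeline demonstrates that the features read geometry, not
composition. Passing the synthetic benchmark therefore shows the encoding
and pipeline are sound, not that real sumoylation sites are predictable at
any particular accuracy; the headline numbers reported for real data
require the AlphaFold/UniProt inputs, which this repository deliberately
does not fetch.

## Problem sizes and numerical choices

The synthetic benchmark runs 50 windows per class at noise 0.05 Å with a
5-fold CV — about 340 heavy atoms and ~1M enumerated VR tetrahedra per
compact window, a few seconds each on one core; the oracle-equivalence
suites use ≤ 8-point clouds where full enumeration is exact and cheap.
Simplex order ties break by (filtration value, lexicographic vertices).
The permuted-label control reuses the same feature matrix with labels
shuffled by a seeded generator. Because the classes separate almost
perfectly, the classifier's scores are bimodal and a single permutation
draw's pooled CV AUC is wide-spread (≈ 0.52 ± 0.13 measured over 12
draws) — it tracks how the shuffled labels happen to fall across the two
score clusters. The control therefore averages 10 independent permutation
draws, the usual permutation-test estimate of the null; that mean is
expected in [0.4, 0.6] at 100 samples.

## Known limitations

* VR homology is computed only up to dimension 2, below an explicit `r_f`;
  classes alive at the cap are censored rather than tracked further.
* Alpha values on near-degenerate clouds rest on a deterministic 1e-6 Å
  jitter; barcode entries are then reproducible but carry that
  perturbation, and bars below 1e-4 Å are suppressed.
* The per-residue (TF3) barcodes see each residue in isolation; inter-residue
  contacts appear only in TF1/TF2/TF4.
* `read_structure` expects single-chain models numbered 1..L (the
  AlphaFold convention); windows spanning unresolved interior residues are
  an error rather than a guess.
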