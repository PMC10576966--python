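# topoptm

Topological encoding of lysine-centered peptide structures for
sumoylation-site prediction.

Sumoylation — the attachment of a SUMO protein to a substrate lysine — is a
reversible post-translational modification implicated in transcription,
nucleocytoplasmic transport and disease. Experimental mapping of modified
lysines is slow, so computational site predictors matter. `topoptm`
implements a *structure-only* encoding: each candidate lysine is represented
by the persistent homology of the heavy-atom point cloud around it, and
those topological summaries alone drive the classifier. The intended inputs
are per-protein 3D models (e.g. AlphaFold PDB/mmCIF files) with matching
sequences and a site-annotation table; a synthetic-structure generator
provides realistic peptide geometry so the entire pipeline is testable
without downloading anything.

## The encoding

For a candidate site, a peptide window `P` of 41 residues (the central
lysine K ± 20 residues, dummy code `X` past the termini) is mapped to its
heavy-atom point cloud. Persistent homology tracks connected components
(dimension 0), loops (1) and voids (2) across a filtration: a nested family
of simplicial complexes indexed by a scale parameter. Each homology class is
a bar with birth time BT, death time DT and length BL = DT − BT.

Two filtrations are used:

* **Vietoris–Rips (VR)** — a simplex enters when its largest pairwise
  distance reaches the filtration value (distance scale, Å);
* **Alpha** — the nerve of Voronoi-restricted balls of radius δ, built on
  the Delaunay triangulation; its persistence coincides with the Čech
  filtration's.

Barcodes are vectorized by **binning** (the number of bars of a dimension
whose death time falls in a half-open bin `(lo, hi]`) and by **barcode
statistics** (max, min, mean, sum, population SD of the BTs, DTs and BLs —
15 numbers per dimension). Four feature blocks are concatenated into a
356-entry vector:

| block | length | content |
|-------|--------|---------|
| TF1 | 48 | whole-window VR: 0/1/2-bar death bins (edges 1.2–2.0, 1.5–6.7, 2.4–6.7 Å), ranked 0-bar lengths, 0-bar length sum/mean, onset of the longest 1-bar, 1-/2-bar statistics |
| TF2 | 30 | whole-window Alpha: 1- and 2-bar statistics |
| TF3 | 240 | each of the 40 flanking residues alone: 0-bar bins (1.25,1.5], (1.5,1.75], 0-bar count, BL sums of dims 0–2; `X` ⇒ zeros |
| TF4 | 38 | local region (K ± 2 residues): all-atom VR bins + 1-bar stats, carbon-only VR bins + 1-bar stats (element-specific PH), nitrogen-only 0-bar count below 10 Å |

Downstream, candidate windows are de-redundantized at 40% positionwise
identity, classes are balanced by NearMiss-1 undersampling, features are
ranked by the F-score

F_i = [(m⁺_i − m_i)² + (m⁻_i − m_i)²] / [s²⁺_i + s²⁻_i]

(between-class deviation over summed within-class sample variances), and a
gradient-boosting classifier (500 estimators; random-forest and SVC
configurations included) is evaluated by stratified cross validation or
repeated independent splits with Sp, Sn, Acc, MCC and rank-based AUC.

## Worked example

```bash
python examples/04_classification_pipeline.py
```

builds 8 compact (helical) and 8 extended synthetic 41-mer peptides with
identical sequence statistics, featurizes them and runs the full pipeline:

```
cross-validated performance (compact vs extended):
  Sp 1.000  Sn 1.000  Acc 1.000  MCC 1.0000  AUC 1.000

top 5 features by F-score (between/within-class variance ratio):
  tf1_d1_bl_mean                     F = 44.122
  tf2_d1_bl_std                      F = 42.230
  tf2_d2_dt_sum                      F = 30.622
  ...
```

The two classes differ only in backbone conformation, so perfect separation
shows the features carry geometric information; a label-permutation control
(also printed) collapses toward chance. The other examples demonstrate
barcodes of simple shapes (`01`), window extraction and redundancy
filtering (`02`) and the named feature vector of a single window (`03`).

Real-data runs use the same API: `read_structure` / `read_fasta` /
`build_samples` to assemble windows from AlphaFold models and an annotation
TSV (`protein_id  position  label`), then `feature_matrix`, `near_miss`,
`f_scores`, `incremental_selection` and `cross_validate` /
`independent_test`. The library never performs network I/O.

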