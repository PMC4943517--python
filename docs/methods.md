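# Methods

## Problem and model

Protein phosphorylation occurs at serine, threonine and tyrosine (S/T/Y)
residues, and whether a given S/T/Y site is a kinase substrate depends not
only on the local sequence motif but on the residue's three-dimensional
context.  `structphos` encodes every candidate site as a 153-dimensional
vector built from three blocks:

1. **Site features (51).**  Thirteen groups with fixed arities: PSSM (20),
   evolutionary conservation (1), disorder (6), solvent-accessible area
   (2), pair potential (1), atom/residue contacts (2), topographical index
   (1), physicochemical properties (6), four-body pseudo-potential (1),
   local structural entropy (2), side-chain energy (6), Voronoi contacts
   (2) and structural conservation (1).
2. **Euclidean neighborhood properties (51).**  For each site feature f,
   `ENP_f(i) = sum_j P_f(i,j)` where `P_f(i,j)` is residue j's value of f if
   `i != j` and the minimum heavy-atom distance `d_ij <= 10 A` (boundary
   inclusive), else 0.
3. **Voronoi/Delaunay neighborhood properties (51).**  `VDP_f(i) =
   sum_j P_f(j)` over residues j that share a Voronoi facet with i at the
   atom level, i.e. some heavy atom of i and some heavy atom of j are
   joined by a Delaunay edge of the all-atom tessellation.

Both neighborhood blocks are raw sums, not means; a mean-normalised
variant exists behind the `normalize` flag for ablation and is off by
default.  Sums deliberately include imputed site values -- the sum is over
"the value of feature f", not over a validity mask.

Feature selection is two-step.  Step 1 fits a random forest (500 trees,
sqrt-p features per split, fixed seed) and standardises the per-feature
mean decrease in Gini impurity to Z-scores `z_i = (x_i - mean)/sd`
(sample SD; a constant importance vector maps to all-zero Z), keeping the
top 80.  Step 2 is a sequential backward elimination wrapped around an SVM:
at each step every single-feature removal is scored by

    Rc(i) = (1/k) * sum_{j=1..k} (AUC_j + Accu_j + Sen_j + Spe_j)

over k repeats of stratified tenfold cross-validation on the candidate
subset, the argmax removal is applied, and the path runs down to one
feature.  The selected subset is the Rc-maximising point of the entire
path, ties resolved toward the larger subset.

The classifier is an ensemble built for class imbalance: n asymmetric
bootstrap subsets (every minority sample, plus an equal-size
with-replacement resample of the majority), one RBF-kernel SVM per subset,
fused by majority vote.  The vote fraction (positive votes / n) is the
continuous score used for ROC analysis; tied votes classify positive,
which favours sensitivity -- the cost regime of site prioritisation for
bench validation.

## Geometry

* **Parsing.**  PDB ATOM/HETATM records via Biopython in strict mode
  (malformed records surface line-numbered errors).  Hydrogen and
  deuterium are dropped everywhere ("heavy atoms"); alternate locations
  resolve to the highest-occupancy conformer, ties by altLoc letter;
  selenomethionine maps to M, all other HETATM groups are skipped so the
  residue alphabet stays the 20 standard letters plus X.
* **Side-chain centroid.**  Unweighted mean of side-chain heavy atoms;
  glycine falls back to CA (the standard convention in centroid
  tessellation work).
* **Euclidean graph.**  KD-tree atom search; edge iff minimum heavy-atom
  distance <= cutoff (default 10 A, inclusive).  Sequence separation never
  excludes a pair beyond self-exclusion, so inter-chain neighbors are
  allowed.
* **Tessellations.**  Qhull Delaunay via scipy.  Two tessellations are
  used: all heavy atoms (residue Voronoi adjacency) and side-chain
  centroids (four-body potential).  Degenerate inputs (coplanar,
  cospherical) are retried once with a deterministic jitter of 1e-6 A
  seeded from a CRC of the coordinates, mirroring Qhull's joggle but
  reproducibly.  An optional `max_edge` filter (off by default) prunes
  sliver tetrahedra that connect physically remote residues across the
  convex hull; 8 A is a reasonable value when enabled.

## Four-body pseudo-potential

Each Delaunay tetrahedron of side-chain centroids contributes one
residue-quadruplet composition (unordered multiset of four letters).  The
score of a composition is `Q = ln(f/p)` with observed frequency f and
multinomial expectation `p = C q_i q_j q_k q_l` (q the marginal residue
frequencies of the training tetrahedra, C the multiset permutation count
4!/prod(multiplicities!)).  Natural log is the knowledge-based-potential
convention.  Compositions never observed get a pseudo-frequency floor of
1/(2N) by default (configurable).  Tetrahedron typing is a single pooled
class by default; an optional scheme types tetrahedra by their number of
sequence-adjacent vertex pairs (0-3).  A residue's site feature is the
mean Q over tetrahedra incident to its centroid, zero when incident to
none -- a sum would confound the potential with the incidence degree.

Calibration is testable by construction: a composition stream whose counts
equal their exact multinomial expectation (largest-remainder rounding over
a uniform 8-letter alphabet, ~1e5 tetrahedra) must score |Q| < 0.05
everywhere, and a composition planted at twice its expected rate must
score within 0.05 of ln 2.  The planted composition uses four distinct
letters so the letter marginals stay (almost) uniform under the boost.

## Local structural entropy

LSE averages the Shannon entropy (bits, hence in [0, 3] over 8 states) of
the 8-state secondary-structure distributions of the up-to-four length-4
sequence windows covering a residue; fewer windows exist near termini, and
sequences shorter than one window are treated as a single window.  The
8-state probabilities are approximated natively from a per-residue
propensity table (Chou-Fasman helix/sheet/turn scales distributed over the
eight DSSP states and normalised); this is a heuristic stand-in for a
trained secondary-structure predictor and is documented as such -- its
role is to make the slot computable offline and deterministic, not to be a
state-of-the-art predictor.  Delta-LSE is `LSE(variant) - LSE(wild type)`
and defaults to 0 when no variant is supplied.

## Solvent accessibility and other native features

ASA uses the rolling-probe (Shrake-Rupley) construction with a probe of
1.4 A and a fixed golden-spiral point set of 960 points per atom -- fully
deterministic, accurate to roughly 1 A^2.  Relative ASA divides by the
residue type's theoretical maximum (Tien et al. 2013 Gly-X-Gly values);
unknown residue types divide by the table mean and are flagged imputed.
Contacts use a 5 A atom-pair cutoff and an 8 A minimum-distance residue
cutoff (the group arities fix only the counts, not the cutoffs; these are
conventional values).  The six physicochemical scalars are Kyte-Doolittle
hydrophobicity, net charge at pH 7, Grantham polarity, Zamyatnin side-chain
volume, isoelectric point and an aromaticity flag; unknown letters impute
column means.  The "Voronoi contacts" pair is (number of Voronoi-adjacent
residues, number of atom-level Delaunay edges leaving the residue).

The remaining 36 slots (PSSM, conservation, disorder, pair potential,
topographical index, side-chain energy, structural conservation) depend on
third-party tools and are ingested from per-residue TSV tables keyed by
(chain, seq_num).  Slots absent from the tables are imputed with
training-set column means and flagged; the package never shells out to
external predictors.  The gap-padded 15-mer sequence window is exported
for profile providers but does not itself occupy feature slots -- the
printed arities leave no room for a one-hot window encoding.

## Datasets

Every S/T/Y residue is a candidate; annotated candidates are positive.
Negatives must be unannotated, must lie in a protein with at least one
positive, and must be solvent-inaccessible -- implemented as relative ASA
below a threshold (default 0.05).  The inaccessibility direction is
biologically surprising (kinases modify exposed residues), so the
`negatives_accessible` flag inverts criterion (3); the stated direction
remains the default.  Train/test splitting is by annotation deposit year
(default boundary 2008); undated sites go to train with a warning.
Kinase-family subsets keep one family's positives plus all negatives.
Homology mapping and redundancy reduction are upstream concerns: the
package consumes already-mapped annotation tables.

## Wrapper calibration

The SBE wrapper's SVM uses C = 0.3 with gamma = 1/p (RBF).  This value was
calibrated on the planted-signal generator, where ground truth is known:
the wrapper's purpose is to *detect* redundant features, so its classifier
must degrade measurably when irrelevant features are present.  At larger C
the cross-validated metrics saturate (perfect classification) while many
irrelevant features remain, leaving the elimination criterion without a
gradient; at C = 0.3 the composite Rc rises monotonically as noise
features are removed and peaks at (near-)pure subsets.  Removal ties --
frequent in the saturated early phase where many removals leave the
metrics unchanged -- are broken toward the feature ranked least important
by step 1, so the Gini ranking acts as the prior exactly when the wrapper
criterion carries no information.  k (the repeat count in Rc) defaults
to 1.

Two caveats follow from the calibration study.  First, step 1 selects the
80 features with the highest forest importance, so the retained noise
features are precisely those with the strongest spurious label
correlation; the wrapper evaluates them on the same labels and therefore
retains a small number of them -- this is an intrinsic limit of in-sample
wrapper selection, not an implementation artifact.  Second, the selected
subset is the argmax of a noisy path; with near-separable data the
location of the maximum can move by a few features between seeds.

## Evaluation

Sensitivity, specificity, precision, the Matthews-style correlation
coefficient, F1, accuracy ((TP+TN)/total) and ROC AUC.  Any metric with a
vanishing denominator reports 0 and is flagged -- a conservative
convention that also keeps Rc finite.  The tenfold CV harness makes fold
sizes differ by at most one, tests every row exactly once, stratifies by
label by default (`stratify=False` restores plain random division), and
runs all fitting inside the training folds.  Aggregate metrics come from
summed fold confusion counts; aggregate AUC pools the held-out scores.

## Synthetic data

The generator provides the package's test bed and emulates three things:

* **Structures:** self-avoiding chains with consecutive CA distances of
  3.8 +/- 0.1 A, one pseudo side-chain atom 1.5 A from each CA, and S/T/Y
  enriched to 20 % of residues.  They have protein-like spacing and density
  but no secondary structure, no real side-chain geometry and no burial
  core -- toy chains are nearly fully solvent-exposed, which is why demo
  pipelines raise the negative-site ASA threshold.
* **Feature matrices:** standard-normal noise with planted informative
  columns whose class means differ by delta (default conditions: 400
  sites, 200 features, 10 planted, delta = 1.5, 1:9 imbalance).  The
  Gaussian model is chosen for analyzability: recovery thresholds have
  exact sampling interpretations.
* **Composition streams:** exact-expectation quadruplet streams for
  potential calibration (above).

Passing tests on this generator demonstrates the machinery -- geometry,
bookkeeping, selection and ensemble logic -- under known ground truth.  It
does not demonstrate biological accuracy on real phosphoproteomes, which
requires curated site annotations and real structures.

## Numerical choices and limitations

* All randomness flows through explicit integer seeds; repeated runs are
  bit-identical, and every CLI step writes a manifest (config hash, output
  SHA-256) to verify it.
* Feature matrices are written with `%.10g` floats so CSV round-trips are
  exact at the precision used.
* Degenerate labels (single-class targets) raise typed errors rather than
  producing silent constants.
* Problem sizes in the test-suite demos (tens of residues, hundreds of
  sites) are chosen so the full pipeline runs in minutes on one CPU;
  statistical checks report their n.
* The LSE provider and the physicochemical scales are fixed tables; users
  with access to real secondary-structure predictors or profile tools
  should supply those quantities through the external-feature tables
  instead.
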