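# structphos

Structure-based prediction of protein phosphorylation sites.

Phosphorylation — the kinase-catalysed transfer of a phosphate group onto a
serine, threonine or tyrosine residue — regulates most cellular processes,
and experimentally verifying candidate sites is slow.  `structphos`
predicts, from a protein's 3-D structure, which of its S/T/Y residues are
phosphorylation sites.  It is aimed at structural bioinformaticians who
have PDB structures and per-residue annotations (plus, optionally,
precomputed sequence-profile/disorder/energy tables) and want a
reproducible, scriptable pipeline.

## Method

Every candidate site *i* is encoded by 153 features:

* **51 site features** in thirteen groups (PSSM 20, conservation 1,
  disorder 6, ASA 2, pair potential 1, contacts 2, topographical index 1,
  physicochemical 6, four-body pseudo-potential 1, local structural
  entropy 2, side-chain energy 6, Voronoi contacts 2, structural
  conservation 1);
* **51 Euclidean neighborhood properties**
  `ENP_f(i) = Σ_j P_f(i,j)`, summing feature *f* over residues *j* with
  minimum heavy-atom distance `d_ij ≤ 10 Å`;
* **51 Voronoi/Delaunay neighborhood properties**
  `VDP_f(i) = Σ_j P_f(j)` over residues sharing a Voronoi facet (an
  atom-level Delaunay edge) with *i*.

The four-body pseudo-potential scores each Delaunay tetrahedron of
side-chain centroids by the log-odds `Q = ln(f/p)` of its observed
residue-quadruplet frequency against the multinomial expectation.

Features are then reduced in two steps — random-forest mean-decrease-Gini
ranking standardised to Z-scores `(x_i − x̄)/σ` (top 80 kept), followed by
an SVM-wrapper sequential backward elimination maximising
`Rc = (1/k) Σ_j (AUC_j + Accu_j + Sen_j + Spe_j)` under tenfold CV — and
classified by an imbalance-aware ensemble: *n* asymmetric bootstrap
subsets (all minority samples + equal-size majority resamples), one
RBF-kernel SVM each, fused by majority vote.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

The package ships a generator for a fully synthetic project (toy
structures with protein-like spacing, annotations, external feature
tables), so the whole pipeline runs offline:

```sh
structphos simulate --preset project --n-structures 4 --n-residues 40 \
    --seed 13 --out-dir fixtures/
structphos extract --pdb-dir fixtures/ \
    --annotations fixtures/annotations.tsv \
    --external-features fixtures/external_features.tsv \
    --rel-asa-threshold 1.0 --out matrix.csv
structphos select  --matrix matrix.csv --top-m 80 --seed 13 --out sel.json
structphos train   --matrix matrix.csv --features sel.json --n 5 --seed 13 \
    --out model.joblib
structphos predict --model model.joblib --matrix matrix.csv --out pred.tsv
structphos evaluate --pred pred.tsv --truth matrix.csv --out report.json
```

(The toy chains are almost fully solvent-exposed, hence the raised
negative-site ASA threshold.)  The steps report

```
30 labelled sites -> matrix.csv
selected 23 features -> sel.json
trained 5-model ensemble on 23 features -> model.joblib
```

and the final `report.json` is

```json
{
 "accuracy": 0.8666666666666667, "auc": 1.0, "cc": 0.760885910252682,
 "f1": 0.846153846153846, "precision": 0.7333333333333333,
 "sensitivity": 1.0, "specificity": 0.7894736842105263, "n_sites": 30
}
```

i.e. on its own training matrix the balanced ensemble recovers every
annotated site (sensitivity 1.0) at specificity 0.79 — the tie-to-positive
vote rule deliberately trades false positives for recall, the right cost
regime when predicted sites are candidates for bench validation.  Every
command writes a `*.manifest.json` with the config hash and output SHA-256
checksums; re-running with the same seeds reproduces the files
bit-for-bit.

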