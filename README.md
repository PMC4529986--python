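# patchbind

Structural-feature prediction of RNA-binding residues in protein–RNA
complexes.

Identifying which amino-acid residues of a protein touch RNA is a core
problem in structural biology: binding residues explain recognition
specificity and are the targets of mutagenesis and docking studies.
`patchbind` implements a purely geometric family of features for this task —
instead of sequence windows alone, it describes the *shape of the protein
surface* around each residue and learns which local surface shapes are
typical of RNA interfaces.

## Method

**Shape descriptor.** Every residue is reduced to five points: backbone
N, CA, C, O plus the side-chain center (mean of the heavy side-chain atoms;
for glycine the HA hydrogen, idealized from backbone geometry when absent).
Surface residues are those with solvent-accessible area > 0 (Shrake–Rupley,
probe 1.4 Å); binding residues are those with any atom within 5 Å of any
nucleotide atom.

**Patches and their distance.** Two surface residues are neighbors when
their smallest heavy-atom distance is ≤ d_N (3 Å).  A residue with k
neighbors spans C(k,2) 3-aa patches (residue + neighbor pair) or, when
k = 1, one 2-aa patch.  Two same-size patches X, Y are compared as rigid
point sets by the least-squares distance

d_LS(X, Y) = √ min_{R,t} Σᵢ Σⱼ ‖xᵢⱼ − (R yᵢⱼ + t)‖²,

solved in closed form by SVD of the cross-covariance (Kabsch/Umeyama, proper
rotation enforced, scale fixed to 1).  Because the residue correspondence is
unknown, the structural similarity d_SS is the minimum d_LS over all m!
residue reorderings (6 alignments for 3-aa patches, 2 for 2-aa).

**Representative patches and features.** Patches centered on binding
residues of the training set are the positive *templates*.  A random
subsample (≤ 10,000 3-aa templates; all 2-aa templates) is grouped by
complete-linkage hierarchical clustering under d_SS into 40 + 20 clusters,
and each cluster's medoid — smallest sum of squared d_SS to the other
members — becomes a representative patch Y₁…Y₆₀.  A residue's structural
feature fⱼ is the accumulated d_SS of its surrounding patches to Yⱼ
(3-aa block for k ≥ 2, 2-aa block for k = 1, the other block zero).  With
20 PSSM conservation scores and the amino acid's interface propensity, the
final vector has 81 dimensions.

**Classifier and protocol.** A mean-aggregated ensemble of ridge regression
(on ±1 targets), a perceptron, and a small MLP scores residues in [−1, 1];
each member's hyperparameter is tuned by inner 5-fold cross-validation
maximizing AUC.  Evaluation uses protein-level 4-fold cross-validation —
templates, representatives, propensities and the classifier are rebuilt from
the training proteins of each fold — with sensitivity, FPR, accuracy,
precision, specificity, F-score, MCC, and ROC/AUC reports.

## Worked example

The package ships a synthetic-benchmark generator that plants a recoverable
geometric motif at binding sites: toy proteins whose binding residues sit in
"linear" surface triads (collinear CA atoms, 5 Å spacing, 0.2 Å jitter)
with nucleotides placed 3 Å away, while non-binding surface geometry is
random.  The planted shape signal is the only systematic difference between
the classes.

```python
from patchbind import FixtureSpec, load_benchmark, crossvalidate

spec = FixtureSpec(n_proteins=24, residues_per_protein=40,
                   motif="linear", jitter_sigma=0.2, seed=1)
complexes, pssms, truths = load_benchmark(spec)
result = crossvalidate(complexes, pssms, n_folds=4, seed=1)

m = result.pooled
print(f"residues scored : {m.n}")
print(f"sensitivity     : {m.sensitivity:.3f}")
print(f"precision       : {m.precision:.3f}")
print(f"MCC             : {m.mcc:.3f}")
print(f"AUC             : {m.auc:.3f}")
```

prints

```
residues scored : 936
sensitivity     : 0.993
precision       : 0.969
MCC             : 0.973
AUC             : 0.999
```

The 936 scored residues are the surface residues with at least one surface
neighbor, pooled over the four test folds; the near-perfect recovery shows
that the accumulated-distance features isolate the planted motif from the
random surface background.

The same workflow is available from the shell:

```bash
patchbind make-fixtures --out bench --seed 1
patchbind crossvalidate --manifest bench/manifest.json --out run --seed 1
```

which writes per-stage artifacts (annotation TSVs, prediction TSVs, ROC
points, `metrics.json`) into `run/`.  `patchbind run --config config.yaml`
drives the same pipeline, including the four-way feature-ablation design
(structural / PSSM / structural+PSSM / all), from a single config file.

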