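# Methods notes

This note records the model, the numerical choices, and the design decisions
behind `patchbind`, in the spirit of a package methods appendix.  It states
no empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Model and assumptions

The method assumes that RNA-binding surfaces are built from small recurring
shape units — pairs and triples of spatially adjacent surface residues —
and that the repertoire of those units can be summarized by a fixed set of
representative patches learned from known interfaces.  A residue is then
described by how far its own surface neighborhood is, in rigid-body
least-squares terms, from each representative.  The assumptions this makes:

* rigid comparison is adequate at patch scale (no flexibility, scale fixed
  to 1 — similar patches differ only by rotation and translation);
* the five-point residue descriptor (N, CA, C, O, side-chain center)
  retains enough side-chain information through a single centroid point;
* binding is operationalized purely by distance (any residue atom within
  5 Å of any nucleotide atom).  Interaction-type criteria (hydrogen bonds,
  electrostatics) are deliberately not modeled: they need force-field
  machinery and do not change the geometric feature construction.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| probe radius | 1.4 | Å | solvent probe for accessible area |
| sphere points | 960 | /atom | Shrake–Rupley resolution |
| binding cutoff | 5.0 | Å | residue–nucleotide distance rule (inclusive) |
| d_N | 3.0 | Å | surface neighbor cutoff (min heavy-atom distance) |
| n3 / n2 | 40 / 20 | clusters | representative counts; L = 60 |
| n_max | 10,000 | patches | 3-aa template subsample before clustering |
| propensity α | 1.0 | pseudo-counts | additive smoothing of frequency ratio |
| θ | 0.0 | score | decision threshold on the [−1, 1] ensemble score |

Distances use heavy atoms only for the neighbor relation (crystal structures
usually lack hydrogens, and including them would change d_N semantics
between structures), but *all* recorded atoms for the binding rule, which
mirrors how interface contacts are counted.

## Numerical choices

* **Superposition.** The optimal rotation is R = V·diag(1,1,det(VUᵀ))·Uᵀ
  from the SVD of the centered cross-covariance.  The determinant correction
  matters: the uncorrected closed form can return a reflection, and physical
  patches must never be mirror-superposed (a mirrored patch has d_SS > 0
  unless the patch is planar-symmetric; asserted in tests).  Distances below
  10⁻⁹ Å are reported as exactly 0.  The batched kernel computes explicit
  residuals rather than the trace identity ‖X‖²+‖Y‖²−2·tr(DΣ), which loses
  ~7 digits to cancellation on near-identical patches.
* **SASA.** Shrake–Rupley with a deterministic golden-spiral point set and
  vdW radii C 1.70, N 1.55, O 1.52, S 1.80 Å (others 1.70).  Only protein
  heavy atoms occlude; RNA is excluded so that surface status reflects the
  protein alone and interfaces are not mislabeled buried.  Because the
  sphere points are fixed in the lab frame, per-residue areas are
  rotation-invariant only to sampling error (~1% at 960 points/atom); the
  *sign* — the one property consumed downstream via the area > 0 surface
  rule — is exactly invariant and is what the invariance suite asserts.
* **Glycine side-chain center.** File hydrogens named HA/HA2/HA3 are used
  when present; otherwise an idealized HA is placed 1.09 Å from CA in the
  direction completing tetrahedral geometry given N, CA, C (opposite the
  N/C bisector, tilted out of plane).  A non-glycine residue with no
  side-chain heavy atoms falls back to CA with a warning.
* **Clustering.** Complete linkage on the precomputed d_SS matrix, cut by
  cluster *count* (40/20), never by height.  "Centroid" is implemented as
  the medoid under squared d_SS — no coordinate averaging, so every
  representative is a real patch.  scipy's agglomerative implementation is
  deterministic; exact merge ties are measure-zero for real-valued d_SS.
  Single/average linkage are available behind a flag for comparison (they
  produce ladder-shaped dendrograms on template patches) but are not used.
* **Degenerate inputs.** Collinear point sets still have a defined SVD and
  the reflection correction applies; a fully degenerate (zero) covariance
  is treated as proper.  Residues with incomplete backbones are retained in
  the model but excluded from patch construction; k = 0 residues (no
  surface neighbor) are excluded from training and evaluation with a
  logged count, since an interface is assumed to span at least two
  residues.

## Design decisions where the design was open

* **Ensemble aggregation.** The member roster (ridge regression on ±1
  targets, perceptron, one-hidden-layer MLP) is fixed; the aggregation is
  the unweighted mean clipped to [−1, 1] — the simplest rule consistent
  with the stated score range.  The perceptron contributes
  tanh(decision margin) rather than its hard ±1 label so that inner-CV AUC
  tuning and the ensemble mean see a graded score.  The MLP uses lbfgs
  with a fixed seed: small, and bit-deterministic across reruns.  Hidden
  width ∈ {5, 10, 20}, ridge penalty ∈ {0.1, 1, 10}, perceptron epochs
  ∈ {5, 20, 50}, all tuned by stratified inner 5-fold AUC.
* **Decision threshold.** θ = 0, the midpoint of the score range.
* **Interface propensity.** Defined as the ratio of the interface frequency
  to the surface frequency of each amino-acid type with additive smoothing
  (α = 1), pooled over the training proteins of the current fold only — a
  log-transform was rejected to keep the values nonnegative.  Recomputing
  per fold (rather than once globally) avoids test-set leakage.
* **PSSM handling.** The package never runs the profile search itself; it
  parses precomputed PSI-BLAST ASCII matrices (first 20 log-odds columns)
  and uses the raw integers.  An optional logistic rescale is not applied
  by default since no transform is canonical.
* **Neighbor scope.** Neighbors must themselves be surface residues, and by
  default may come from any protein chain of the complex (multimer
  interfaces are physically continuous surfaces); a same-chain-only switch
  exists.  Patch residue order (center first, then neighbors by sequence
  index) is canonical only — d_SS minimizes over residue permutations, so
  ordering cannot affect any distance (asserted in tests).

## The synthetic benchmark

The fixture generator emits toy protein–RNA complexes in which the *only*
systematic class difference is geometric.  Defaults, chosen once as the
study conditions of the test suite: 24 proteins × 40 residues, arranged as
13 spatially separated triads plus one lone residue per protein on a 25 Å
grid; contact fraction 0.3, i.e. 4 binding triads (12 residues) per
protein; planted motif "linear" (three collinear CA positions at 5 Å
spacing; "fork" = two 5 Å arms 60° apart from a stem) with 0.2 Å Gaussian
jitter; non-binding triads get random bend angles (70–150°), random residue
rolls, and 0.15 Å jitter at 4.4 Å spacing.  Each binding residue receives a
minimal nucleotide (P, O5′, C1′, N9) 3 Å away; grid separation keeps RNA
≥ 8 Å from every other residue, so the 5 Å rule reproduces the intended
labels exactly.  Jitter draws are redrawn (deterministically, from the same
seeded stream) until the required neighbor edges hold, so the emitted
neighbor graph is guaranteed regardless of the noise realization.

What the generator does **not** emulate: covalent chain connectivity
(residues are internally ideal but not bonded to each other), Ramachandran
statistics, realistic side chains (a single CB heavy atom stands in for the
full side chain; glycine has none, exercising the idealized-HA path), RNA
chemistry beyond atom positions, sequence signal (amino-acid types are
uniform random, so PSSM and propensity carry essentially no class
information — which is what makes the feature-ablation comparison
meaningful), and the size or category structure of real benchmark sets.
Passing tests therefore demonstrate that the geometric machinery recovers a
planted structural signal end-to-end under leakage-free cross-validation;
they do not certify performance on real crystal structures, which depends
on data the package does not download.

Problem sizes in the test suite and acceptance script (24×40 benchmark,
≤ 100-pair superposition oracles, 80-patch clustering benchmarks) were
chosen as comfortable desk-scale runs of the full pipeline.

## Known limitations

* Patch sizes are fixed at 2 and 3 residues; larger surface units are out
  of scope.
* The template subsample seed is a run parameter; different subsamples give
  (slightly) different representative sets, which is inherent to the
  method.
* Multi-model PDB files use MODEL 1 only; mmCIF is not parsed; nonstandard
  amino acids are skipped (modified nucleotides do count as RNA atoms).
* Class imbalance is not resampled by default; the decision threshold, not
  the sampling, is the tunable operating point.
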