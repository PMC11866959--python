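# Methods

This note records the models implemented in `ionsaxs`, the conventions and
default parameters, what the synthetic generators emulate, and the design
choices made where the design was genuinely open.

## Scattering model

**Debye formula.** The orientationally averaged intensity of a rigid
particle is I(q) = Σᵢ Σⱼ fᵢ(q) fⱼ(q) sinc(q·dᵢⱼ), with sinc(x) = sin(x)/x
and the i = j and q → 0 limits set to 1 explicitly to avoid 0/0. The sum is
evaluated exactly (chunked vectorized pair loop); no distance-histogram
approximation is used, so the fast path agrees with a naive double loop to
machine precision (the test suite asserts ≤ 1e−10 relative).

**Form factors.** Vacuum factors use the standard 4-Gaussian-plus-constant
Cromer–Mann tabulation for H, C, N, O, P and Mg; f_v(0) equals the element's
electron count to the ~1e−2 precision of the published coefficients.
Excluded volume is modelled by Gaussian dummy atoms at bulk water density
ρ = 0.334 e/Å³ with the Fraser displaced volumes (H 5.15, C 16.44, N 2.49,
O 9.13, P 5.73 Å³); Mg, which has no published Fraser volume, uses a
Bondi-radius sphere (21.7 Å³). The hydration term adds c₂·sᵢ·f_w(q) per
atom, where f_w = f_O + 2f_H and sᵢ ∈ [0,1] is the atom's fractional
solvent accessibility. The c₁ adjustment multiplies the dummy term by
c₁³·exp(−(4π/3)^{3/2} r_m² (c₁²−1) q²/4π) with r_m the model's mean dummy
radius.

**Parameter conventions.** c₁ ∈ [0.95, 1.05], c₂ ∈ [−2, 4] (negative c₂
models a depleted shell). The default policy fixes c₁ = c₂ = 1: adjusting
the hydration layer while also placing ions and reweighting conformers
invites overfitting, so the free parameters are opened only on request.
When opened, (c₁, c₂) are grid-searched (steps 0.005 and 0.05) with the
analytic least-squares scale c at each grid point — deterministic and free
of local-minimum risk; the grid is affordable because I(q, c₁, c₂)
decomposes into six precomputed partial intensities (vacuum/dummy/hydration
auto- and cross-terms), making each evaluation O(S).

**χ² fitting.** χ² = (1/S) Σ [(I_exp − c·I_calc)/σ]² with c analytic.
Computed profiles are evaluated directly on the experimental grid where
possible; otherwise linear interpolation in q is used. χ² is evaluated on
the full overlap of the grids.

**Solvent accessibility** is computed by Shrake–Rupley dot sampling:
100 deterministic golden-spiral points per atom on the extended sphere
(vdW + 1.4 Å probe), counting the fraction not covered by any neighbor's
extended sphere. The dot set is oriented in the molecule's principal-axis
frame (signs fixed by third moments), which makes the discretized result
exactly invariant under rigid motions of the model. Waters present in
input files are parsed (they are classifier training material) but never
scatter; Bondi vdW radii are compiled in.

**Guinier analysis** fits ln I vs q² by weighted least squares, iterating
the low-q window until q_max·Rg ≤ 1.3 is self-consistent; at least five
points are required and a non-negative slope is an error. The dimensionless
Kratky curve (qRg, (qRg)²I/I(0)) takes I(0) from the Guinier fit and
refines its sampled peak parabolically; an ideal globular (Guinier-like)
profile peaks at (√3 ≈ 1.73, 3/e ≈ 1.10). P(r) is computed from the model
as a histogram of interatomic distances weighted by fᵢ(0)·fⱼ(0); an
experimental P(r) by regularized inversion is out of scope.

## Ion-site prediction

**Probes.** Candidate positions are seeded on the solvent-accessible
surface: deterministic dots on each atom's extended sphere, with dots
inside any other extended sphere removed and survivors deduplicated on a
1 Å grid. This occlusion-filtered dot surface gives the same candidate
coverage as a full reentrant molecular surface at a fraction of the
complexity. The generic default probe radius is 1.5 Å (water scale); the
pipeline seeds ion candidates with a 0.6 Å probe instead, because a bound
Mg²⁺ sits at ~2.1 Å from its inner-shell oxygens — roughly the oxygen vdW
radius plus the ionic radius — and a water-scale probe can never reach
coordination distance, which would make every true site undiscoverable.

**Neighborhood graphs.** Each probe's neighborhood is the set of RNA atoms
within 8 Å, encoded as a graph: node features are an element one-hot
(H, C, N, O, P), the distance to the probe (normalized by the radius) and
the atom's solvent accessibility; atom pairs within 5 Å are connected by
edges carrying their distance. Only distances enter, so the representation
is invariant to arbitrary rigid motions of the structure — no orientation
augmentation is needed.

**Classifier.** A compact graph neural network: two single-head graph
attention layers (edge distances feed the attention logits), two
symmetric-normalized graph convolution layers, hidden width 64, mean-pool
read-out and a sigmoid head. Training uses binary cross-entropy, Adam
(lr 5e−3), minibatches of 64 packed graphs, 50 epochs, with the majority
class subsampled to 1:1 per epoch. The network, its backward pass and the
optimizer are implemented directly in numpy; gradients are verified against
numeric differentiation in the test suite. All randomness flows from one
seed, so training is exactly reproducible, and checkpoints embed a feature-
schema hash so inference detects mismatched inputs. Cross-validation uses
stratified folds with AUROC on the held-out fold.

**Site selection.** Probe probabilities are clustered greedily: repeatedly
accept the most confident probe above the threshold (0.5 by default, 0.9
strict; ties broken by probe index) and discard everything within the
minimum separation (3.5 Å). Raising the threshold can therefore only
shrink the accepted set.

## Ion subset selection

The intensity of RNA plus an ion subset A decomposes exactly as
I(A) = I_rna + Σ_{k∈A}(I_kk + X_k) + Σ_{k<l∈A} C_kl, where X_k is the
RNA–ion cross term and C_kl the ion–ion cross terms. All terms are
precomputed once (O(M·N + M²) profile work for M candidates), after which
assembling any subset is independent of RNA size. The ion–ion terms are
included explicitly so the assembly is *exactly* the Debye intensity —
omitting them would silently bias χ². Ions scatter with the Mg form factor
and no hydration term; candidates within 1 Å of an RNA atom are rejected.
Under the default c₁ = 1 policy the decomposition is exact; with c₁ ≠ 1
the cache applies the RNA's mean dummy radius in the excluded-volume
adjustment.

Subsets are enumerated level-wise: level n keeps the K best χ² subsets of
size n (K = 50 by default; K = None is exhaustive), extends each by every
unused candidate, canonicalizes and deduplicates children, and stops when
the best χ² no longer improves or the ion cap (min(M, 30)) is reached.
Ties break lexicographically, so the search is deterministic. The reported
trajectory (best χ² per level, starting from the RNA-only fit) is
non-increasing by construction. With K = None the search provably equals
brute-force enumeration; with finite K its result lies between the
exhaustive optimum and the greedy (K = 1) result.

## Multistate models

When no single conformation fits, the measured profile is modelled as
c·Σ_m w_m I_m(q) with w ≥ 0. Weights are solved by non-negative least
squares on the σ-normalized design matrix — convex and deterministic — and
normalized to Σw = 1 with the scale c absorbing the norm. Conformer subsets
are enumerated with the same beam machinery, scored by their NNLS χ²; the
best model per state count (1..4 by default) is reported. The pipeline
prefers the smallest state count whose χ² is within 5% of the overall best:
extra states must buy a real improvement. Ions are selected per
conformation *before* conformations are combined; a joint ion+conformer
search is deliberately avoided as it invites overfitting. Duplicated pool
members make the weight split degenerate without changing the fitted curve.

## Pipeline

For each conformation: accessibility assignment → RNA-only χ² → (on the
top 50 conformations by that score, plus the starting structure) probe
generation → classifier → site selection → branch-and-bound ion subset →
χ² with ions. "Fits within the noise" is operationalized as χ² ≤ 1.3, a
conventional closeness criterion (configurable); only when the best single
state exceeds it does the multistate stage run. The manifest always
satisfies: best-conformer χ² ≤ starting χ², and multistate χ² ≤ best
single-state χ², because each is a superset search of the previous.

## Synthetic fixtures: what they do and do not show

- `make_helix` builds an idealized A-form-like double helix from a
  6-pseudo-atom per-nucleotide template (rise 2.81 Å, twist 32.7°). The
  reduced atom count keeps the O(N²) Debye sums fast while preserving
  scattering-level realism (helical form-factor features, correct size
  scaling). It is not a chemically correct RNA.
- `perturb_ensemble` applies random rigid hinge rotations about backbone
  pivots — a stand-in for kinematics-based conformational sampling. It
  preserves atom ordering and intra-segment geometry exactly but not base
  pairing.
- `simulate_profile` adds Gaussian noise with σ(q) = 0.01·I(q) +
  0.002·I(0)·q/q_max, mimicking the growing relative error of SEC-SAXS at
  high q; fitting the generating model back gives χ² = 1 ± 0.2 by
  construction (verified over 50 replicates). A zero noise model attaches
  unit errors so χ² against the truth is exactly 0.
- `make_neighborhoods` generates labeled coordination shells: positives
  have 4–6 oxygens at 2.0–2.2 Å in jittered octahedral geometry (the
  canonical Mg²⁺ inner sphere), negatives are looser element-mixed shells
  with nearest atom at 2.6–3.5 Å. A one-rule classifier ("≥4 O within
  2.3 Å") already separates the classes (AUROC ≥ 0.99), so a near-perfect
  GNN score on this corpus demonstrates the training/inference mechanism,
  not performance on real structures — deposited coordination chemistry is
  far more ambiguous, and nothing here licenses accuracy claims about real
  PDB data.
- `make_binding_pockets` plants open octahedral oxygen cages at
  coordination distance just outside a model's surface, giving end-to-end
  tests ground-truth ion positions that are *structurally* discoverable:
  the classifier trained on the synthetic corpus scores pocket-adjacent
  probes highly because they present the same inner-shell geometry.

All generators are deterministic under a fixed seed, and all default sizes
(10–12 bp helices, ensembles of ~6, 1000 training graphs, 81–101-point q
grids to q = 0.4–0.5 Å⁻¹) were chosen so the full suite and the acceptance
script each run in minutes on a single CPU while leaving every statistical
margin comfortable.

## Numerical details and degenerate inputs

- sinc limits at q = 0 and i = j are set to 1 explicitly.
- χ² ties in the beam bound step break by lexicographic subset order;
  equal-confidence probes in site clustering break by probe index.
- A probe with no atom within 8 Å yields an empty-neighborhood signal and
  is skipped; a single-atom model has accessibility 1 by convention; a
  single profile in `fit_weights` reduces exactly to the scalar χ² fit.
- Candidate ions closer than 1 Å to an RNA atom are rejected with a
  warning; duplicate subset indices are an error.
- NNLS returning the zero vector (no profile positively correlated with
  the data) is an error rather than a silent zero-weight model.

## Known limitations

- The scattering model is the standard reduced representation (implicit
  hydration layer, Gaussian dummy atoms); explicit-solvent effects are out
  of scope.
- The classifier is trained here only on synthetic shells; applying it to
  real structures requires retraining on a curated corpus (an importer for
  deposited structures is provided but unused by the tests).
- Kinematics-based conformational sampling, base-pair assignment and
  experimental SEC-SAXS processing are consumed as inputs, not
  reimplemented.
- Multistate weights carry no uncertainty estimates; weight splits between
  near-identical conformers are not identifiable.
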