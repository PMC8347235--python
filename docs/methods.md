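# Methods

This note documents the models and procedures implemented in `mmpscreen`,
the parameters that matter, the numerical choices made where the design
was open, and what the synthetic-data generators do and do not emulate.

## The screening funnel

The pipeline screens one compound library against several MMP targets
independently and intersects the survivors. Stages are strictly ordered
filters: each stage's survivor set is a subset of the previous one, which
`FunnelReport.validate()` enforces. A target without usable docked poses
(no crystal structure suitable for docking) simply configures a shorter
funnel — bioactivity filter plus ligand-based pharmacophore only.

### Stage 1: calibrated random-forest bioactivity filter

- Features: Morgan fingerprints, radius 2, folded to 2048 bits. Radius 2
  (ECFP4-like environments) is the fixed descriptor; 2048 bits is the
  default length, chosen as the common de-facto standard.
- Model: 100-tree random forest; vote fractions are mapped to
  probabilities with Platt (sigmoid) scaling fitted on cross-validated
  out-of-fold scores (`CalibratedClassifierCV`, `ensemble=False`). The
  single-sigmoid form makes the calibrated probability an exactly
  monotone function of the forest's vote fraction, so calibration can
  never reorder compounds.
- Threshold: 0.20. The filter discards only compounds with a
  *less-than-20%* probability of activity, so a probability of exactly
  0.20 survives. The threshold is deliberately permissive because later
  stages are far more specific.
- Validation: stratified seeded 5-fold cross-validation (80%/20% splits),
  predicted class at probability ≥ 0.5, nine confusion-matrix statistics
  averaged over folds. Ratios with a zero denominator are reported as
  NaN, never silently as 0, so degenerate folds remain visible.

### Stage 2: pharmacophore screening

Feature perception uses an explicit, overridable SMARTS catalogue
(`DEFAULT_FEATURE_SMARTS`): donors are N–H/O–H/S–H heavy atoms; acceptors
are carbonyl/hydroxyl/ether oxygens and non-amide sp²/sp³ nitrogens;
negative features sit at the centroid of deprotonated
carboxylate/sulfonate/phosphonate/tetrazole groups; positive features at
protonated nitrogens; aromatic features at all-aromatic ring centroids;
hydrophobic features at centroids of contiguous clusters of ≥ 3 apolar
non-aromatic carbons. Commercial packages perceive features with
undocumented defaults; an explicit catalogue keeps the vocabulary
inspectable and configurable.

- **Structure-based generation** pools features from scored docked
  fragment poses, clusters them kind-wise (average-linkage agglomerative
  clustering, cluster budget 15 allocated proportionally to per-kind
  feature counts), scores each cluster by the *sum* of its contributing
  poses' docking scores (lower = better) and turns the best ≤ 8 clusters
  into sites at score-weighted centroids. Any per-pose scalar score is
  accepted; the original energetic per-site terms of commercial
  implementations are proprietary, and the sum-of-scores rule preserves
  the intent (sites supported by many good poses rank first).
- **Ligand-based generation** enumerates 3–5-feature subsets from each
  active's first conformer as candidate hypotheses (capped at 500 subsets
  per reference), screens each candidate flexibly against all actives
  (≤ 10 conformers each) and keeps those matching ≥ 50% of actives by
  default. Emitted hypotheses are therefore self-consistent by
  construction and re-screening verifies it.
- **Matching semantics**: a pose matches iff every *required* site is
  satisfied by a distinct same-kind feature within the site tolerance and
  at least `min_optional_matches` optional sites are satisfied
  (default 0). Hypothesis strings such as `A (+) A (−) R (+)` mark
  required sites with `+` and optional ones with `−`. The in-place
  matcher solves the injective assignment as a rectangular linear
  assignment problem with a large required-site bonus; it is verified
  against an exhaustive assignment oracle in the tests. The flexible
  screener superposes candidate feature subsets onto the sites with a
  proper rigid motion (Kabsch with det(R) = +1 — reflections are not
  rigid motions of a molecule) and accepts if all post-alignment
  distances are within tolerance, reporting the lowest-RMSD conformer.
- Default site tolerance: 2.0 Å — a typical pharmacophore sphere radius;
  configurable per site.
- **Selection** is sensitivity-first (ties by specificity, then fewer
  sites): the pharmacophore stage sits in the middle of the funnel and is
  meant to lose as few true actives as possible, leaving specificity to
  the electrostatic stage.

### Stage 3: electrostatic-field Tanimoto

Two poses in a common receptor frame are compared by the continuous
Tanimoto coefficient of their sampled electrostatic potentials,
T = Σab / (Σa² + Σb² − Σab), evaluated over the grid points outside both
molecules' van der Waals envelopes. T is 1 for identical fields; by the
Cauchy–Schwarz bound Σab ≥ −(Σa² + Σb²)/2, it is bounded below by −⅓,
attained exactly for b = −a (perfect charge inversion).

- Field model: screened Coulomb with distance-dependent dielectric
  ε(d) = 4d, i.e. V(r) = Σᵢ qᵢ/(4dᵢ²); a constant-dielectric (vacuum)
  model is available. A true linearized Poisson–Boltzmann solver is *not*
  implemented: the comparison layer consumes any two fields sampled on a
  common grid, so a PB field can be substituted. Consequently absolute
  similarity values from this field model are not comparable with those
  of PB-based tools — only the metric's algebraic contract (bounds,
  symmetry, scaling law T(a, λa) = λ/(1 + λ² − λ)) is guaranteed, and the
  per-target cutoffs must always be calibrated with the same field model
  used for screening.
- Grid: 0.5 Å spacing, 4 Å padding around the union bounding box of the
  two compared molecules; interior masking by Bondi radii removes the
  Coulomb singularities. On the toy fixtures, refining 0.5 → 0.25 Å moves
  T by < 0.02.
- Best-pose rule: for each compound, every docked pose is compared with
  every reference and the single (pose, reference) pair with the highest
  T is kept — one pose per compound regardless of which reference
  produced it.
- Reference triage: a reference ligand is kept only if the two-sample
  Kolmogorov–Smirnov statistic between the T-values of potent actives
  (pX > 7) and decoys is ≥ 0.25. This quantifies the qualitative rule of
  discarding references whose active and decoy distributions look alike;
  0.25 is a moderate-separation KS value at the validation-set sizes
  used.
- Cutoff calibration: candidate cutoffs are midpoints between adjacent
  distinct values in the pooled potent-active + decoy sample; the one
  maximizing Youden's J = sensitivity + specificity − 1 is chosen, the
  lowest on ties (favouring sensitivity). A calibration with best
  J < 0.25 is flagged non-discriminating. Manual overrides are supported
  and recorded as such. Histograms (bin width 0.05 over [−⅓, 1]) are
  emitted for decoys and the three pX strata (< 4, 4–7, > 7). The cutoff
  is applied inclusively (T = cutoff passes).

### Stage 4: consensus, clustering, selection

Compounds surviving the *final* stage of ≥ 2 target funnels are consensus
hits (≥ 3 defines a stricter inspection tier). Hits are clustered
together with known actives by HDBSCAN on the Jaccard distance matrix of
their Morgan fingerprints (`min_cluster_size` 2 by default). Clusters
containing any known active are flagged and their hits excluded — they
are not novel chemotypes. HDBSCAN noise points become unflagged singleton
clusters: a structurally isolated hit is exactly the kind of novel
chemotype the selection wants, so noise must remain eligible. Selection
takes at most one hit per unflagged cluster, ranked by the number of
funnels survived with ties broken by ascending compound id (a
reproducible stand-in for the visual inspection a medicinal chemist would
apply). PAINS alerts (RDKit's built-in catalogue, families A–C) are
reported with the selection, not used to remove compounds.

### Assay math

Percent inhibition is 100·(1 − vi/v₀) against an uninhibited control.
IC₅₀ is fitted by least squares to the one-parameter model
vi/v₀ = 1/(1 + [I]/IC₅₀) — no Hill slope, no baseline. Only measurements
with inhibition in [10%, 90%] qualify (evaluated on the measurements
themselves, not the fitted curve), and ≥ 5 distinct qualifying
concentrations are required; points near 0% or 100% carry almost no
information about IC₅₀. The initial guess is the concentration whose
inhibition is nearest 50% ([I] = IC₅₀ gives exactly 50%). The reported SD
is the single-fit uncertainty from the curvature at the optimum
(linearized covariance); it is *not* an inter-experiment SD and is
labelled accordingly.

## Synthetic data

`mmpscreen.fixtures` generates every input the tests and examples use;
all generators are pure functions of their arguments.

- `make_classification_set`: actives decorate a shared N-aryl
  sulfonamide/benzoic-acid scaffold with aryl substituents (masses
  ~305–480 Da, inside the 300–600 Da screening window); decoys are linear
  alkyl esters with chain length tuned to match an active's mass within
  25 Da. Active pX is sampled 25% in [1, 4), 35% in [4, 7], 40% in
  (7, 13]. The shared scaffold guarantees shared fingerprint bits, so the
  RF filter separates the classes almost perfectly — the set tests the
  training/calibration/threshold machinery, *not* the difficulty of real
  bioactivity data, where actives and decoys overlap structurally.
- `make_planted_pose_set`: matching poses put a feature within 0.4×
  tolerance of every site; non-matching poses displace one required
  site's feature by > tolerance + 0.5 Å and away from all same-kind
  sites. Sites must be > 2× tolerance apart (as `make_random_hypothesis`
  guarantees) so labels are unambiguous by construction.
- `make_charged_pose`: carbons at uniform random positions in a 10 Å box
  with profile-controlled charges; used for the field-Tanimoto algebra
  tests, where chemistry is irrelevant.
- `make_et_validation_set`: decoys and weak actives draw T from
  N(0.3, 0.1) truncated to [−⅓, 1]; mid actives are shifted by half the
  given shift and potent actives by the full shift — emulating the
  empirical pattern that field similarity to reference inhibitors tracks
  potency. Real validation-set histograms are messier (multimodal,
  reference-dependent); the fixture tests calibration behaviour, not
  distribution shape.
- `make_inhibition_curve`: exact model values with multiplicative
  Gaussian noise, clipped at 0.

What passing tests show: the algebra, the contracts and the decision
rules are correct, and each stage behaves as designed on data with known
ground truth. What they do not show: performance on real screening
libraries, which depends on docking quality, charge models and the
structural overlap of actives and decoys.

## Problem sizes and numerical choices

The suite runs at desk scale: RF cross-validation on 500 + 500 generated
compounds, matcher-vs-oracle equivalence on 1,000 random instances
(≤ 4 sites, ≤ 8 features), consensus-vs-counting on 100 random 10×200
membership matrices, IC₅₀ bias on 100 simulated curves (5% noise, doses
at IC₅₀·{¼, ½, 1, 2, 4} so every point stays inside the 10–90% qualifying
window), and field-Tanimoto checks on 5-atom toy poses with 0.5 Å grids.
Tie-breaks are deterministic everywhere (lowest cutoff on equal Youden J,
ascending compound id in selection, stable feature ordering by kind and
atom indices); two all-zero fingerprints define Tanimoto 0, while two
all-zero potential fields raise an error (a fingerprint can be legally
empty, a charged pose's field cannot).

## Known limitations

- The surrogate field model reproduces the Tanimoto metric's contract,
  not PB-quality potentials; cutoffs calibrated with one field model do
  not transfer to another.
- Standardization trusts input charge states; protonation/tautomer
  enumeration at assay pH and stereoisomer expansion are out of scope.
- Conformer generation is external; the flexible screener consumes at
  most 10 supplied conformers per compound.
- The ligand-based hypothesis search enumerates subsets from single
  reference conformers and is exponential in feature count; the caps
  (500 subsets per reference) make it practical only for the small
  feature sets typical of drug-like actives.
- `fit_ic50` reports a per-fit SD; averaging IC₅₀ over independent
  experiments and reporting their spread is the caller's responsibility.
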