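# Methods

This note records the scientific choices behind `triface`: the model and
its assumptions, the defaults and their units, the numerical conventions,
and what the synthetic experiments can and cannot show.

## Problem setting

A protein trimer contributes three chain–chain interfaces. Within one
interface, every residue of one chain paired with every residue of the
other is a candidate; a pair is *positive* when any two of its atoms are
in contact (positive contact area). Candidate counts grow as the product
of chain lengths (~10⁴–10⁵ per interface) while positives number in the
tens, so the classification task is characterised by extreme imbalance,
and ranked top-t lists — not global classification accuracy — are the
meaningful output.

## Sequence descriptors

Sequences over the 20-residue alphabet are mapped through seven property
scales (packaged constants from the standard literature tabulations;
`scales.load_scales_tsv` swaps in any other parameterisation). The
k-interval product factor treats the numeric sequence as a cycle: the
feature at position j with interval k is Φ_j·Φ_{(j−k) mod L}/k (forward)
or Φ_j·Φ_{(j+k) mod L}/k (backward). Rationale for the cyclic
convention: it keeps the feature defined at the termini without padding
or truncation, and makes the feature matrix exactly equivariant under
sequence rotation — a property the tests exploit. Intervals run k = 1..5
over the first five scales (both directions), giving 50 features; the
residue's seven raw scale values complete the 57-column block. Whether
terminal residues deserve additional special handling beyond the cyclic
convention is an open question; none is applied.

Fixed column order: (property 1..5) × (k = 1..5) × (forward, backward),
then the seven basic values. Every table writer emits this manifest.

Non-standard residues: selenomethionine is read as methionine; any other
unknown residue type is rejected rather than imputed, because an imputed
scale value would silently distort all 50 interval products of its
neighbourhood.

## Structure descriptors

ASA uses Shrake–Rupley sampling: each atom's van der Waals sphere
(Bondi-style single radius per element, default 1.70 Å) is inflated by
the probe radius (default 1.4 Å, water) and covered with `n_points`
golden-spiral test points (default 960; the suite checks 960 agrees with
9600 within 2%). Per-residue ASA is the sum over heavy atoms; hydrogens,
waters and non-amino-acid heteroatoms are excluded, and only the first
model of a multi-model file is read. RASA = ASA_bound/ASA_unbound, with
the unbound state the isolated chain; a residue fully buried already in
the monomer (denominator zero) gets RASA 0 with a warning.

Atom–atom contact area is approximated as the mean lateral
(spherical-cap) area of the lens where the two probe-expanded spheres
overlap. This is a geometric stand-in chosen for smoothness and symmetry;
its absolute scale is heuristic, but interface labelling only uses its
sign, and the per-residue sums (ECA across chains, ICA within a chain
excluding sequence neighbours at distance < 2) enter the descriptor
after min–max normalisation, where a monotone rescaling is immaterial.
Exterior void area is defined as EVA = max(0, (ASA_unbound − ASA_bound)
− ECA): surface buried on binding but not in direct atomic contact.
Users with Naccess/Qcontacts/propka-style outputs can inject per-residue
ASA, per-pair contact areas and per-residue pK1/pK2 through the TSV
importers and bypass all three internal models.

pK1/pK2 default to the textbook intrinsic ionisation constants of the
free amino acid (α-carboxyl and α-amino groups, pH units). They are
type-level constants — two residues of the same type are
indistinguishable — which is exactly the property needed for a
reproducible default; structure-aware estimates belong in the import
path.

## Pair features and selection

A pair vector concatenates the two 64-dim descriptors, lower chain id
first (one orientation per unordered pair; generating both orientations
is available for training augmentation but off by default). Min–max
parameters are learned on training data only; test-time values are
clipped to [0, 1] and constant training columns map to 0.

Selection happens after normalisation. Columns with pairwise |r| > 0.5
(Pearson, population moments) are grouped by connected components of the
thresholded correlation graph — single linkage, chosen because it is
deterministic and parameter-free. Per group the column with the largest
F-value |μ⁺ − μ⁻|/(σ⁺ + σ⁻) survives (ties to the lower index; the
preserved basic-sequence and basic-geometry columns survive
unconditionally). Note the F denominator is the *sum* of the class
standard deviations: a difference of deviations would be identically
zero for equally dispersed classes and can be negative, so the sum is
the only denominator that makes the score a meaningful Fisher-type
separation measure. Population rather than sample deviations are used
throughout; at the intended sample sizes (~10⁴ pairs) the distinction is
far below any decision threshold. Zero-variance columns have no defined
correlation and stay as singletons (they are harmless after
normalisation). With these rules selection is idempotent, which the
suite verifies. The retained count is data-dependent; a fixed retained
list can be injected for strict replication of a published column set.

## Ensemble

Each layer draws `n_members` = 100 balanced subsets (all positives plus
an equal-count uniform draw of negatives without replacement,
independent per member, seeds derived from the master seed by fixed
offsets) and trains one RBF SVM per subset (C = 1, gamma = "scale",
probabilities by Platt sigmoid calibration with internal 5-fold CV).
Under-sampling plus ensembling is the standard remedy for 1:10³-scale
imbalance: each member sees a balanced problem, and averaging over 100
independent negative draws restores coverage of the negative manifold.
The layer score is the *mean* member probability — summed votes give an
identical ranking but leave [0, 1], and the fusion
P = ω·P₁ + (1 − ω)·P₂ (ω = 1/2 by default) is only well-scaled for
means. Ranking ties break deterministically by ascending residue
numbers. SVM hyperparameters are deliberately the least-surprising
baseline and sit in `EnsembleConfig`, all overridable.

## Random baseline

With N candidate pairs per interface of which M are true, the hit count
of a random top-T list is X ~ H(N, M, T); interfaces are treated as
i.i.d., with N and M the benchmark means (40 920 and 83). Exact forms:
p₁ = 1 − C(N−M, T)/C(N, T) per interface; at least two of three
interfaces: 3p₁²(1−p₁) + p₁³; all three: p₁³; at least one of three:
1 − (1−p₁)³ (`trimer_null_exact`). All combinatorics are evaluated in
log space.

The module also reports the widely quoted simplified closed forms
(`bound1` = 1 − (N−M−T+1)/(N−T+1), and the corresponding z = 2, 3
expressions). These replace the product of T depletion ratios by its
single smallest factor **without re-exponentiating**, so for T ≥ 2 they
are not upper bounds but *single-draw-style approximations that
understate the exact null* — at N = 40 920, M = 83, T = 10 the exact
per-interface probability is 2.010% against a "bound" of 0.20288%. The
exact forms are authoritative in this package; the simplified forms are
kept because they are the numbers quoted in published comparisons. The
Monte-Carlo sampler simulates three i.i.d. hypergeometric counts per
draw and is validated against `trimer_null_exact` (3 standard errors
over a parameter grid); no Monte-Carlo procedure can reproduce the
simplified forms, since it necessarily estimates the exact event
probability.

Percent rendering uses 4 significant figures (5 for the larger z = 1
quantities), matching customary reporting.

## Synthetic data

The pair generator draws class-conditional Gaussians: a seeded subset of
columns (default 20% of 128) is shifted by d·σ for positives (default
d = 1.5, σ = 1), the rest is i.i.d. noise; options plant exactly
duplicated informative columns (for selection tests) and set the
imbalance (default 1:200). This is a deliberate idealisation: real
descriptor columns are heteroscedastic, mutually correlated and
non-Gaussian, and real interface signal is not a uniform mean shift.
Passing the end-to-end tests therefore shows the machinery — selection,
under-sampling, calibration, fusion, ranking, and the top-t metrics —
recovers a planted signal of realistic strength; it does not certify
accuracy on real trimer structures.

The toy structure generator places three straight poly-alanine CA traces
far apart and adds, per planted cross-chain pair, two bridge pseudo-atoms
0.8 Å apart at the pair's midpoint, so the contact model labels exactly
the planted pairs. Pairs on one interface must keep their position sums
≥ 3 apart — closer bridges would touch each other and create unplanted
contacts — and infeasible plantings are rejected.

End-to-end study conditions (fixed in `tests/conftest.py`): training
pool of 60 positives at 1:200, evaluation on 6 trimers × 3 interfaces ×
(2 true + 1000 decoy pairs), top-10 lists. With those interface sizes
the exact null probability of hitting ≥ 1 interface per trimer is 5.84%,
leaving clear room for the required ten-fold margin, and the whole
experiment runs at desk scale; with d = 1.5 the fitted ensemble reaches
100% z = 1 accuracy (17× the null), and with d = 0 its hit rate is
statistically indistinguishable from the null.

## Known limitations

- The contact-area model is a sphere-overlap heuristic, not a
  Voronoi/power-diagram buried-surface computation; absolute areas
  should not be compared against Qcontacts outputs (import them
  instead).
- EVA is an approximation defined by the subtraction above.
- No mmCIF input, no hydrogen placement, no electrostatics beyond the pK
  lookups, no modelling of binding-induced conformational change.
- Training pools all pairs into one classifier per view; per-interface
  training is not provided.
- The i.i.d.-interfaces assumption of the null ignores that the three
  interfaces of a real trimer share chains and geometry.
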