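# Methods

## Reaction representation

A reaction must be fully atom-mapped; the map is the only atom
correspondence used (no automatic atom-to-atom mapping is attempted — an
unmapped or unbalanced input is an error naming the offending map numbers).
The Condensed Graph of Reaction (CGR) superposes both sides: each atom
stores charge, heavy-neighbor count and hybridization before and after the
transformation; each bond stores its order on both sides, `none` when the
bond exists on one side only. Hydrogens are implicit everywhere and
heavy-neighbor counts exclude them. Aromaticity is taken from the input
SMILES notation (lowercase atoms / aromatic bonds, with a ring-membership
validity check) rather than re-perceived, which keeps parsing
deterministic; hybridization is assigned by rule — aromatic flag →
`aromatic`, any triple bond or two double bonds → `sp`, one double bond →
`sp2`, else `sp3`.

An atom is *dynamic* when any of its before/after attributes differ or
when it touches a dynamic bond; this deliberately includes pure charge
changes so that zwitterion-neutral tautomerization (no dynamic bonds at
all) still yields nonempty reaction centers — the case where fragment
control is structurally blind and reaction type control must act.

## Signatures

The signature of a center is the canonical string of the subgraph
containing the center atoms plus all atoms within graph distance R,
together with every CGR bond among the included atoms. Atom tokens carry
`element:neighbors_before>>after:hyb_before>>after:charge_before>>after`;
bond tokens carry `order_before>>order_after`. Canonical ranks come from
iterative extended-connectivity refinement seeded with the atom token;
remaining symmetric cells are resolved by individualization with exhaustive
enumeration, keeping the lexicographically smallest depth-first
serialization (ring closures as numbered back-edges). Only *equality* of
signatures is ever consumed, so any injective deterministic canonical form
is adequate; the grammar here is self-defined and not byte-compatible with
other toolkits. Neighbor counts in atom tokens are molecule-wide degrees
(an atom keeps its parent-graph degree inside the extracted neighborhood),
so R = 0 distinguishes, say, a methyl from an ethyl substrate through the
center carbon's degree while remaining blind to everything beyond the
center atoms themselves.

The exhaustive tie-break is exponential in the size of a symmetric orbit;
reaction-center neighborhoods at the default R = 1 are small (typically
under 15 atoms) and the refinement resolves almost all ties first, so this
is never a cost in practice.

## Fragments and conditions

Structural descriptors are counts of simple linear paths of 2–4 atoms on
the CGR, canonicalized as the lexicographic minimum of the forward and
reversed serializations; a path and its reverse are one occurrence.
Fragment atom tokens carry the element only, while bond tokens keep the
full before/after order pair. This asymmetry is intentional: dynamic
*bonds* are visible to fragment control, but charge-only changes are not —
reproducing the documented failure mode in which tautomerizations whose
CGRs have no dynamic bonds pass a fragment filter trained on a different
reaction class. The signature grammar, by contrast, encodes charges, so
reaction type control catches exactly these cases.

Conditions contribute 17 columns: 15 solvent descriptors (Catalan SPP, SA,
SB; Kamlet–Taft α, β, π\*; ε and the functions (ε−1)/(ε+2), (ε−1)/(2ε+1),
(ε−1)/(ε+1); n² and (n²−1)/(n²+2), (n²−1)/(2n²+1); two user-definable
reserved slots, zero by default — the published 15-descriptor scheme names
only 13), the inverse absolute temperature 1/T in K⁻¹, and the organic
solvent molar ratio in percent (100 for a pure solvent). A bundled table
covers 13 common solvents from literature physical constants; user tables
(CSV, name + 15 values) extend or override it.

All descriptors are standardized to zero mean and unit variance with the
population (1/N) standard deviation, fitted on training data only;
constant columns map to zero. For Gaussian-process models the property is
standardized too and predictions are rescaled before any scoring.

## AD definitions: conventions and defaults

- Boundary conventions are inclusive on the inlier side: h = h\*, d = Dc,
  v = σ\*, |error| = 3×RMSE are all inliers; the 2CC probability rule is
  strict (> p\*), following its stated definition.
- Leverage uses the Moore–Penrose pseudo-inverse of XᵀX because fragment
  matrices are routinely rank-deficient; M in the default threshold
  h\* = 3(M+1)/N counts non-constant columns.
- Z-1NN distances are Euclidean on standardized descriptors;
  nearest-neighbour statistics exclude self-matches.
- RFR_VAR uses the population variance of the 500 per-tree predictions of
  the QRPR forest itself.
- The GPR kernel is a fixed RBF k(x,x′) = exp(−γ‖x−x′‖²), i.e. sklearn
  length_scale 1/√(2γ), with observation noise α; γ and α are grid-tuned
  by cross-validated RMSE, never by marginal-likelihood optimization, so
  the variance threshold σ\* remains comparable across folds.
- 2CC requires at least two training reactions in each Y-class; otherwise
  it records the degeneracy, emits a warning and decides all-inlier (the
  least harmful fallback for a method defined as a refinement of OZ).
- A change-free reaction (empty signature set) is an RTC outlier: a model
  of transformations has nothing to say about a non-transformation.
- OD returns 0.5 when either Y-class is absent (the zero-model value);
  ΔR²_AD uses R²_in = 0 for an empty inlier set so the pessimistic model
  scores −R²_all; OIR is 0 when either side of the domain is empty;
  AUC_AD counts tied error pairs one half.

## Tuning workflow

Nested cross-validation, 5 outer × 5 inner folds by default, seeded
uniform shuffling without stratification. Fragment vocabulary,
standardization, thresholds and sub-models are fitted inside each fold's
training data only. The forest's max_features is chosen by minimal inner
RMSE (grid 0.3/0.6/1.0); AD thresholds maximize OIR or OD on merged
inner-fold predictions, ties broken toward larger coverage, then first in
grid order. Threshold grids are 20 quantiles of the corresponding
inner-loop score distribution; the SVM grid is ν ∈ {0.01…0.5} × γ ∈
{10⁻⁴…1, 7 log-spaced points}; GPR α ∈ {10⁻³…10, 5 points} with the same
γ grid; 2CC max_features ∈ {0.1…1.0}; RTC radius ∈ {0…3}. The Y-outlier
labels for 2CC come from inner-loop errors; the labels used for OD
evaluation and the Perfect baseline come from the merged outer-loop
errors. Outer-fold predictions and decisions are merged before metrics are
computed. Composites AND a method's decision with RTC1 fitted on the same
training fold.

The ranking scheme assigns, per dataset and per characteristic (coverage,
ΔR²_AD as the performance-improvement measure, OD), a zero penalty to
methods strictly above the median and one penalty otherwise (NaN always
penalized); accepting at least one non-native reaction costs one penalty.
Methods are ordered by ascending penalty sum, ties alphabetical.

## Synthetic data

The generator emulates the statistical structure of curated kinetic
datasets: a few reaction-type templates (halide substitution, elimination,
Diels–Alder-like cycloaddition, zwitterion tautomerization, and a
substitution variant with a methanesulfonate leaving group), substituent
alphabets of at most 8 groups, solvents drawn from four common polar
solvents, temperatures uniform on 280–360 K. The property is a linear
function of fragment counts and conditions plus N(0, 0.3) noise; each
fragment's weight is derived from a salted hash of its canonical string
(≈40% of fragments active, weights ~N(0, 0.35²)), so differently seeded
train and test sets obey one common law. Condition terms are an
Arrhenius-like slope of −1500 K on 1/T and +2.0 on the solvent SPP value.

Gross Y-outliers are planted as an exact count (fraction × n rows, chosen
without replacement) with a ±6.0 offset. The exact count and the offset
magnitude matter: the 3×RMSE labelling rule is self-referential — the
planted errors inflate the very RMSE that defines them — and at 5%
contamination a Bernoulli draw can fluctuate to a fraction where no offset
is ever 3×RMSE-detectable (3·√0.1 ≈ 0.95 of the offset). At the defaults,
cross-validated forest errors flag essentially all planted outliers. The
novel-leaving-group suite adds a +2.5 systematic offset to its
methanesulfonate cluster, emulating a sub-population a model trained on
halides cannot predict.

What the generator does **not** emulate: real kinetic noise structure
(heteroscedastic, correlated within publications), realistic chemical
diversity (each suite has ≤ 12 scaffold/leaving-group combinations, so
descriptor space is far more clustered than a curated dataset), mechanism
changes within a type, or condition–structure interactions. Consequently a
passing benchmark here demonstrates the *machinery* — fold hygiene,
tuning, metric identities, type separation — not transferable performance
figures for any real reaction class; absolute coverage/OIR/OD values on
these suites should not be compared with values measured on experimental
data.

Hidden per-row flags (true type, planted outlier, novel cluster) are
written to a sidecar table so fitted models can never see them.

## Problem sizes

Default study conditions keep everything desk-scale: datasets of ~100
reactions, 500-tree forests (as in the benchmarked workflow), 5×5 nested
CV. A full default benchmark of one suite runs in a few minutes on one
CPU; the cross-application and baseline-identity analyses run in seconds.

## Known limitations

- No automatic atom mapping, stereochemistry, or RDF/RXN input.
- Signature strings are canonical within this package only.
- The 1-SVM ν-property (training outlier fraction ≤ ν) is asymptotic;
  small training sets violate it by O(1/n).
- GPR scales as O(n³); it is intended for datasets of at most a few
  thousand reactions.
- The two reserved solvent-descriptor slots default to zero, which after
  standardization contributes nothing; they exist for users who know what
  their remaining two descriptors should be.
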