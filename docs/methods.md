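# Methods

`gridqsar` implements the ligand-based quantitative half of a
structure-guided kinase-inhibitor campaign: grid-based molecular fields
(CoMFA/CoMSIA) over a pre-aligned congeneric series, PLS regression with
cross-validated component selection and a full internal/external validation
battery, model-stability (progressive scrambling) and applicability-domain
analysis, StDev*Coeff contour fields, and the arithmetic aggregation of
end-state binding free energy components (MM-PB(GB)SA, LIE). This note
records the models, the parameters that matter, the numerical choices, and
what the synthetic data generator does and does not emulate.

## Molecular fields

Molecules arrive aligned (common-substructure alignment is upstream and out
of scope). Fields are evaluated on a rectangular lattice built over the
union bounding box of all atoms, expanded by `margin` (default 4.0 Å — the
classic choice of a probe-reachable shell; the literature default spacing
2.0 Å is kept) and ordered x-fastest.

**CoMFA steric** is the Lennard-Jones energy of an sp³-carbon-like probe
(radius 1.52 Å, well depth from the carbon entry of the built-in table,
charge +1):

    E_S(q) = Σ_i ε_i [ (R_i/r_iq)¹² − 2 (R_i/r_iq)⁶ ],
    R_i = r_vdw,i + r_vdw,probe,  ε_i = sqrt(ε_i ε_probe)

with arithmetic-radius / geometric-well-depth combination. The per-point
sum is clamped to ±30 kcal/mol (the conventional energy tolerance); a grid
point on an atom center clamps to +30 rather than propagating a
singularity. Caps are applied after summation over atoms.

**CoMFA electrostatic** is the Coulomb energy
`332.0636 · Σ_i q_probe q_i / (ε(r) r)` with a distance-dependent
dielectric ε(r) = r by default (constant ε = 1 selectable), clamped the
same way. At grid points where the steric field is clamped at +30 for a
molecule (the point is inside that molecule), the electrostatic entry is
replaced by the column mean over the non-buried molecules — the classic
convention of not evaluating electrostatics inside atoms — and flagged;
a plain "clamp" policy is selectable.

**CoMSIA similarity fields** use Gaussian attenuation with no cutoff:

    A_k(q) = − Σ_i w_probe w_i,k exp(−α r_iq²),   α = 0.3 Å⁻²

with property weights per kind: steric ∝ r_vdw³, electrostatic = partial
charge, hydrophobic from the built-in atom table, donor/acceptor flags as
0/1. α = 0.3 is the literature default for similarity-index fields.

Per-atom parameters (Bondi radii, Amber-style well depths, coarse
hydrophobic weights, N/O acceptor and N/O–H donor rules) live in a small
element table, user-overridable via YAML, because the original analyses
delegate them to a commercial force field whose exact values are not
public. Exact parity with commercial field engines is therefore not
expected and not asserted.

**Column filtering.** Descriptor columns with sample SD (ddof = 1) below
`min_sigma` (default 2.0 kcal/mol; the same numeric threshold is applied to
unitless CoMSIA columns) are dropped. In addition — a design choice of this
package — CoMFA columns whose value hits the ±30 cap for at least one
molecule are dropped by default (`drop_clamped`): such points sit partially
inside the union molecular volume, and their across-series variance is a
discontinuous artifact of the clamp, not a smooth field response. Keeping
them measurably degrades cross-validated component selection (the LOO q²
profile keeps creeping upward as extra components mine the clamp kinks).

## PLS model

PLS1 by NIPALS on mean-centered X and y, no autoscaling and no block
scaling between field kinds by default (an optional flag equalizes kind
variances). For a single response each NIPALS component is a closed-form
power step, so the fit is deterministic; deflation stops early when the
residual covariance ‖X_dᵀ y_d‖ falls below 1e−10 of its initial scale
(rank-deficient X).

Training statistics: r² = 1 − RSS/SS; SEE = sqrt(RSS/(n−c−1));
F = (r²/c)/((1−r²)/(n−c−1)). Cross-validation is leave-one-out with a full
refit per left-out sample: q² = 1 − PRESS/SS, SEP = sqrt(PRESS/(n−c−1)).
The (n−c−1) denominators follow the SYBYL-style conventions; alternates are
one flag away. The optimal number of components maximizes LOO q², with ties
broken toward fewer components (smallest c within 0.005 of the maximum —
parsimony practice).

Field contributions of kind k are Σ_j |b_j|·sd_j over the columns of that
kind, normalized to 100 %. Contour fields map b_j·sd_j (StDev*Coeff) back
to grid points; display isolevels default to the 80th/20th percentiles of
the nonzero values per kind.

## Validation battery

Internal fitness: χ² = Σ(y−ŷ)²/y² following the printed rendering of the
chi-squared fitness measure (a /y variant is selectable; nothing downstream
depends on the choice); RMSE with the n−1 denominator; MAE; RSS.

External (test-set) predictivity, with r² the squared Pearson correlation
of observed vs predicted:

- through-origin slopes k = Σyŷ/Σŷ², k′ = Σyŷ/Σy², with the conventional
  0.85–1.15 acceptance window;
- r0² and r′0² from through-origin fits in both directions, with
  |r0²−r′0²| < 0.3 and (r²−r0²)/r² < 0.1;
- rm² = r²(1 − sqrt(|r²−r0²|)), its reversed-axis twin, their mean and
  absolute difference (rm², r̄m² > 0.5);
- QF3² = 1 − [Σ_test(y−ŷ)²/n_test]/[Σ_train(y−ȳ_train)²/n_train] (> 0.6),
  which is 1 for perfect test prediction regardless of test-set
  composition;
- Lin's concordance correlation coefficient (population moments), which
  penalizes location/scale shifts that Pearson r² ignores.

Every metric is cross-checked in the tests against an independently coded
closed-form recomputation on seeded random vectors (1e−10).

**Progressive scrambling.** The response is perturbed at graded strengths
s ∈ [0, 1]: the activity-sorted y is partitioned into consecutive bins of a
size drawn uniformly in [bin_min, bin_max] (defaults 2 and 10), each bin is
permuted with probability min(1, 2s), and a further max(0, s−0.3) fraction
of entries is swapped globally, so the draws span r²_yy′ from 1 down to
≈ 0. For each draw and component count the LOO q² and SDEP of the perturbed
response are recorded; per component count, Q² and cSDEP are read off a
quadratic fit against r²_yy′ at the critical perturbation 0.85, and the
sensitivity slope dq²/dr²_yy′ is the fit's derivative there. cSDEP is
evaluated at the same critical point as the slope (the cited methodology
leaves this open; one consistent convention is used). Slopes above 1.2 flag
instability. Strength 0 is the identity, so the first draw reproduces the
unperturbed q² exactly.

**Applicability domain.** Leverage is computed in latent-component space:
h_i = 1/n + t_iᵀ(T_cᵀT_c)⁻¹t_i on centered training scores, so the
training centroid sits at h = 1/n; test compounds are projected with the
same centering. The warning leverage is h* = 3(p+1)/n with p the number of
components. Standardized residuals are scaled by the training residual SD;
a compound is flagged outside the domain when h > h* or |std. residual| > 3
(the Williams-plot rule).

## End-state energetics

The MM-PB(GB)SA layer is pure aggregation over solver output (no PB/GB
solver, no trajectory parsing): component means over the final `last_n`
frames (default 200, i.e. a 2 ns tail at 10 ps/frame) compose as

    ΔG_gas = ΔE_vdW + ΔE_ele,  ΔG_solv = ΔG_PB|GB + ΔG_SA,
    ΔTOTAL = ΔG_gas + ΔG_solv

with the entropy term −TΔS structurally excluded (no field; an optional
user-supplied adjustment is applied only on request). Reports round to two
decimals for table parity while full precision is stored; published tables
of this kind show up to 0.01 rounding drift between printed totals and
their printed components, so comparisons tolerate ±0.01 per term.

LIE: ΔG_bind = α(⟨V_vdW⟩_bound − ⟨V_vdW⟩_unbound) + β(⟨V_ele⟩_bound −
⟨V_ele⟩_unbound) with the neutral-ligand literature scaling α = 0.181,
β = 0.43 as defaults.

Per-residue decomposition tables get NA for residues farther than 4.0 Å
from the ligand or with |contribution| below a negligibility threshold
(default 0.05 kcal/mol — the convention behind published NA entries is
unstated, so the threshold is configurable); the distance column is
optional, in which case only the negligibility rule applies.

## Synthetic data generator

The generator emulates the study conditions every pipeline stage assumes:
~40 pre-aligned analogs sharing a rigid common core, activities spanning
3 log units that are linear in a small number of grid-field values plus
Gaussian noise (SD 0.2 log units), and stationary per-frame energy series
(200 frames). All generators are bit-reproducible under their seed and the
defaults are the study conditions — they are not tuned per test.

Structural variation across the series is deliberately low-dimensional.
A fixed set of R-group sites (positions in a 1.5–4 Å shell off the
scaffold's attachment atom; elements, base charges and donor/acceptor flags
drawn once per series) is shared by all molecules; each molecule carries a
small latent trait vector (default 3 traits) that linearly scales every
site's partial charge, steric weight (through the LJ well depth, so the
steric field scales linearly) and hydrophobic weight. Because all grid
fields are additive over atoms, the descriptor matrix is then an exact
low-rank function of the traits, which makes the planted-recovery problem
well-posed: the planted rank equals the trait count and is a meaningful
target for component selection. Charges are zero-sum per molecule.

What this does *not* emulate: real analog series vary by discrete
substituent swaps (atoms appear, move and change element between
compounds), which injects high-rank, partly unpredictable descriptor
variance; conformational and alignment noise; and correlated, drifting MD
energy series. Passing the recovery tests therefore shows the pipeline is
correct and well-behaved in its intended regime, not that any real series
will reach the same q².

The planted activity is y = baseline + Σ_j w_j F_ij + ε on post-filter
columns (so the signal survives filtering), with planted columns drawn by
default from smoothly varying high-variance columns (no single molecule
dominating a column's variance). The realized activity vector is affinely
rescaled so its range equals the requested span (3 log units) centered on
pIC50 = 6; the planted truth (columns, effective weights, rank, pre-noise
signal) is returned for recovery tests.

## Problem sizes and runtime choices

The test suite and the acceptance script run the full pipeline at the study
scale (40 molecules, 2.0 Å spacing, ~1500 raw / ~150–350 kept columns,
30/10 split, LOO with explicit refits, 50-draw scramble control), which
completes in seconds; progressive scrambling in the CLI defaults to 100
draws. Degenerate inputs fail loudly: zero-variance response, all columns
filtered, singular score covariance, empty ensembles and malformed files
all raise with actionable messages rather than propagating NaNs.

## Known limitations

- The built-in atom parameter table is a coarse element-level surrogate for
  a commercial force field; absolute field values (and hence field
  contribution percentages) will differ from commercial engines even on
  identical structures.
- Test-set selection is stratified-random by activity tertile only; the
  "structural diversity" criterion sometimes used in dataset curation is
  not algorithmically enforced.
- MOL2 reading covers the Tripos MOLECULE/ATOM records (coordinates,
  SYBYL-type-derived elements, charge column) — enough for aligned-series
  input, not a general MOL2 round-tripper.
- Progressive scrambling's perturbation schedule is one defensible
  realization of the cited methodology; published Q²/cSDEP values from
  other engines are comparable in spirit, not digit-for-digit.
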