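# Methods

## Problem and scope

Hydrogen-bond acceptor (HBA) and donor (HBD) strengths are modelled as Gibbs
free energies of 1:1 complex formation in CCl₄ against fixed reference
partners (4-fluorophenol for acceptors, acetone for donors).  The package
covers everything *around* the quantum chemistry: site perception, fragment
generation, descriptors, calibration, database curation and statistics, and
Gaussian-process models with an applicability domain.  The quantum-chemistry
stages themselves (semi-empirical charges and localized lone pairs,
conformer generation, DFT optimizations, Hessians, high-level single points,
implicit solvation) are consumed as numbers via SDF property tags, never
executed.

## Molecular representation

Molecules are kekulized throughout: only integer bond orders 1–3, no
aromatic bond type.  This makes heterocycles — for which aromaticity
perception is framework-dependent — compare consistently when fragments are
deduplicated by canonical SMILES.  `MoleculeRecord` stores the element,
formal charge and non-graph hydrogen count per atom; hydrogens are normally
kept as explicit graph atoms (`from_smiles` adds them) because donor
perception needs the donated hydrogen's index and descriptors include
hydrogens in the shells.  Internal indexing is 0-based, SDF tags are
1-based; energies are stored in kJ/mol with explicit unit conversion on
read (1 Hartree = 2625.4996 kJ/mol).

The tag names of external strength databases are not standardized, so the
reader resolves them through a tag dictionary (JSON-overridable); unknown
dictionary keys fail loudly rather than being silently ignored.

## Site rules

Acceptors: every oxygen; every nitrogen unless it has a covalent bond of
any order to an oxygen (this removes nitro, nitroso and N-oxide nitrogens
while keeping, e.g., both nitro oxygens).  Donors: O–H, N–H (one site per
heavy atom; an NH₂'s donated hydrogen is the lowest-index attached H), S–H,
and terminal alkyne C–H (sp carbon in a C≡C bearing an H).  All patterns
are R-substituted: the heavy atom must have at least one heavy-atom
neighbour, so bare water, ammonia and H₂S are not sites.  Secondary amide
N–H is treated as an NH donor — donor databases contain hundreds of amides,
so the N–H pattern is read broadly rather than restricted to amines.
Protonation states are taken as given; charged fragments are removed later
by the neutrality filter, not here.

## Fragment generation

Around each site the substructure up to the 4th topological shell is cut
out.  Case priority: if the site atom is in a ring, the whole fused ring
system plus side chains within 4 bonds are taken (*ring*); else if any ring
atom lies within 3 bonds, that complete ring system is added to the 4-bond
neighbourhood (*ring_sidechain*); else the 4-bond neighbourhood alone
(*chain*).  Ring systems are rings merged when they share a bond.  Ring
atoms at exactly shell 4 whose system is not otherwise included are
substituted by sp³ carbon caps (bonds to them become single): shell
occupancy is preserved without importing ring context.  This substitution
rule is applied uniformly in all three cases, a deliberate generalization of
the chain-case rule so that no ring is ever cut below the 4th shell.  All
open valences are capped with hydrogens; severed bonds of order *n* add *n*
hydrogens to the kept atom.

Fragments are identified by the canonical SMILES of the kekulized,
hydrogen-collapsed graph.  Deduplication sums incidences and concatenates
parent identifiers.  Filters (first failing rule reported): allowed elements
{H, C, N, O, F, Cl, S, Br, I}; ring count ≤ 3; molecular weight < 300 Da;
site count for the role ≤ 4; net formal charge 0.  The site-count bound is
inclusive of 4 because shipped databases contain fragments with up to four
acceptor sites.  An optional halogen-corrected weight mode counts Br/I at
the mass of Cl; the default is the plain molecular weight.

Diversity selection works per element-by-topology class (O/N × case for
acceptors; O/N/S/Csp × case for donors): MACCS structural keys, Tanimoto
distance, cluster count max(1, ⌊N/25⌋).  The original work used a
proprietary clustering component; here clustering is a deterministic
maximum-dissimilarity procedure — the first seed maximizes total distance,
subsequent seeds maximize the minimum distance to existing seeds, points go
to the nearest seed, medoids are refined to convergence — and from each
cluster the `keep_central` (default 3) members with the smallest summed
intra-cluster distance are kept, capped at `cluster_cap` (default 30).
Both counts are exposed because the published description does not fix
whether the 30-fragment cap applies per cluster or per class.  The
procedure consumes no randomness, so results are reproducible by
construction.

## Descriptors

Six radial families describe the site atom; all atoms including hydrogens
populate the shells.  With q the partial charges, c the center, shell k the
atoms at graph distance exactly k, d_cj Euclidean distances and r a grid:

* **CS** — mean charge per shell, k = 1..K.
* **sorted shell** — per shell, the individual charges in descending
  substituent priority, truncated/zero-padded to W slots.  Priority is
  descending (atomic number, atomic mass, recursively compared neighbour
  environments to depth 3), ties broken by descending charge then input
  index — a deterministic ordering in the spirit of CIP rules without the
  full stereochemical machinery, which ordering shell members does not
  need.
* **MS** — summed standard atomic weights per shell.
* **GACF** — Σ_{j∈shell k} q_c·q_j.
* **CRDF** — g(r) = Σ_{j≠c} q_j·exp(−β(r − d_cj)²) on the inclusive grid.
* **CACF** — the same smoothing applied to the center-anchored products
  q_c·q_j, split into a positive-product and a negative-product block.
  The center-anchored form follows from the descriptors being *atomic*
  reactivity descriptors.

Defaults: K = 4 shells, W = 4 slots, grid 1.0–8.0 Å in 0.5 Å steps
(15 points), β = 4 Å⁻².  The grid spans the diameter a 4-shell fragment can
reach; every constant is a `DescriptorSpec` field.  The shell-averaged
families are undefined when a requested shell is empty; strict mode raises
a `DescriptorInapplicableError` — sites lost this way are dropped from the
training matrix, mirroring the data loss such sites incur in practice —
and zero-filling is opt-in.  Charges come from the record, then from the
named property tag (QC-derived charges such as CM5 when available), then
from an electronegativity-equalization fallback with a warning:
q_i = 0.1·Σ_bonds(χ_neighbor − χ_i) with Pauling electronegativities, which
conserves molecular charge exactly.

## Energetics and calibration

ΔG_sol,QC = ΔE_high-level DFT + ΔG_RRHO + ΔδG_solv with each
Δ = complex − molecule − reference.  Raw composed values carry a large
systematic error (overly repulsive thermal and solvation contributions);
the affine calibrations HBA: 0.56·x − 20.12 and HBD: 0.63·x − 20.94 kJ/mol
map them onto the experimental scales and are stored at their printed
two-decimal precision as canonical defaults.  `fit_calibration` refits by
unweighted ordinary least squares (no weighting scheme is assumed) and
reports k-fold stability: each fold's slope/intercept comes from refitting
on the other k−1 folds, and their relative standard deviations quantify
calibration stability alongside pre-/post-calibration RMSE.  Refits never
silently replace the defaults.

## Curation and statistics

Complex entries are kept when all QC stages converged, the hydrogen-bond
X–H distance (the donated-hydrogen-to-acceptor-heavy-atom distance — the
reading consistent with 2.0–2.65 Å magnitudes) does not exceed 2.40 Å
(acceptor complexes) or 2.65 Å (donor complexes), and the lowest normal
mode is ≥ −50 cm⁻¹.  The distance is read from its tag when present and
otherwise recomputed from the complex 3D coordinates via tagged atom
indices.  Summaries report n/mean/sd/min/max and histograms (default bins
1 kJ/mol and 0.05 Å) pooled or per functional class; distance–energy
Pearson correlations can be restricted by site element, where "oxygen
donors" are selected by donor heavy-atom element, not class string.

## Gaussian-process models

K = C·M + W.  C is optimized in [10⁻³, 10³] and the length scale in
[10⁻², 10²] by restarted (5 by default) maximization of the log marginal
likelihood; ν is fixed per configuration at ½, 3/2 or 5/2; W is a white
kernel with noise fixed at 0.05.  Targets are standardized to zero mean and
unit variance before fitting, so the 0.05 noise lives on the standardized
scale — on raw kJ/mol it would be negligible against the ≈2.6 kJ/mol
uncertainty of the underlying data.  The γ scale inside the Matérn form is
kept as a configurable constant (default 1, under which the ν = 3/2 form is
the standard Matérn); for fitting it is absorbed into the length scale.
`kernel_eval` implements the closed forms natively and is cross-checked
against the scikit-learn kernels that back the fitted models.

Predictions return the back-transformed posterior mean and a *variance
estimate* defined as 1.96·σ, the 95 % confidence half-width; raw σ is also
available.  The applicability domain flags a query as outside when its
variance estimate exceeds 4.2 kJ/mol (HBA) or 3.2 kJ/mol (HBD), the plateau
values fully trained models reach; the boundary is non-strict.

Cross validation uses deterministic shuffled k-fold splits (default k = 10)
with pooled metrics (RMSE, R², Spearman, mean variance estimate) over the
concatenated held-out predictions.  Learning curves grow nested training
subsets in 10 % steps under a fixed shuffle; each fraction's model is
evaluated on the full data set, so the terminal point reports training-set
performance and smaller fractions mix seen and unseen points — this makes
the variance-estimate decline across fractions directly interpretable,
which evaluating only on the (shrinking) training fraction would not.

## Synthetic data

The fixture generator enumerates small molecules from a scaffold ×
substituent grammar covering alcohols, amines, ethers, carbonyls,
N-heterocycles, thiols and alkynes — every site kind and every topology
case — with charge-conserving pseudo-charges and deterministic
distance-geometry 3D coordinates (fixed seeds; a zig-zag layout backstops
rare embedding failures).  Synthetic strength data draw a latent
ΔG_QC ~ U(−60, 10) kJ/mol per site and set
y = 0.56·ΔG_QC − 20.12 + N(0, 2.6) by default, matching the slope,
intercept and residual scale of the acceptor calibration; component triples
compose exactly to the latent value; the X–H distance is
2.0 + 0.15·(ρ·z_y + √(1−ρ²)·ε) Å with z_y the target standardized by its
theoretical moments, giving population Pearson correlation exactly
ρ = 0.5 by default, the magnitude observed for acceptor databases.

The generator emulates the *statistical* structure of the problem, not its
physics: pseudo-charges are not CM5 charges, targets are independent of the
descriptors, and geometries are single conformers of toy molecules.
Passing tests therefore demonstrate correctness of the machinery —
parsing, perception, fragmentation, descriptor algebra, calibration,
curation, GP inference — and parameter recovery under known generative
models, not predictive accuracy on real chemistry.

## Numerical choices and limitations

* Problem sizes: test and acceptance runs use hundreds of molecules/sites
  and GP fits on 100–150 points, the scale at which every property checked
  (recovery, monotonicity, positive-definiteness) is already stable.
* Kernel matrices are positive definite by construction (white noise on the
  diagonal); a singular fit raises with the condition number.
* Degenerate inputs: zero target variance is handled by unit scale;
  zero-variance calibration abscissae and sub-3-point fits are errors;
  empty fragment classes are skipped with a log entry.
* The exact published fragment sets (3326/1088) are not reproducible: they
  depend on a licensed compound database and a proprietary clusterer.
  Likewise the exact 151/115-dimensional tuned descriptors and the CV RMSEs
  that depend on them are out of reach without the tuned parameter sets;
  the descriptor machinery exposes every parameter instead.
* Tautomer enumeration, pKa-based protonation, non-alkyne C–H donors, SDF
  V3000 and 2D depiction are out of scope.
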