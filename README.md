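# hbstrength

Modelling of hydrogen-bond acceptor (HBA) and donor (HBD) strengths from
quantum-chemically derived complexation free energies.

Hydrogen-bond strength can be expressed as the Gibbs free energy ΔG of 1:1
complex formation against a common reference partner — 4-fluorophenol for
acceptors, acetone for donors — in CCl₄.  Computing these free energies
quantum-chemically for thousands of fragments yields training databases far
larger than any experimental scale, and machine-learning models trained on
them predict per-site strengths for arbitrary molecules.  `hbstrength`
implements the modelling stack around such databases:

* **Site perception** — HBA sites are every oxygen and every nitrogen not
  covalently bound to an oxygen; HBD sites are R–OH, R–NH₂, R¹–NH–R²,
  R–SH and terminal alkyne C–H.
* **Fragment generation** — the substructure up to the 4th topological shell
  around each site, with three cases (chain / ring + sidechain / ring) and
  whole fused ring systems, kekulized canonical-SMILES deduplication with
  incidence counting, organic-element/ring-count/MW/site-count/neutrality
  filters, and per-class diversity selection by Tanimoto clustering on MACCS
  keys (clusters = class size / 25, most central members kept).
* **Radial atomic descriptors** — six families for the site atom built from
  per-atom partial charges, topological shells and 3D distances: sorted
  shell, charge shell (CS), spatial charge RDF (CRDF), spatial charge
  autocorrelation (CACF, split by product sign), mass shell (MS) and
  topological charge autocorrelation (GACF), concatenable into a
  combinatorial descriptor.
* **Energetics** — composition of ΔG_sol,QC = ΔE_high-level DFT + ΔG_RRHO +
  ΔδG_solv (each Δ = complex − molecule − reference) and the affine
  calibrations onto experiment:

      HBA ΔG (kJ/mol) = 0.56 · ΔG_sol,QC − 20.12
      HBD ΔG (kJ/mol) = 0.63 · ΔG_sol,QC − 20.94

* **Curation & statistics** — complex filters (X–H ≤ 2.40 Å for acceptors /
  2.65 Å for donors, lowest normal mode ≥ −50 cm⁻¹, convergence), database
  summaries, and distance–energy Pearson correlations.
* **Gaussian-process regression** — kernel K = C·M + W (Matérn with fixed
  ν ∈ {½, 3/2, 5/2}, C ∈ [10⁻³, 10³], length scale ∈ [10⁻², 10²], fixed
  white noise 0.05), tenfold CV, learning curves, and a variance-based
  applicability domain: a prediction whose variance estimate (1.96 σ)
  exceeds 4.2 kJ/mol (HBA) or 3.2 kJ/mol (HBD) is flagged untrustworthy.
* **Synthetic fixtures** — deterministic toy molecules with
  electronegativity-equalization pseudo-charges, distance-geometry 3D
  coordinates, and linear-model targets, so every stage runs without any
  quantum-chemistry software.

## Worked example

```python
from hbstrength import *

mol = MoleculeRecord.from_smiles("CC(=O)NCCO", name="N-(2-hydroxyethyl)acetamide")
for s in find_sites(mol, "both"):
    print(f"  {s.role}  atom {s.atom_index:2d} ({mol.atoms[s.atom_index][0]})  {s.site_kind}")

frag = extract_fragment(mol, find_acceptor_sites(mol)[0])
print("fragment:", frag.canonical_key, "| case:", frag.topo_case)
print("calibrated strength of dG_sol,QC = -25.0:",
      calibrate(-25.0, default_calibration("HBA")))
```

prints

```
  HBA  atom  2 (O)  O_acceptor
  HBA  atom  3 (N)  N_acceptor
  HBA  atom  6 (O)  O_acceptor
  HBD  atom  3 (N)  NH_donor
  HBD  atom  6 (O)  OH_donor
fragment: CCNC(C)=O | case: chain
calibrated strength of dG_sol,QC = -25.0: -34.120000000000005
```

The amide nitrogen is both an acceptor and a donor; the hydroxyl counts
once each way; the 4-shell cut around the carbonyl oxygen is the
N-ethylacetamide fragment.  A raw quantum-chemical ΔG_sol,QC of −25 kJ/mol
maps to a calibrated acceptor strength of −34.1 kJ/mol.

Training a GP on strengths and gating predictions by the applicability
domain:

```python
import numpy as np
from hbstrength import fit_gpr, predict_gpr, ad_check, KernelConfig

rng = np.random.default_rng(0)
X = rng.uniform(-4, 4, size=(120, 1))
y = -8.0 + 5.0 * np.sin(X[:, 0]) + rng.normal(0, 0.5, 120)   # strengths, kJ/mol
model = fit_gpr(X, y, KernelConfig(nu=1.5), seed=0, role="HBA")
mean, var_est = predict_gpr(model, np.array([[0.5], [3.0], [9.0]]))
```

```
x= 0.5  dG =  -5.70 kJ/mol   var.est =  1.50   AD: inside
x= 3.0  dG =  -7.46 kJ/mol   var.est =  1.48   AD: inside
x= 9.0  dG = -10.19 kJ/mol   var.est = 11.02   AD: outside
```

The query far outside the training range reverts toward the prior and its
variance estimate exceeds the 4.2 kJ/mol acceptor threshold, so the
prediction is flagged as outside the applicability domain.

A `hbstrength` command-line interface wraps the same functionality
(`convert`, `sites`, `fragment`, `describe`, `calibrate`, `curate`,
`stats`, `train`, `predict`, `cv`, `learning-curve`, `simulate`); run
`hbstrength --help`.

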