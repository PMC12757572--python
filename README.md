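# porescale

Radial scaling analysis of ion-channel pore architecture: atom-packing law
fitting, atom-packing entropy, hydropathic moment features, and
machine-learning classification of disease-associated mutation hotspots.

## The problem

Voltage-gated sodium channels (NaVChs) are built from a central pore domain
(PD) surrounded by four voltage-sensor domains (VSDs). Around any point
**p** on the pore axis, the number of atoms N(l) inside a probe ball of
radius *l* grows sigmoidally, and the radius at which its curvature changes
sign — the inflection point *l<sub>i</sub>* — marks the characteristic PD
size and the PD/VSD interface. `porescale` turns this observation into a
quantitative toolbox for structural biologists and channelopathy
researchers: it fits a generalized logistic packing law per pore point,
derives interface scales, entropy and hydropathic-moment features, maps
mutation annotations onto the structure, and trains a transparent SVM that
separates pain-disease-associated mutation hotspots from neutral or benign
locations.

## The model

The cumulative atom count obeys the growth law

    dn/dl = n/ζ − n^(ν+1)/(ζ K^ν),      ν = ζ/ξ,

with repulsive range ζ [Å], attractive range ξ [Å], and carrying capacity
K [atoms]. Its closed form is

    n(l) = K (1 + ν ε/ε_i)^(−1/ν),      ε(l) = ε₀ e^(−l/ξ),

where ε_i = ε(l_i) and the inflection point is
l_i = ξ ln[((n₀/K)^(−ν) − 1)/ν] + l₀. Derived scales and fields:

* **l_i,b = l_i − ξ ln[(2^ν − 1)/ν]** — the radius holding exactly K/2
  atoms (equal to l_i under mean-field conditions ν = 1);
* **d_f = ∂ln n/∂ln l** — the intrinsic (unit-mass fractal) dimension,
  equal to l_i/(ξq) at the inflection point, with q = 1 + ν;
* **S = (1 − Σ p_α^q)/(q − 1)** — the nonextensive atom-packing entropy of
  the occupancy p_α ∝ n(l_α)/K on an 800-point scale grid, with escort
  distribution π_α ∝ p_α^q;
* **hydropathic moments h_j(l)** — radial moments of binarized per-atom
  hydropathy weights (±0.5 kcal, noise-perturbed), with even orders probing
  rotational ("inertia") and odd membrane-perpendicular orders
  translational ("conductivity") constraints;
* **ψ_±, Δψ, I_j = Δψ/l, ϕ_j = ln χ_j** — log-slopes of the
  hydrophilic/hydrophobic moment components, their imbalance, the
  interfacial coupling strength, and the log composite susceptibility;
  {ϕ_2k, I_2k, ϕ_2k+1,⊥, I_2k+1,⊥} for k = 0..5 are the 24 features of the
  two-stage (per-pore-point, then median-summarized) RBF-SVM classifier.

A synthetic-data module draws atom clouds by inverse-CDF sampling of n(l)
with a radius-dependent hydrophilicity profile, so every stage of the
pipeline is testable against known ground truth without downloads.

## Worked example

```python
import numpy as np
from porescale import (GeneratorConfig, sample_structure, radial_profile,
                       build_scale_grid, fit_packing, packing_entropy)
from porescale.mutations import entropy_midpoint

config = GeneratorConfig(n_total=10000, seed=1)   # truth: ζ=5, ξ=10 Å
structure, truth = sample_structure(config)
profile = radial_profile(structure, np.zeros(3))
grid = build_scale_grid(profile)                  # 800 scale indices
fit = fit_packing(profile, grid)
ent = packing_entropy(fit, grid)
l_emp, l_theo = entropy_midpoint(profile, fit, grid)
```

This prints (via the obvious f-strings):

```
n_total = 10000,  R̄ = 1.52 Å,  L = 93.55 Å
ζ = 4.66 Å (truth 5),  ξ = 10.20 Å (truth 10),  K = 10121 (truth 10101)
l_i = 47.46 Å (truth 47.78),  l_i,b = 49.54 Å,  l_> = 59.13 Å
ν = 0.457,  q = 1.457,  MAE = 9.21e-04
S = 2.058,  S_max = 6.111,  Ξ = 10.09 Å
l* (empirical) = 49.37 Å,  l* (model) = 49.36 Å
```

The fit recovers the generator's interaction ranges and capacity to a few
percent; the flipping-coin midpoint l* (the radius inside which a mutation
is equally likely to fall as outside) sits on the characteristic bound
l_i,b, as expected when n(L) ≈ K; and the entropy S stays below its
hydrophobic-core (Shannon) limit S_max.

The same pipeline runs from the shell:

```bash
porescale simulate --n-total 10000 --seed 1 --out run
porescale all --structure run/synthetic.pdb --mutations mutations.csv --out run
```

Stage outputs are TSV tables (`fits.tsv`, `exponents.tsv`,
`clustering.tsv`, `ml_scores.tsv`, ...) plus a JSON run manifest that
caches completed stages by content hash.

For real structures, supply a protonated, membrane-oriented PDB file
(z = membrane normal, extracellular side up) and a mutation CSV with
columns `chain, residue_seq, residue_name, label`, where label is one of
GoF, LoF, neutral, benign, pathogenic, VUS.

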