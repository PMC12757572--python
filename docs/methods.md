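# Methods

This note documents the model implemented by `porescale`, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not establish about real structures.

## Atom-packing law

Around a pore point p, the atom count n inside the open ball B(p, l)
(strict r < l membership; ties broken by strict inequality) is modeled by
the generalized logistic growth law dn/dl = n/ζ − n^{ν+1}/(ζK^ν), ν = ζ/ξ.
ζ is the effective range over which atoms repel (hydrophilicity-driven,
water-structuring), ξ the range over which they attract
(hydrophobicity-driven); K caps the number of atoms the structure can
accommodate. The closed form n(l) = K(1 + ν ε/ε_i)^{−1/ν} with
ε = ε₀e^{−l/ξ} is used everywhere; for ν < 1e−8 the exponential limit
n = K e^{−ε/ε_i} replaces it (the closed form degenerates numerically).
ε₀ := 1 kcal/atom and the entropy constant k := 1; both cancel in every
dimensionless output.

Differentiating the closed form gives, with u = ε/ε_i,

* growth rate dn/dl = n·u / (ξ(1+νu)), globally maximal at l_i (u = 1);
* curvature d²n/dl² = (n·u/ξ²)(u−1)/(1+νu)², positive below and negative
  above the inflection point;
* intrinsic dimension d_f = (l/ξ)·u/(1+νu), hence d_f(l_i) = l_i/(ξq).

These are the forms the code and the tests assert; they satisfy the
self-similarity identity (1/K)dn/dl = (ε/(ε_i ξ))(n/K)^{ν+1} to machine
precision.

## Pore path and scale grid

The pore axis is approximated by slab-wise in-plane geometric centers: a
pore point sits at ((x̄, ȳ), z) for z on a 0.1 Å grid (default), with
(x̄, ȳ) averaged over atoms within |z_a − z| ≤ 5 Å and a fall-back to the
whole-molecule center when a slab is empty. The per-point radial profile
records R̄ (nearest-atom distance; B at l = R̄ is empty by construction),
L (radius of the smallest all-enclosing ball), and the radial size
s := L − R̄, so the uniform scale grid l_α = R̄ + (α/N_α)s, α = 1..800,
spans exactly (R̄, L] and the cumulative count reaches n_total at the last
grid point.

## Fitting

The fit minimizes the mean absolute error between n(l_α)/n_total and
N(l_α)/n_total over the grid. Four parameters are free — log ζ, log ξ,
log(K/n_total), and l_i — with bounds ζ, ξ ∈ (0.1, 100) Å and
K ∈ [n_total, 10·n_total], explored by a short fixed-seed multi-start of
Nelder–Mead (tolerance 1e−10). l_i is parameterized directly rather than
anchored through a hard initial condition: anchoring the curve through the
first occupied grid count (one or two atoms of Poisson noise) was found to
bias ζ by tens of percent on sampled clouds. After the fit, the reported
initial condition is l₀ := R̄ with n₀ := n(R̄) on the fitted curve, which
makes the closed-form inflection expression reproduce the fitted l_i
exactly. l_> (most negative curvature) is found by a grid scan refined
with a bounded scalar minimization. MAE is the fit-quality metric;
goodness-of-fit p-values are not computed. Non-converged fits are flagged
and excluded downstream.

## Entropy

The occupancy p_α ∝ n(l_α)/K and escort π_α ∝ p_α^q (q = 1 + ν) define the
Tsallis entropy S = (1 − Σp_α^q)/(q − 1); at q = 1 the Shannon form is
used directly. S_max is the Shannon entropy of the ν→0 exponential
occupancy e^{−ε_α/ε_i} on the same grid — the hydrophobic-core limit in
which repulsion has collapsed. The finite-size corrected attraction range
is evaluated as Ξ = (Z_p^q Z_π / ε_i)·Σ Δl_α π_α ε_α, which telescopes to
Σ Δl_α (n_α/K)^q ε_α / ε_i and converges to ξ as the grid refines and
L ≫ ξ; the two interfacial-distortion constants it absorbs cannot be
identified separately from a single profile and are reported only through
the lumped Ξ.

## Hydropathic moments

Per-atom weights come from a rule-based binarized atomic hydropathy table
(±0.5 kcal): N and O atoms, Cys SG, amide/carboxyl/guanidinium carbons,
backbone carbonyl carbons, His CE1, and heteroatom-bound hydrogens are
hydrophilic; all other atoms hydrophobic. Hydrogens missing from the table
default to −0.5 (all polar hydrogens are tabulated explicitly); other
unmatched atoms either fail the run (default) or take the residue-majority
sign. Weight noise ι ~ N(0, σ_ι = 1e−3) is drawn once per atom per run
with a fixed seed.

Moment convention: even j sums the scalar r^j·w; odd j sums the vector
r^{j−1}·r⃗·w, so every component scales like r^j and j = 1 is the standard
hydropathic dipole. The ⊥ component is the z (membrane-normal) component;
∥ is the in-plane Euclidean norm. The ± decomposition takes the
hydrophilic-only and hydrophobic-only partial sums; the cutoff scale is
the start of the longest grid suffix on which the two traces hold constant
opposite signs, with the case-A assignment (h₊ = philic) preferred on
ties. Even orders with σ_ι = 0 decompose exactly (case A) from the first
hydrophilic-occupied scale; odd-⊥ orders of nearly symmetric clouds often
admit no sign-stable region and are then excluded from the ϕ/I features —
mirroring the partial decomposability of the first-order dipole seen on
real channels.

ψ_± are centered differences of ln(±h_±) against ln l, optionally smoothed
with a quadratic Savitzky–Golay window (default 5 grid points — enough to
tame grid-level jitter without distorting slow trends; it cannot remove
structured oscillations with periods of many grid steps). ϕ_j is evaluated
pointwise as ln(−h₊/h₋), so the trapezoidal integral of I_j = Δψ_j/l
reproduces its endpoint differences by construction on smooth traces. The
power-law exponents η_j,< and η_j,> are ordinary least squares of ln|h_j|
on ln l over (l₀, l_i] and (l_i, l_>] with zeros masked; fewer than five
usable points leave an exponent undefined. The wave-packet envelope fit
(κ_j from the upper envelope of |h_j|/n) is a diagnostic only; its
peak-based estimator slightly underestimates the envelope when the
oscillation period is comparable to ξ.

## Mutations and the flipping-coin midpoint

A mutation's structural location is the geometric center of all atoms of
the annotated residue (backbone, side chain and hydrogens). Clustering
relative to the PD/VSD interface is summarized per pore point by the mean,
median, and mode of {l_mut − l_i}; the mode uses a Gaussian KDE with
Silverman bandwidth, arg-maxed on a 0.1 Å grid, because a histogram mode
at this sample size is dominated by binning. The collapsed distribution
over all pore points is summarized by sample mean and standard deviation
(moment matching to a normal). The flipping-coin midpoint l* is returned
in both empirical (first grid scale with N/n_total ≥ 0.5) and model
(root of n(l) = n(L)/2) forms; when n(L) ≈ K it coincides with l_i,b.

## Classification

Each (pore point, mutation) row evaluates {ϕ_2k, I_2k, ϕ_2k+1,⊥, I_2k+1,⊥}
for k = 0..5 at l = l_mut by linear interpolation on the finite part of
each trace; mutations outside (R̄, L] at a pore point are masked there,
undecomposable orders yield missing features. Rows with more than half
their features missing are dropped; the rest are median-imputed inside
training folds only. The classifier is a deliberately untuned RBF-SVM
(C = 1, 'scale' bandwidth, class weights balanced) inside a pipeline with
fold-fitted imputation and standardization, evaluated by stratified
k-fold (k = 5) locally per pore point and then in a final round on
per-mutation median-summarized features. The decision threshold is the
median over 1000 bootstrap resamples of the F1-maximizing cut on
out-of-fold disease-class probabilities; permutation importances use 200
within-column shuffles per feature (only the importance ordering is
contractual). All stages are seeded and bitwise reproducible at the
report level. Experiments mirror the three published dataset contrasts:
disease (GoF∪LoF) vs neutral, disease vs neutral∪benign, and all
pathogenic vs neutral∪benign, with optional inertia-only,
conductivity-only, and unsigned-feature variants.

## Synthetic data

The generator inverse-CDF samples atom radii from n(l)/n(l_max) about a
single generating pore point at the origin (so the closed-form law is
exact there), with l_max set where n reaches 99% of K; directions are
uniform on the sphere and emitted as in-plane mirror pairs sharing a
radius, making slab centers fall exactly on the z axis. Default truth
parameters are ζ = 5 Å, ξ = 10 Å, K = 30000, n₀ = 10, l₀ = 1 Å — ranges
of the order seen in fitted channel structures and a eukaryotic-scale atom
count. Hydrophilicity is Bernoulli with logistic probability in radius
(midpoint 40 Å ≈ 0.8·l_i, steepness 0.25 Å⁻¹), so the pore-domain
interior is hydrophobic, the periphery hydrophilic, and the overall
balance close to 1:1. Atoms are single-atom pseudo-residues (PHO/PHI)
resolvable by the shipped hydropathy table, rolling over to successive
chains after 9999 residues. The mutation sampler draws class-specific
radial offsets Normal(μ_class, σ) around l_i (defaults μ = −6 and +1 Å,
σ = 13 Å, mirroring the observed disease/control contrast) and snaps each
draw to the nearest-radius existing residue, resampling draws outside
[R̄, L].

What the synthetic cloud does **not** emulate: covalent geometry and
residue-level correlation of atom positions, membrane anisotropy,
multi-domain symmetry breaking, structured (non-monotone) hydropathy
layering, and the z-dependence of the packing parameters along a real
pore. Passing the recovery and classification tests therefore certifies
the estimators and the pipeline plumbing — not the biological claims,
which require the full structure corpus and curated mutation tables.

## Problem sizes used in the shipped checks

The automated checks fit 20 clouds of 30,000 atoms for parameter
recovery, use a 10,000-atom cloud for moment/entropy/limit checks, and a
5,000-atom cloud with 5 pore points and 80 mutations for the end-to-end
pipeline — sizes chosen so the full suite runs in well under a minute per
stage on a single CPU while leaving the estimators' statistics
well-resolved.

## Known limitations

* The principal-axis orientation mode maps the largest-variance axis to
  +z, which is correct for prolate clouds; real channels (oblate in the
  membrane plane) should be supplied pre-oriented (`as-is`, OPM-style).
* The cleaning policy (keep protein ATOM records with hydrogens, first
  altloc, drop HETATM/waters/ions) is a documented approximation; atom
  counts may differ slightly from other preparation protocols.
* ψ-derivative-based quantities (I_j) are noise-sensitive; ϕ_j is the
  more robust feature, and the classifier treats them as separate inputs
  rather than as the ratio I_j/ϕ_j, which can diverge where ϕ_j → 0.
* Single-model NMR/cryo-EM handling only (first model); no protonation,
  loop modeling, or map-based processing.
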