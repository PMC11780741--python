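# Methods

## Shielding-tensor model

The nuclear shielding tensor σ of nucleus *K* is a 3×3 real matrix in ppm,
expressed in a Cartesian molecular frame recorded in the tensor's
`frame_note`. It decomposes uniquely into a symmetric part
σ_sym = (σ+σᵀ)/2 and an antisymmetric remainder (σ−σᵀ)/2. Only σ_sym
contributes to first-order observables; the antisymmetric part is retained
in the data model but never enters principal components or RCSA
back-calculation (the Frobenius contraction of a symmetric with an
antisymmetric matrix vanishes identically, and this is property-tested).

Principal components are the eigenvalues of σ_sym, computed with
`numpy.linalg.eigh`. Two orderings are supported:

* **Maryland**: σ₁₁ ≤ σ₂₂ ≤ σ₃₃. Anisotropy Δσ = σ₃₃ − (σ₁₁+σ₂₂)/2 ≥ 0 by
  construction and continuous in the matrix entries.
* **Haeberlen**: |σ_ZZ−σ_iso| ≥ |σ_XX−σ_iso| ≥ |σ_YY−σ_iso|. Anisotropy
  Δσ = σ_ZZ − (σ_XX+σ_YY)/2 is signed. When two PCs of opposite sign sit
  nearly equidistant from σ_iso, an infinitesimal eigenvalue change flips
  which one becomes σ_ZZ, and the anisotropy jumps by roughly 3·|σ_ZZ−σ_iso|
  — this discontinuity is why the Maryland form is the default for
  benchmark statistics. Tie-break when |σ_XX−σ_iso| = |σ_YY−σ_iso|: the
  larger eigenvalue is assigned to σ_XX (any deterministic choice is valid;
  this one is documented and stable).
* A third, ordering-free anisotropy is provided under the name
  `turbomole`, the rotationally invariant form
  Δσ = sqrt(3/2 · Σᵢ(λᵢ−σ_iso)²), i.e. sqrt(3/2) times the Frobenius norm
  of the deviatoric part — the root of a non-negative invariant, hence
  always ≥ 0.

Eigenvector signs are intrinsically arbitrary; we fix them by flipping each
eigenvector so its largest-magnitude component is positive. Degenerate
eigenvalues return whatever orthonormal basis the solver produces; the
comparison layer handles degeneracy by exclusion rather than by trying to
canonicalise the eigenspace.

## Comparison criteria

Errors are always test − reference, paired by (molecule, nucleus) key, and
the comparison refuses pairs whose frame notes differ unless explicitly
overridden (tensors in different orientations make every angle
meaningless). Statistics: MSE (mean signed error), MAE, SD (sample
standard deviation, n−1 denominator — conventional for benchmark tables),
max-AE.

**Direction criterion.** Axes are paired by Maryland rank; the angle per
axis is arccos(min(1,|u·v|)) ∈ [0°, 90°], so eigenvector sign flips on
either side are immaterial. An axis is excluded when the minimum gap
between its *reference* eigenvalue and either other eigenvalue is below a
threshold (default 3 ppm): near-degenerate PCs are effectively
omnidirectional and their eigenvector angles are noise. Exclusion is
computed from the reference set only — the benchmark tensors define which
directions are well-posed — and is axis-specific (a well-separated σ₃₃ axis
is retained even when σ₁₁/σ₂₂ are nearly degenerate). With threshold 0,
nothing is excluded; retention counts are non-increasing in the threshold.
Summary tables report angle averages (mean of angles in degrees); averaging
cosines instead would weight large deviations slightly differently but the
two agree closely for the small angles that dominate in practice. A
best-match pairing mode exists for diagnostics only.

**Shape criterion.** ΔΘ_T = arccos(⟨A,B⟩_F / ‖A‖_F‖B‖_F) ∈ [0°, 180°] on
the full unsymmetrized matrices (default) or on the 3-vectors of Maryland
principal values; the cosine is clipped to [−1, 1] before arccos. The shape
and isotropic criteria are deliberately non-redundant: a trace-preserving
shift Δσ₃₃ = −Δσ₁₁ moves ΔΘ_T while leaving σ_iso fixed, and a uniform
rescaling moves σ_iso strongly at ΔΘ_T ≈ 0. Both limiting cases are
asserted in tests.

## RCSA model and fit

Back-calculation: Δν_K = ν·10⁻⁶·(2/3)·Σᵢⱼ S_ij σ_K,sym,ij with σ in ppm and
ν the ¹³C Larmor frequency in Hz (the 10⁻⁶ folds the ppm scale into ν). The
2/3 contraction constant is a convention: the fitted S absorbs any
rescaling, so back-calculated values at the fitted S, residuals, Q-factors
and candidate rankings are invariant to it — this is proved numerically in
the tests rather than argued. The alignment-tensor view is A = (2/3)·S,
again a pure rescaling that no reported quantity depends on.

Observed data are ΔΔRCSA: per-nucleus shift changes between two alignment
conditions, internally referenced to one carbon of the analyte,
ΔΔRCSA_K = (δ¹ᴷ−δ²ᴷ) − (δ¹ʳᵉᶠ−δ²ʳᵉᶠ). Referencing removes the isotropic
medium shift; consequently the fitted S is the *difference* of the two
conditions' order matrices, and no attempt is made to separate them. The
design matrix is built from σ_K,sym − σ_ref,sym per row, in the irreducible
parameter basis (S_zz, S_xx−S_yy, S_xy, S_xz, S_yz) with the trace
eliminated analytically; isotropic shifts of any tensor are therefore
structurally invisible (c·I cancels in the difference before any
arithmetic that could leave a residue).

The ≥ 5-observation system is solved least-squares via SVD. Singular values
below 1e−10 × the largest are treated as zero; rank deficiency raises an
error naming the null-space direction in the parameter basis (e.g. all
tensors axially symmetric about a common axis never determine S_xy), and
the condition number is always reported. Q = sqrt(Σ(obs−calc)²/Σ obs²) —
the RMS-of-observed normalization; Q = 0 for a perfect fit, Q = 1 for a
zero prediction.

**Monte-Carlo errors.** Q is reported as mean ± SD over refits with i.i.d.
Gaussian noise added to every observation (default sd 0.5 Hz, the
conventional estimate of experimental ΔΔRCSA uncertainty; default 1000
samples; fixed default seed, all overridable). Failed refits are counted
and reported, never dropped silently. SD (not percentile intervals) was
chosen as the error-bar convention to match the mean-±-SD decisiveness rule
below.

**Conformer ensembles.** Flexible molecules use the
single-alignment-tensor approximation: one S shared by all conformers, the
design matrix being the population-weighted average over conformers
(equivalent to weight-averaging the back-calculated values). A one-conformer
ensemble reduces exactly to the rigid fit.

## Discrimination and hybrid tensors

Candidates are ranked by Monte-Carlo mean Q computed with a shared seed (so
all candidates see identical noise draws). The result is flagged decisive
only when the [mean−SD, mean+SD] intervals of the two best candidates do
not overlap.

Hybrid tensors V diag(λ) Vᵀ take λ from one method's Maryland-ordered PCs
and V from another's, paired by Maryland rank on both sides — the only
pairing under which a method hybridised with itself reproduces its own
(symmetrized) tensor exactly. Hybrids discard antisymmetric parts, which
the RCSA contraction cannot see anyway, and are built conformer by
conformer for ensembles. The swap table reports, per method, mean Q for the
unaltered tensors, for hybrids with reference frames (`eigvec_ref`), and
for hybrids with reference eigenvalues (`eigval_ref`); in the synthetic
constructions where methods differ only in eigenvalues the `eigval_ref`
column collapses to the reference Q exactly, and the frame-only case
mirrors it.

## Synthetic data: what it emulates and what it does not

Reference tensors are built as R·diag(λ)·Rᵀ + small antisymmetric part with
R Haar-uniform (`scipy.stats.special_ortho_group`) and
λ parameterized by isotropic value, Maryland anisotropy Δ and asymmetry
η ∈ [0,1]: λ₃ = iso + 2Δ/3, λ_{1,2} = iso − Δ(1±η)/3, so the realized
Maryland anisotropy is exactly Δ. Defaults emulate ¹³C diversity: iso
20–180 ppm, Δ 30–180 ppm, η uniform on [0,1], antisymmetric scale 1 ppm.
Near-degenerate nuclei (gap < 3 ppm) are injected only on explicit request,
keeping baseline recovery tests well-conditioned.

Method-like perturbations jitter eigenvalues (default sd 5 ppm — the MAE
scale separating good from mediocre density-functional approximations),
optionally add a systematic anisotropy bias in the trace-preserving
direction (+2b/3, −b/3, −b/3), and rotate frames by a folded-Gaussian angle
(default 2°) about a uniform axis — reflecting the observed error
structure where eigenvalues dominate method differences and frames are
reproduced well by almost everything.

Observations use ‖S‖_F = 10⁻³ by default — the order-parameter magnitude of
weak alignment media, which yields ΔΔRCSA of order 10 Hz at ν(¹³C) =
150.9 MHz (14.1 T) and hence Q ≈ 0.05 at 0.5 Hz noise, the scale seen in
real natural-product fits. The medium shift is applied before referencing
and must cancel; noise is added after referencing.

Not emulated: real alignment-medium physics (the S here is a random
direction in its 5-space, not a prediction from molecular shape),
molecule-specific chemistry and scalar-coupling complications, correlated
experimental errors, and conformer generation. Passing the synthetic
recovery and discrimination tests therefore demonstrates the correctness
and conditioning of the *analysis machinery*, not the accuracy of any
electronic-structure method on real compounds.

## Numerical choices and edge cases

* Cosines clipped to [−1,1] before every arccos.
* Rank tolerance 1e−10 relative; underdetermined (< 5 observations) and
  rank-deficient geometries raise typed errors rather than returning a
  minimum-norm solution.
* Q is undefined (error) for an all-zero observed vector; shape angles are
  undefined for zero-norm tensors; alignment cosines for zero order
  matrices.
* The isotropic-shift invariance is bit-exact when the inputs are exact
  (e.g. entries quantized to a binary grid); for arbitrary floating-point
  inputs it holds to machine rounding of the input shift itself — the
  cancellation happens structurally in the tensor differencing, before the
  design matrix is formed.
* Exchange files declare units (ppm only) and an orientation note; parsers
  reject unit mismatches, duplicate keys and malformed records with line
  numbers, and never coerce silently.
* The deposit adapter is best-effort by design: it recognises both exchange
  dialects and a Turbomole mpshift-like block layout, logs every file it
  cannot convert, and fails loudly on an empty or fully unrecognized tree.

## Problem sizes

Defaults used throughout the test suite and the reproduction script: 10
nuclei per synthetic molecule (8–12 in the noisy-recovery study), 200
replicates for parameter recovery, 100 replicates × 50 Monte-Carlo samples
for the discrimination rate, 1000 random tensor pairs for the metric
oracles. These sizes give stable statistics (medians and rates reproduce
across seeds to well within the asserted margins) at a few seconds of
runtime.
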