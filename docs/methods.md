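# Methods

`twinstack` analyses the geometry and diffraction of a non-merohedrally
twinned triclinic crystal whose twin law is a twofold rotation about the
reciprocal direction **a\*+b\***, with the second extracellular domain of
tetraspanin CD9 (P1, a = 39.986, b = 39.998, c = 63.643 Å, α = 80.39,
β = 76.29, γ = 68.15°) as the worked case.  This note records the models,
the parameters that matter, and the design decisions taken where more than
one reasonable choice existed.

## Cell algebra and conventions

Reciprocal vectors carry no 2π factor, so d = 1/|q| and the reciprocal
basis matrix is the inverse transpose of the direct one.  The direct basis
is oriented with **a** along Cartesian x and **b** in the xy plane.  Angles
are degrees at every interface.  Friedel-unique reflection lists keep the
member with l > 0, then k > 0, then h > 0.  The basis matrices are built in
plain numpy (they feed the twin algebra directly); the test suite
cross-checks volumes and d-spacings against gemmi.

## Twin law and coincidence sublattice

A candidate twin law about a direct [uvw] or reciprocal (hkl)\* axis is the
Cartesian rotation R about the axis image; its action on reflection indices
is the conjugation Q = B⁻¹RB with B the reciprocal basis.  For a genuine
(pseudo-)twin Q is close to a rational matrix.  Q is rationalized entrywise
by *smallest-denominator-within-tolerance* rounding (denominator bound 24,
absolute tolerance 0.05, both configurable).  The smallest-denominator rule
matters: the CD9 cell is only pseudo-coincident (entries of Q deviate from
the ideal quarters by up to ≈ 0.023), and best-approximation rounding under
a denominator bound would latch onto spurious fractions like 23/24 instead
of snapping to {0, ±1, ±1/4}.  The residual max |Q − Q_rat| is reported as
the pseudo-merohedry *misfit*.  A matrix with no admissible rationalization
is flagged irrational and refused by all sublattice operations.

The exact-coincidence sublattice {h ∈ ℤ³ : Q h ∈ ℤ³} is computed without
floating point: its dual is the sum lattice ℤ³ + Qᵀℤ³, reduced by integer
column Hermite elimination after clearing denominators; the sublattice
basis is the rescaled inverse transpose, canonicalized by a second Hermite
reduction.  The index is |det| of that basis.  When the sublattice equals
{h : n | h_i} for a single coordinate, the congruence is reported as a
layer rule; the equality test is exact (the candidate lattice's generators
are checked for membership and the indices compared).  For the idealized
CD9 cell the result is index 4 with rule l ≡ 0 (mod 4), the reciprocal
statement of the c/4 stacking lattice; the printed supercell matrix
(1,−1,0 / 0,0,1 / −2,−2,1) has |det| = 4 and maps both twin lattices to
integer indices, which is verified in rational arithmetic.

**Idealization.**  Because the real cell is only pseudo-coincident, the
sublattice statements are exact only after projecting the metric onto the
nearest one for which the law is an isometry.  The reciprocal metric G\* is
averaged over the two-element group {I, Q_rat}; since Q_rat² = I this is
the least-squares symmetrization, and the cell changes by < 0.7% in lengths
and < 0.3° in angles.  On the idealized cell the numeric conjugation equals
the rational matrix to machine precision, and the fixed axis of Q_rat is
exactly (1,1,0)\*.

**Obliquity.**  Reported as the angle between the twin axis and the nearest
complementary-kind lattice direction with indices up to a search bound
(default 4).  The bound matters for this crystal: the stacking-repeat row
[4,4,−1] lies 0.95° from (1,1,0)\*, while no row with indices ≤ 3 comes
closer than 4.6°.  The twin-law search filters by obliquity (default cutoff
5°) and additionally reports the misfit; a genuine twin law needs both to be
small.

**Overlap prediction.**  For every reflection of lattice 1 to a resolution
limit, the separation to the nearest lattice-2 node is minimized over
candidate images (rounded Q⁻¹h plus a ±1 neighbourhood).  On a cell where
the law is exact, coincidences are established by the integer congruence
N h ≡ 0 (mod d) (N = dQ) and reported as exactly zero; on the real cell
this shortcut is disabled and all separations are metric.  Reflections on
the twin axis itself, (h,h,0), coincide for *any* cell — the overlap
fraction therefore tends to the on-axis fraction, not zero, as the
tolerance shrinks.  The default overlap tolerance is 0.002 Å⁻¹, roughly a
detector spot width at this geometry; it is exposed as a parameter and the
reported statistics are grouped by l mod 4, where the mean separation is
zero at l ≡ 0, intermediate at l ≡ ±1 and maximal at l ≡ 2.

## Stacking-disorder diffraction model

The crystal is modelled as coherent blocks of N layers (default 64),
summed incoherently over many blocks (default 512); the finite block
stands in for the X-ray coherence length, which is not quantified
experimentally.  Each layer is one of two states drawn from a two-state
Markov chain started in its stationary distribution.  A layer is a motif
of 3–5 Gaussian pseudo-atoms (weight w, width b in Å², amplitude
w·exp(−b|q|²)·exp(2πi q·r)), optionally repeated on a finite in-plane
lattice, which multiplies the amplitude by two Dirichlet kernels and
confines the scattering towards the layer's reciprocal rods — the
in-plane sharpness of real spots and streaks.

The block amplitude is A(q) = Σ_j F_{s_j}(q) exp(2πi q·d_j) with
d_j = Σ_{i<j} t_{s_i}.  Two points differ deliberately from the most
naive layer model:

* **Per-state stacking vectors.**  State 2 is state 1 transformed by the
  twin twofold, *including its growth step*: t₂ = R t₁.  On the idealized
  CD9 cell, with t₁ = a, the rotated step is exactly b − c/4, so the
  accumulated phase mismatch per layer is q·(t₁ − t₂) = h − k + l/4 ≡ l/4
  (mod 1).  A model in which only the layer content rotates but the
  stacking step is shared cannot reproduce the ordered l = 4n slices for
  generic content; the disorder of this twin lives in the stacking step.
* **Twofold-symmetric interface content.**  The twin-stacking preset's
  motif is exactly invariant under the twofold (atoms in S-related pairs
  about the axis), mirroring the NCS-symmetric interface layer of the real
  crystal, so F₂ = F₁ identically and the two states differ only in their
  step.  Consequently, on every rod of an l = 4n section each layer
  contributes an identical amplitude whatever the stacking sequence: the
  amplitude is non-random and the diffuse component vanishes *identically*,
  while sections with l ≡ 2 (mod 4) (half-integer phase mismatch) streak
  maximally along a\*+b\*.  The second preset, `c-layer-rotation`, models
  the weaker c\* streaks: a single domain stacking along c in which a layer
  is occasionally (probability β, uncorrelated by default) replaced by its
  rotated copy; there the content differs (asymmetric motif) while the step
  is shared, and the diffuse spreads along c\* only.

**Intensity decomposition.**  Bragg = |⟨A⟩|², diffuse = Var(A); the total
is their sum.  This makes "ordered slice" an exact statement (variance of
a deterministic amplitude) rather than a numerically small one.  Note that
at α → 0 the ensemble is a mixture of two perfect domains: the total is the
π-weighted incoherent sum of two sharp single-domain patterns, and the
"diffuse" (variance) component then measures the inter-domain intensity
difference, not broadening.

**Evaluation routes.**  `pattern_mc` samples stacking sequences and
averages |A|²; its standard error per grid point is the block-sample
standard deviation over √B.  `ht_intensity` computes the *exact*
stationary-chain expectation by transfer matrices,

    E|A|² = N Σ_s π_s |F_s|² + 2 Re Σ_{m=1}^{N−1} (N−m) (π∘F*)ᵀ T^m F,
    T_{ss'} = P_{ss'} exp(2πi q·t_s),

together with ⟨A⟩ = Σ_j πᵀT^j F.  With finite-block weights (N−m) the two
routes estimate the same quantity, so Monte-Carlo agreement within
sampling error is a sharp test; the classical damped infinite-stack closed
form Σπ|F|² + 2 Re (π∘F*)ᵀ T_d(I−T_d)⁻¹ F with T_d = e^(−1/L) T is kept as
`ht_intensity_infinite` (default damping length L = N; the resolvent is
singular at Bragg nodes without damping and the computation is refused).
The infinite form differs from the finite-block intensity by about a
factor 2 at Bragg nodes (geometric vs Laue summation), which is why it is
not the reference for the Monte-Carlo comparison.

**Sum rule.**  Integrating the per-layer intensity I/N over one full
period of the stacking phase leaves only the incoherent term
Σ_s π_s ⟨|F_s|²⟩, because every transfer-matrix cross term carries a factor
e^(2πimξ) that integrates to zero — *provided* F is constant along the
integration line.  The conservation check therefore uses a motif confined
to the interface plane (coordinates d·(1,−1,0) + g·(0,0,1), for which the
form factor depends only on the rod indices) with near-zero Gaussian
widths; with the default 3D motif the integral acquires an O(1%) drift from
the |q|-dependent width factor, which is physics, not error.  Uniform
periodic trapezoid quadrature (512 points/period) is spectrally exact for
the trigonometric polynomial involved.

**Grids and maps.**  Patterns are sampled on rod grids (sections × rods ×
along-rod samples; default 8 samples per repeat along the streak) or on
continuous 2D plane grids for imaging streak elongation, quantified as the
ratio of autocorrelation lengths of the diffuse component parallel vs
perpendicular to the streak.  Full 3D grids export as CCP4/MRC mode-2 maps
through gemmi, with the parent (or super-) cell in the header; write→read
round-trips are exact at float32.

## Detwinning and merging

HKLF4/HKLF5 files use the fixed-width dialect 3I4, F8.2, F8.2, I4; in
HKLF5 a negative batch marks a component belonging to the group closed by
the next positive-batch record, intensity and sigma are repeated on each
record of a group, and an all-zero record terminates the file.  Round
trips are byte-identical.

Twin fractions are estimated from I_i ≈ s·Σ_k f_k A_ik with a free global
scale s: non-negative least squares in g = s·f (weights 1/σ²) followed by
normalization f = g/Σg.  This enforces f ≥ 0 and Σf = 1 without tuning,
and makes the estimate invariant to any global scale on the reference
intensities — the reason observations covering a single domain are
*unidentifiable* (raised as an error) rather than silently fit.  Rank
deficiency (proportional reference columns) is detected by SVD.  The
covariance is (AᵀWA)⁻¹ propagated through the normalization by the delta
method; intervals use ±1.96σ.

Detwinning groups observations into connected components over the unknown
per-(reflection, domain) intensities and solves each small weighted
system; rank-deficient groups are flagged `singular` and negative
solutions `negative`, never dropped.  Merging under Laue −1 classes
reflections by Friedel-canonical index; Rmerge = ΣΣ|I−⟨I⟩|/ΣΣI and Rpim
(with √(1/(n−1)) weights) sum over classes with n ≥ 2; CC1/2 correlates
seeded random half-splits; completeness counts observed unique reflections
against the enumerated Friedel-unique set; shells hold equal unique counts
(default 10).

## Synthetic data

Ground-truth single-domain intensities are log-normal (median 100,
σ_log = 1.0), mimicking the heavy right tail of macromolecular intensity
data.  Composites follow the coincidence rule by default — the reflections
with l ≡ 0 (mod 4), about 25% of the list, become two-component
observations I = f₁J(h) + f₂J(Qh) — or a separation-threshold rule on the
real cell for more realism.  Both domains share one intensity table (they
are the same structure).  Noise models: none, Gaussian, or Poisson with a
stated mean count; Poisson sigmas are the true standard deviations from
the *expected* counts, as an integration program estimates them from the
profile model — sigmas taken from observed counts correlate with the noise
and visibly bias any weighted fit.  Optional multiplicity emits repeated
Friedel-alternating measurements for merging studies.  Every generator is
a pure function of its spec and seed.

The synthetic NCS structure is a CA-only random-walk chain plus its copy
rotated 180° about (1,1,0)\* and jittered (default 0.28 Å per coordinate,
chosen so the Cα superposition lands near the ~0.5 Å scale typical of
NCS-related chains).  It is a labelled synthetic stand-in: tests verify
that the pipeline recovers the constructed twofold and its co-alignment
with the twin axis, not any deposited value.  The deposited CD9 model can
be fetched with `tools/fetch_6rlr.py` (kept outside the tested core; the
library itself never touches the network).

## What the synthetic conditions do and do not show

Passing tests demonstrate the internal consistency of the geometry and the
statistical machinery under the stated generative models: exact coincidence
algebra, an unbiased fraction estimator with calibrated intervals under
Poisson noise, and a stacking simulator whose two independent evaluation
routes agree.  They do not validate against measured CD9 intensities: the
published overlapping-reflection percentage, merging table and refinement
R-values derive from profile deconvolution of thousands of raw detector
frames and are outside this package's inputs.  Twin fraction, domain-size
distribution and coherence length of the real crystal are unknown; in the
simulator they are free parameters (α, β, N, block count) with defaults
chosen for illustration (α = 0.2, β = 0.1, N = 64, 512 blocks).

## Known limitations

* Layer content is a Gaussian pseudo-atom toy, not atomic structure; all
  simulated intensities are in arbitrary units.
* The coincidence machinery requires a rationalizable twin law; laws that
  fail rationalization are refused rather than approximated.
* Detwinning keeps negative recovered intensities (flagged); no
  French–Wilson-style truncation is applied.
* The Markov chain is first-order; correlated runs of rotated layers are
  expressible through the transition matrix but higher-order stacking
  memory is not.
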