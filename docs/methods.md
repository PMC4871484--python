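# Methods

## Kinetic model

A photocycle is a continuous-time linear system: states s (one ground state,
the rest photo-intermediates) with populations c(t) obeying dc/dt = K·c,
where K holds first-order rate constants (K[i,j], j→i, off-diagonals ≥ 0;
each diagonal is minus its column sum, so total population is conserved).
Populations are propagated analytically through the eigen-decomposition
K = V Λ V⁻¹; there is no step-size error.  Matrices whose eigenvector basis
is numerically singular (condition number > 1e10) are rejected as defective —
the caller is advised to perturb near-equal coupled rates, since a Jordan
block would need t·e^(λt) terms outside this model class.

The observable is

ΔA(λ, t) = f · c₀ · ℓ · Σ_s (ε_s(λ) − ε_ground(λ)) · c_s(t)

with excited fraction f, sample concentration c₀ and pathlength ℓ.  Because
the coefficient of the ground state vanishes identically, ground-state bleach
and recovery come out of the same sum without special-casing.  ΔA is an exact
sum of exponentials whose rates are the eigenvalues of K; the
decay-associated spectrum (DAS) of mode i is the eigenmode-weighted mixture
of state difference spectra.  `predict_das` merges exactly repeated
eigenvalues of a diagonalizable matrix into a single kinetic mode (their DAS
add — they are indistinguishable in any measurement) and errors only on
genuinely defective matrices and on complex (oscillatory) modes.

### Default green-PR scheme

The default scheme reproduces a four-lifetime photocycle — 3.5 µs, 84 µs,
11 ms, 82 ms — of red-shifted intermediates plus a kinetically hidden
M-like state:

- Main path: P1(560 nm) → P2(600 nm) → P3(600 nm) → P4(560 nm) → ground
  (524 nm), rate constants equal to the reciprocal lifetimes.  A sequential
  irreversible chain has a triangular rate matrix, so its eigen-lifetimes are
  exactly the step lifetimes.
- Hidden M: a branch P1 → M(400 nm) carrying 10% of the P1 flux, with M
  decaying to P3 at the same 1/84 µs rate as the parallel P2 step.  The
  eigenvalue −1/84 µs is then repeated, but P2 and M are uncoupled, so the
  matrix stays diagonalizable and the observable still contains exactly four
  distinct lifetimes.  M's peak occupancy is ≈ 0.09 and its 400 nm signature
  stays at the noise scale — the "invisible intermediate" argument made
  concrete.  Putting M *in series* with equal formation and decay rates was
  rejected: that makes K defective and adds a fifth near-84 µs mode.  The
  matched-rate limit itself is carried by `max_transient_occupancy`, whose
  closed form (k₁/k₂)^(k₂/(k₂−k₁)) → 1/e as k₁ → k₂.
- Band shapes: bifurcated Gaussians (independent blue/red half-widths via a
  skew parameter), peak value exactly at the center.  FWHM ≈ 80–110 nm,
  typical of retinal-protein bands.  Amplitude scale: ground peak extinction
  50,000 M⁻¹cm⁻¹, c₀·ℓ = 2·10⁻⁶ M·cm (A₅₂₄ ≈ 0.1, inside the working range
  of a titration sample) and f = 0.15, giving bleach/DAS amplitudes of order
  10 mOD.  The intermediate band parameters are fixture choices — only the
  lifetimes are constants of the modelled experiment.

### Blue-light shunt

`steady_state_current` augments a scheme with a green excitation edge
(ground → entry states at the given rate, split like the t = 0⁺ populations)
and a blue shunt edge (M → ground at blue_rate × branch ratio).  The
photostationary populations are the null vector of the augmented K (via SVD);
the pumped current is the flux into the ground state through the scheme's
*original* edges — shunted molecules return without pumping.  The result is
normalized to the blue-off current, so it is dimensionless and monotonically
non-increasing in the blue rate.  No voltage, pH or capacitive-transient
modelling is attempted.

## Synthetic acquisition

`make_photocycle_dataset` emulates the recording geometry: two oscilloscopes
digitizing the same transient at 200 ns/point and 20 µs/point, 46,080 samples
each (read as 45 × 1024 — the only interpretation consistent with 880
log-reduced points), 14 probe wavelengths (380–645 nm), time zero at the
flash with the first sample one step later, and the first intermediate fully
formed at t = 0⁺ (sub-resolution formation; no instrument-response
convolution).  Noise is independent Gaussian per sample, default
σ = 0.3 mOD.  Not emulated: photoselection/anisotropy, shot noise, baseline
drift, scattered excitation light.  A green suite therefore establishes
correctness of the *analysis chain*, not robustness to structured
instrumental artifacts.

## Logarithmic reduction and merge

Century n (n = 1, 2, …) consumes 100·2^(n−1) consecutive raw samples and
emits 100 block means of block size 2^(n−1); the final partial century emits
only its complete blocks, discarding the incomplete tail (this keeps block
variance uniform within a century and is required for the 880 count).  Block
timestamps are arithmetic means of member sample times — unbiased for uniform
sampling.  46,080 samples → 8 full centuries (800 points) + 80 blocks of 256
= 880 points.  Merging keeps every fast point and the slow points whose
block-center time strictly exceeds the last fast time: 880 + 640 = 1520
points spanning 200 ns to ~0.92 s.  Reduction is block *averaging*; no
interpolation onto an exact logarithmic grid is performed.

## Global fitting

Variable projection: for trial lifetimes τ (parameterized as log τ to keep
them positive), amplitudes solve a linear least-squares problem over all
wavelengths at once; the nonlinear optimizer (Levenberg–Marquardt,
`scipy.optimize.least_squares`, ftol 1e-10, ≤ 500 iterations per component)
sees only the projected residual.  When no initial lifetimes are supplied,
five starts are used — one log-spaced, four drawn log-uniformly from
[2·min Δt, 2·max t] with a fixed internal seed — and the best optimum kept.
Lifetimes are reported ascending with DAS rows carried along; the per-τ
relative standard error comes from the projected-problem Jacobian.

Defaults reconstruct a plain analysis: no additive offset (the cycle fully
recovers; `offset=True` adds a constant column) and unweighted least squares
despite the block-averaged heteroscedasticity (`weighting="block"` applies
√(block size) weights from reduction provenance).  `select_n_exponentials`
grows the model until an added component improves the residual rms by less
than 5%.

## Titration and steady-state spectra

The titration model is the additive double Henderson–Hasselbalch curve

λ(pH) = p_base + (p_mid − p_base)/(1 + 10^(pH−pK₁)) + (p_acid − p_mid)/(1 + 10^(pH−pK₂))

with pK₂ the acidic and pK₁ the basic transition (Hill coefficients fixed at
1 unless `free_hill`).  The model is linear in the plateaus, so plateaus are
solved by least squares at each trial pK pair (variable projection again)
from three deterministic starts.  The fitted observable is λ_max(pH); any
other spectral observable column works (`value_column`).  An acidic midpoint
within 0.5 pH units of the lowest sampled pH flags the acid plateau as
extrapolated.

λ_max refinement fits a parabola over a window (default 20 nm) around the
grid maximum.  For a symmetric peak this is exact; for skewed bands the
parabola is biased toward the wider flank by up to a few nm at wide windows —
narrow the window for asymmetric peaks.

The oxime-referenced extinction ε_Rh = ε_oxime·ΔA(Rh)/ΔA(oxime)
(ε_oxime = 33,600 M⁻¹cm⁻¹) reads both extrema off the bleach difference
spectrum.  The round-trip identity with the generator is exact only when the
rhodopsin and oxime bands do not overlap at the extrema; overlapping bands
bias both ΔA readings — an intrinsic limitation of the internal-standard
method, not of the implementation.

## Sequence analyses

Pairwise alignment is global Needleman–Wunsch (Bio.Align.PairwiseAligner)
with BLOSUM62, gap open 10 / extend 0.5; an end-gap-free variant sits behind
a flag.  Percent identity = identical aligned pairs / aligned columns
containing at least one residue, × 100, reported to one decimal and as a
rounded integer.  Spectral tuning is read at the query residue homologous to
position 106 in blue-PR numbering (L → green, Q → blue, otherwise unassigned
with the residue reported); residue mapping transfers 1-based annotated
reference positions through the alignment and checks the expected residue
class, reporting gapped positions as unmapped.  Queries under 30% identity to
the reference are rejected as unalignable.  No multiple alignment or
phylogeny is provided.  The bundled sequences are synthetic stand-ins
engineered to reproduce the field's published residue numbering offsets; no
database sequence ships with the package, so identity values between real
accessions cannot be asserted offline.

## Numerical choices and degenerate inputs

- Eigen-lifetime merge tolerance 1e-9 (relative); diagonalizability limit
  cond(V) ≤ 1e10; population mass conservation holds to 1e-10.
- Uniform-time check for raw traces: constant step to 1 part in 1e9.
- TSV dialect: `time_s` plus integer-nm columns, 9 significant digits,
  `#` comment lines carrying provenance (config hash, seed, version);
  parse errors report line numbers.  All randomness flows from a single
  config seed; reruns are byte-identical.
- Degenerate inputs rejected with specific errors: empty traces, non-uniform
  timebases, schemes without an excited state, more fit components than time
  points, constant titration data, zero concentration, edge-located spectral
  maxima.

## Known limitations

- The fit assumes a pure exponential sum: distributed kinetics, spectral
  shifts within one intermediate, or photoselection decay would be absorbed
  into effective DAS.
- Noise heteroscedasticity after block averaging slightly biases unweighted
  lifetime estimates at high noise (the ~3% scatter seen on the fastest
  lifetime at 0.3 mOD); block weighting mitigates this.
- The photostationary current model is relative and steady-state only.
- The default scheme's topology (where M branches, which states share bands)
  is one consistent choice among several the kinetic data cannot
  distinguish; only the four lifetimes are identifiable.
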