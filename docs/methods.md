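# Methods

## Generalized modes from velocity covariance

The central object is the time-averaged covariance of mass-weighted
atomic velocities, K_ij = ⟨q̇_i q̇_j⟩ with q̇_i = √m_i v_i, built from a
trajectory sampled at a fixed timestep (fs). Its eigenvectors define
collective coordinates whose velocities are mutually uncorrelated over
the sampled window — "generalized modes". No quadratic-potential
assumption enters: the frequencies read off the per-mode velocity
spectra are the anharmonic frequencies the dynamics actually explores.

Choices a user should know about:

* **Mean-centering.** Velocities are mean-centered per coordinate
  before forming K (configurable). After global-motion removal the
  means are already ≈0; centering makes K a true covariance and is
  immaterial for oscillatory signals sampled over many periods.
* **Global-motion removal.** Per frame, the center-of-mass velocity is
  subtracted and the rigid-body rotation ω×r removed, with
  ω = I⁻¹J from the instantaneous inertia tensor and angular momentum.
  For collinear geometries I is singular along the molecular axis; the
  pseudo-inverse restricted to well-conditioned axes (relative
  eigenvalue tolerance 1e-10) is used and the number of dropped axes is
  recorded per frame. Residual linear and angular momenta are at
  numerical zero afterwards.
* **Determinism.** Eigenvalues are sorted descending and each
  eigenvector's sign is fixed so its largest-magnitude component is
  positive. Near-zero eigenvalues (below rel_tol = 1e-8 × the largest)
  are counted as external (translation/rotation) modes; their
  individual vectors are an arbitrary orthonormal span and are flagged
  `degenerate` — only the count and the subspace are meaningful.
* **External-mode counting is a small-oscillation statement.** With
  finite vibration amplitude the instantaneous rotation directions
  wander with the geometry, leaking O((δ/L)²) velocity variance (δ =
  displacement amplitude, L = molecular size) into the nominally zero
  modes. At relative amplitude 1e-3 this leakage sits near the 1e-8
  counting threshold; at 1e-5 (the regime used for the mode-count
  checks and `scripts/acceptance.py`) it is ~1e-11 and the counts
  6 (nonlinear) / 5 (linear) are exact.
* **Projection order for ensembles.** Excited-state velocities are
  projected per trajectory (Q̇ = Lᵀq̇ with the ground-state L) and any
  ensemble averaging is applied to the resulting spectra/spectrograms,
  never to raw velocities — averaging unsynchronized velocities would
  cancel the oscillations the analysis is after.
* **Stationary spectra.** The default estimator is the periodogram of
  the Hann-windowed, mean-centered signal with 4× zero-padding —
  equivalent up to windowing to Fourier transforming the velocity
  autocorrelation (Wiener–Khinchin). Window and padding are arguments.

## Morlet wavelet spectrograms

The analytic Morlet mother wavelet e^{iω₀u}e^{−u²/2} is used with
ω₀ = 6 by default: the standard balance of time and frequency
resolution, for which the admissibility correction term is negligible
(ω₀ ≥ 5 is enforced) and the scale–frequency map
ν[cm⁻¹] = ω₀/(2πa[fs]) × 33356.40952 is accurate. Scales are laid out
on a logarithmic grid, 12 voices per octave by default.

The transform is evaluated by FFT convolution against each scaled
wavelet, with the signal extended by symmetric reflection. The cone of
influence marks, per time point, the frequency below which the distance
to the nearest edge is shorter than the Gaussian envelope's e-folding
time √2·a; ridge extraction ignores the contaminated region. Power is
|W|² with no per-scale renormalization beyond the L² 1/√a, so
intensities are comparable across frequency in arbitrary units.

**Decay times.** Band power (trapezoidal integral of |W|² over a
frequency band) is smoothed with a 5-step moving average; the decay
time is the first time after the early maximum (within the first
quarter of the window) at which the smoothed power falls and stays
below 1/e of that maximum, with an infinite sentinel when it never
does. An amplitude envelope e^{−t/τ} therefore reads out as ≈ τ/2.
This is an *operational* definition with a known resolution limit: the
wavelet at frequency ν has time-width a = ω₀/(2πν), and when a is not
small against τ the measured decay is biased long (at 198 cm⁻¹,
a ≈ 160 fs, a τ/2 = 700 fs decay reads ≈ 830 fs). Quantitative decay
recovery should use — and the verification suite does use — bands where
a ≪ τ.

## Solvation structure and reactive events

* **Finite-droplet RDF.** The system is a non-periodic droplet, so
  g(r) is normalized by a reference density ρ₀·4πr²dr with ρ₀ supplied
  or estimated ("auto") as N_B over the volume of the minimal enclosing
  sphere of B's time-averaged positions (Bădoiu–Clarkson iteration;
  centroid-centered estimates systematically inflate the radius).
  g(r) → 0 near the droplet edge is a finite-size artifact, not
  structure; no excluded-volume correction is applied. The running
  coordination number n(r) is the exact cumulative pair count per A
  atom per frame, tabulated at bin right-edges so interpolation at a
  cutoff carries no half-bin bias. The auto estimate assumes a roughly
  stable configuration; for uncorrelated ensembles estimate ρ₀ on one
  configuration and pass it explicitly.
* **Dihedrals.** Signed IUPAC dihedrals (cis 0°, trans ±180°) computed
  in double precision; collinear triples are flagged per frame, never
  dropped. Series are unwrapped by minimal-jump continuation so motion
  about planarity averages to ≈180° instead of oscillating between
  ±180°.
* **Proton assignment and hops.** Each hydrogen belongs to its nearest
  heavy atom if within r_bond = 1.3 Å (a standard covalent O–H cutoff;
  ties go to the lowest index). An event opens when the assignment
  changes between frames and closes at the next change or at the end of
  the window; a return to the just-left donor closes the event without
  opening a new one, so a brief round trip is one transient event.
  Events persisting ≥ t_permanent = 100 fs (the natural scale of a
  hydronium intermediate's lifetime) are classified permanent. Both
  cutoffs are arguments. A hydronium is an oxygen with exactly three
  assigned hydrogens; lifetimes are maximal consecutive runs × dt.

## Synthetic generators

`make_harmonic` synthesizes mass-weighted displacements
d(t) = Σ_k A_k L_k cos(2πν_k t + φ_k) e^{−t/τ_k} with exact analytic
velocities, using orthonormal mode vectors built in the complement of
the translation/rotation subspace at the reference geometry — so no
global motion is injected and every downstream quantity has a closed
form. Damping acts on the amplitude; band *power* decays twice as
fast, which decay-time checks account for. Ready-made specs: a
water-like bent triatomic (3 internal modes), a CO₂-like collinear one
(4 internal modes, exercising the singular-inertia fallback), and a
demo configuration with transient modes at 110 and 198 cm⁻¹ (amplitude
τ = 1400 fs, i.e. power 1/e ≈ 700 fs) mimicking the low-frequency
wagging/breathing phenomenology of a photoexcited chromophore — the
demo numbers are documentation inputs, not test truths.

`make_droplet` draws uniform points in a sphere (default 19 Å, the
size of a realistic microsolvation cluster); `make_pt_script` moves
hydrogens between static heavy atoms at scripted times with
instantaneous side-switching, so detected event times are exact to one
frame. All generators are seed-deterministic.

What the synthetic data does *not* emulate: thermal multi-mode
occupation with mode coupling, anharmonic frequency shifts, real
hydrogen-bond network fluctuations, or diffusive proton motion.
Passing tests therefore certify the *analysis machinery* — projection
identities, spectral estimators, normalizations, event bookkeeping —
not the physics of any particular chromophore; applied to real AIMD
trajectories the method's accuracy is limited by sampling and by the
assumption that the reference mode composition holds over the window.

## Verification problem sizes

The test suite and acceptance script run on deliberately modest sizes
chosen for statistical adequacy: 20 ps at dt = 0.5 fs (40 000 frames)
for 2%-level frequency recovery; 4096-frame trajectories for mode
counting; 4096–8192-sample signals for wavelet checks; droplets of
4000 points × 50 independent configurations (~10⁵ pair samples within
9.5 Å) for the RDF null; 5000–6000-frame scripted trajectories at
dt = 0.2 fs for event detection. Everything completes in seconds.
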