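# Methods

This note documents the models, parameter choices and numerical decisions
behind `opmconn`, and what the synthetic-data tests do and do not establish
about real recordings.

## Geometry and units

Field values are femtotesla, positions metres, in a head-centred
right-handed frame with z through the vertex. The volume conductor is a
homogeneous sphere centred at the origin (default radius 0.09 m); sensors
sit on a scalp sphere outside it (default 0.10 m). Triaxial sensors
contribute three channels each — one radial and two tangential unit axes —
so 56 sensors give the 168-channel configuration the pipeline targets.
Sensor positions follow a golden-angle (Fibonacci) spiral over the
spherical cap covering 75% of the sphere's solid angle, a deterministic
low-discrepancy layout with near-uniform nearest-neighbour spacing.

## Forward model

The magnetic field of a current dipole in a spherically symmetric
conductor is evaluated with the Sarvas closed form. Two classical
properties are load-bearing for the tests: the exterior field is
independent of the sphere radius and conductivity profile, and a dipole
with purely radial moment is externally silent. A third — the radial field
component equals that of the free-space (Biot–Savart) dipole term — gives
an independent analytic oracle for the implementation. For a spherical
synthetic head the sphere model and a realistic single-shell model
coincide; realistic head geometry is out of scope.

## Preprocessing

The filter chain follows the acquisition convention for mains-powered
labs: a forward-only 2nd-order IIR notch at 50 Hz with Q = 35 at −3 dB
(zero-phase operation is specified only for the Butterworth band-passes,
so the notch is a plain biquad), then a 4th-order Butterworth band-pass
applied forward and backward (zero phase, squared magnitude response) at
1–150 Hz and again per band of interest.

Channel screening is automated: a channel is removed when its variance is
≤ 10⁻⁶ × the median channel variance (dead) or its broadband power exceeds
10 × the median (noisy). These thresholds stand in for visual inspection
and are exposed as parameters.

Epoch rejection operates on 5-s windows tiling the run (trailing partial
window discarded). For each channel, the SD of the band-passed data is
computed within every epoch; a cell is flagged when it exceeds that
channel's across-epoch mean by more than 3 across-epoch SDs, and an epoch
is rejected when at least two channels are flagged ("more than one"). The
baseline is deliberately per-channel — it keeps the rule scale-free across
channels with different gains; a pooled-across-channels baseline is the
plausible alternative reading. With the strict `>` comparison the
degenerate case of identical epochs (zero SD spread) flags nothing.

Homogeneous field correction builds the N×3 matrix N of good-channel
orientation vectors and removes the least-squares fit of a spatially
uniform field at every sample: `x ← (I − N N⁺) x`. The projector is
idempotent with rank N_good − 3 when the orientations span 3-space; if
they do not, a warning is raised and only the spanned subspace is
projected. In the pipeline the projector is also applied to the
leadfields, so the forward model lives in the same projected space as the
data; the small brain-signal distortion this implies is measured in the
tests rather than assumed away. HFC runs after epoch screening, matching
the stated processing order.

## Beamformer

Per band, the data covariance is computed over concatenated good epochs of
band-passed data (clean-segment covariance; using all data regardless of
artifacts is the other defensible reading) and regularised as
`C_r = C + μI`, `μ = 0.05 σ_max(C)`. The source orientation at a parcel
maximises unit-gain projected amplitude: with A = Lᵀ C_r⁻¹ L, projected
power along η is (ηᵀAη)⁻¹, so η is the eigenvector of A with the smallest
eigenvalue. Eigenvalues below 10⁻¹⁰ × the largest are treated as silent
moment directions (e.g. the radial direction of a central dipole) and
excluded from the search; the sign is fixed by making the
largest-magnitude component positive. Note a consequence verified in the
tests: with an information-free covariance (C_r ∝ I) this criterion picks
the *weakest* leadfield column, because unit gain there requires the
largest weights. Weights are the standard LCMV solution
`w = C_r⁻¹ l / (lᵀ C_r⁻¹ l)`; matrix inverses go through a symmetric
eigendecomposition with a relative eigenvalue floor of 10⁻¹², which the
Tikhonov step makes inactive in practice. An SNR-maximising orientation
(generalised eigenproblem with C_r⁻² weighting) would be a different
criterion and is not what "maximum projected signal amplitude" describes.

## Connectome

For a parcel pair (a, b), leakage correction regresses b on a in the time
domain, `b⊥ = b − (⟨b,a⟩/⟨a,a⟩) a`, which exactly removes zero-lag shared
signal; envelopes are the magnitudes of analytic signals, down-sampled
1200 → 120 Hz by non-overlapping block means (envelopes are slow, so no
anti-alias filter is needed), and Pearson-correlated against the
reference parcel's envelope. Both directions are averaged — the
orthogonalisation is asymmetric and averaging is standard practice; a
single-direction mode exists. A residual at numerical rounding level
(power ≤ 10⁻²⁰ of the source) is a degenerate direction — a pure copy —
and contributes 0 by convention rather than the spurious correlation its
rounding-noise envelope would produce.

The batch builder exploits linearity of the Hilbert transform
(`H[b − βa] = H[b] − βH[a]`): per-parcel analytic signals are computed
once and each of the P(P−1)/2 pairs costs O(T). A test asserts exact
agreement with the literal per-pair recipe.

Whole-matrix normalisation divides by √(mean of all squared elements),
including the zero diagonal (the literal reading; a toggle excludes it) —
all correlation-based reliability statistics are invariant to this
per-matrix scale. Global connectivity is the mean over the P(P−1)/2
unique off-diagonal pairs of the *unnormalised* matrix; including the
zero diagonal would only deflate it by a constant factor. At 78 parcels
there are 3003 unique pairs.

## Reliability statistics

Connectomes are vectorised from strictly-above-diagonal elements.
Group-level reliability is the Pearson correlation between run-wise
group averages of per-subject *normalised* connectomes (so one
high-amplitude subject cannot dominate); the subsample analysis repeats
this over every subject subset of each size N, with a guard that refuses
combinatorial explosions beyond 10⁵ subsets.

Individual-level analysis forms the n×n matrix of run-1 (rows) versus
run-2 (columns) correlations. The identifiability difference is
Δ = mean(diagonal) − mean(off-diagonal); its null is built by re-drawing
which n of the n² values count as "within", uniformly without replacement
(the literal resampling described for the test; a label-permutation
variant constraining one within value per subject would be the stricter
alternative), with p = (1 + #{Δ* ≥ Δ}) / (1 + iters) so p is never 0.
With n subjects the null has C(n², n) distinct draws, so small groups
floor the attainable p (n = 3 → min ≈ 0.012). Fingerprinting is row-wise:
subject s is identified iff their diagonal entry strictly exceeds every
other entry in their row; ties count as unidentified (conservative and
deterministic). Per-band p-values are Benjamini–Hochberg corrected across
the six bands at α = 0.05 (statsmodels implementation, hand-checked
oracle in the tests).

## Synthetic-data generator

Each subject owns a symmetric unit-diagonal coupling matrix in [0, 1] —
the planted envelope-correlation structure; both runs draw independent
sample paths from it, which is the entire mechanism of run consistency
(no stimulus-locked component is simulated; a run-correlated envelope
option was considered and left out). Parcel signals are
envelope × carrier:

- latent envelopes: white Gaussian processes low-passed below 1 Hz
  (synthesised at ~16× the cutoff and polyphase-upsampled — designing the
  filter at cutoff/fs ≈ 8·10⁻⁴ produces destructive edge transients),
  standardised, mixed by the symmetric square root of the coupling matrix
  (after projection onto the PSD cone by eigenvalue clipping), and mapped
  through exp(σz) with σ = 0.5, a moderate, realistic modulation depth;
- carriers: independent white noise band-passed to the carrier band
  (default α, 8–12 Hz), unit variance.

The exponential is monotone, so the planted structure survives in rank
order but not element-wise; recovery is therefore asserted with Spearman
correlation. Dipole orientations are random with the radial component
suppressed ×0.2 before renormalisation — purely random orientations would
occasionally produce near-silent (untestable) parcels. Source scale is
set so each parcel's RMS moment is 10 nAm, giving sensor-level fields of
order 10²–10³ fT at 2–4 cm standoff.

Degradations, all logged as ground truth: white channel noise with
density 13 fT/√Hz (variance = density² · fs/2); a spatially homogeneous
three-axis interference field, each axis an independent 1 pT-RMS process
low-passed below 2 Hz, coupling into channel i as oᵢ·B(t) (rank ≤ 3 by
construction — exactly the subspace HFC removes); Gaussian bursts at
20× the channel-noise SD on 10 random channels in a Bernoulli-selected
fraction (default 0.14) of 5-s epochs, chosen to mirror a realistic
bad-trial rate of roughly 17 per 120; and a 5% rate of zeroed dead
channels.

What the generator does **not** emulate: ocular/cardiac artifacts (ICA is
out of scope), head movement, realistic cortical geometry and leadfield
correlations, 1/f background spectra, multi-band sources (one global
carrier band per dataset; the single-band design also means envelope
structure leaks into spectrally adjacent bands through filter skirts —
visible as above-zero theta-band statistics in the worked example), or
mains harmonics. Passing tests demonstrate the pipeline's correctness and
its ability to recover planted structure under these idealised
conditions; they do not certify performance on real OPM data.

## Desk-scale problem sizes

The verification suites run the chain at sizes chosen to exercise every
mechanism while staying desk-friendly: beamformer localisation uses 50
repetitions of a single active parcel among 20 (16 sensors, 30-s runs);
structure recovery uses one subject, 20 parcels, 25 sensors and the full
600-s run length with coupling entries {0, 0.3, 0.6}; fingerprinting uses
5 subjects × 2 runs of 150 s with 15 parcels, 20 sensors and subject-wise
random couplings, with 2000 permutation iterations (the 100,000-iteration
default is for analysis use, not the test loop). Pilot runs across seeds
gave end-to-end Spearman recovery ≈ 0.79–0.89 and 5/5 identification;
the asserted bounds (≥ 0.6, 5/5, sensitivity ≥ 0.95 / FPR ≤ 0.05) sit
inside those margins.

## Known limitations

- The conducting-sphere forward model is exact only for the spherical
  synthetic head; no realistic-surface option is provided.
- Pairwise orthogonalisation removes only zero-lag leakage; residual
  higher-order leakage biases AEC downward, which is why absolute AEC
  values are not compared against planted values element-wise.
- The epoch-rejection baseline interpretation (per-channel) and the
  covariance data selection (clean epochs only) are documented choices
  among defensible readings, switchable in code.
- `psd_fractional_difference` follows the quoted definition literally;
  its numerator and denominator carry different units, so the value is
  comparable only across runs sharing a Welch grid (2-s Hann segments,
  50% overlap, Δf = 0.5 Hz).
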