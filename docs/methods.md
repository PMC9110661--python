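# Methods

## Signal model

A dynamic angiogram is a frame stack $I(t, r, c)$ at frame rate $f_s$
(6–7 Hz clinically), with intensities in *contrast-concentration* polarity
(larger = more contrast; the DICOM reader inverts native fluoroscopic
brightness on request). Because $f_s$ exceeds twice the cardiac frequency
(1–2 Hz), each pixel's time signal resolves a cardiac-band oscillation
superimposed on the bolus envelope. A concurrent pulse-oximeter trace
provides the external cardiac reference.

## Gabor wavelet cross-correlation

The analytic Gabor (Morlet) mother wavelet at scale $a$ seconds is

$$\psi_a(u) = \pi^{-1/4} a^{-1/2} e^{i\omega_0 u/a} e^{-u^2/(2a^2)},$$

with equivalent analysis frequency $f = \omega_0/(2\pi a)$. Coefficients
are correlations of the zero-mean signal with $\psi_a^*$, computed by FFT
convolution with reflect padding; frames closer than $a\sqrt2$ seconds to
either record edge (the cone of influence) are flagged invalid and zeroed.

Defaults, chosen as standard admissible values since the method itself does
not prescribe them:

| parameter | default | rationale |
|---|---|---|
| $\omega_0$ (image) | 6 | classic admissible Morlet choice; good time-frequency balance at 6 Hz sampling |
| $\omega_0$ (trace) | 12 | the trace is filtered at comparatively high frequency resolution (≥ 2× the image value) |
| scale grid | 32 log-spaced scales over 0.5–3.0 Hz | covers physiologic cardiac rates; the grid is clipped strictly below the Nyquist frequency of the acquisition |
| magnitude floor | 0.1 × median | reference frames with near-zero trace magnitude carry no phase and are dropped |

The *cardiac reference* is the unit-normalized coefficient row of the trace
at the scale maximizing time-mean squared magnitude within the band. Every
pixel is then transformed at the single image-domain cardiac scale
$\omega_0^{img}/(2\pi f_\star)$ and multiplied by the conjugate reference
phasor. With one retained scale this demodulated product *is* the
time-domain complex envelope — a full inverse wavelet transform restricted
to one scale is proportional to it, and the constant cancels in all
downstream phase and coherence statistics. An optional magnitude-weighted
average over ±`band_width` neighbouring grid scales is exposed but off by
default.

Per-pixel temporal means are removed before transformation; the slow bolus
envelope itself leaks negligibly into the cardiac band at $\omega_0 = 6$
(the Gaussian frequency response at DC is $e^{-\omega_0^2/2} \approx
10^{-8}$, and the zero-noise validation below bounds the total effect).

## Coherence masks

At one analysis frame — the valid frame between the arterial and venous raw
bolus peaks that maximizes the real part of the arterial ROI mean — every
pixel's signed projection $\mathrm{Re}\,(z \cdot \overline{u}_{ROI})$ onto
the seed ROI's unit mean phasor is computed. Positive projection means
relative coherence (within ±π/2); zero or negative means reciprocal
coherence (a projection of exactly zero is classified reciprocal so the
boundary is deterministic). Otsu's histogram threshold (256 bins,
between-class variance, ties toward the lower edge, equality with an
exhaustive search over bin edges verified in tests) binarizes the signed
projections of coherent pixels *inside the intracranial mask* —
extracranial pixels are pure background and would only bias the threshold
toward noise. Each vessel mask is the suprathreshold coherent set inside
the intracranial mask, minus both seed ROIs (so the segmentation never
certifies the pixels it was conditioned on); a pixel qualifying for both
vessel masks goes to the larger projection (ties to arterial). The
parenchymal mask is the intracranial remainder.

Standard Otsu is purely histogram-based; descriptions of it as spatially
selective cannot be reconciled with the cited method. We therefore
implement the standard histogram form and expose an optional
minimum-connected-component filter (8-connectivity, default off) that
removes isolated coherent single pixels when that behaviour is wanted.

The canonical segmentation is single-frame; `mask_stability` quantifies how
little the masks change when recomputed at other valid frames.

## Time-signal statistics

Masked curves report mean ± standard error per frame (normalizing for mask
size). Mean arrival time is the time centroid $\bar t = \sum s_i t_i /
\sum s_i$ after subtracting the curve minimum and clamping at zero
(angiographic curves ride on a pre-contrast pedestal; the centroid formula
assumes $s_i$ is contrast signal). Two caveats are inherent to the
estimator and verified by tests: residual contrast truncated at the last
frame biases $\bar t$ early, and because the *minimum* of a noisy baseline
lies a few standard errors below its mean, a small positive pedestal
survives subtraction and pulls every $\bar t$ slightly toward the record
centre — a shared, order-preserving bias.

With three masks there are $3! = 6$ possible MAT orderings per projection;
the hypothesized joint ordering across $P$ projections has null probability
$6^{-P}$ ($6^8 = 1{,}679{,}616$ combinations for an eight-projection
study). Ordering requires strict inequalities; ties are flagged, never
broken silently.

The Monte Carlo check subsamples 100 mask pixels without replacement, 1000
times, and compares the per-frame dispersion of subsample means with the
analytic finite-population standard error
$\sqrt{(\sigma^2/n)\,(N-n)/(N-1)}$.

## Synthetic validation

Every phantom pixel carries a gamma-variate bolus envelope (shape $k$,
scale $\theta$, delay $d$, normalized to unit peak then scaled by $A$) and
an envelope-gated multiplicative cardiac modulation:

$$s(t) = \mathrm{env}(t)\left(1 + \tfrac{a_c}{A}\cos(\Phi(t) + \varphi)\right)
          + \mathcal N(0,\sigma) + B .$$

Multiplicative gating was chosen over additive modulation because cardiac
power physically exists only where contrast is present. The phase integral
$\Phi$ (constant 1.2 Hz by default; optional per-beat period jitter) is
shared with the emitted synthetic pulse trace $\cos\Phi$, so trace and
pixels are coherent by construction. The pedestal $B = 2$ (6σ) keeps
intensities nonnegative under the additive noise.

Compartment defaults reflect cerebral bolus physiology — the injected bolus
is several seconds wide, *wider* than the few-second arterial-to-venous
transit, so all three envelopes overlap strongly at any mid-passage frame
while their centroids stay ordered:

| compartment | k | θ (s) | d (s) | A | a_c | φ centre (sd) | MAT $d + k\theta$ |
|---|---|---|---|---|---|---|---|
| arterial | 2.0 | 2.5 | 3.5 | 1.00 | 0.60 | 0 (0.3) | 8.5 s |
| parenchymal | 2.0 | 3.5 | 4.5 | 0.30 | 0.06 | π/2 (1.0) | 11.5 s |
| venous | 1.6 | 7.0 | 4.5 | 0.85 | 0.50 | π (0.3) | 15.7 s |

Venous phases are centred π from arterial — the reciprocity the analysis
must recover. Cardiac modulation depths of tens of percent of the bolus
peak reflect the strong pulsatility of contrast concentration in major
cerebral vessels; parenchymal (capillary-blush) pulsatility is near zero.
`noise_sigma = 1/3` sets the bolus signal-to-noise ratio $A/\sigma = 3$.
The default geometry is 128×128 pixels and 256 frames at 6 Hz (<10 s to
render and analyze): two procedurally drawn, structurally disjoint vessel
trees (~900 pixels each) inside an elliptical intracranial mask.

The negative control (`control_mix`) draws each vessel pixel's *cardiac*
parameters ($a_c$, φ) from a 50/50 mixture of the arterial and venous
distributions, making the two populations exchangeable in cardiac behaviour
while bolus travel keeps its compartment identity (so ROI placement and
frame selection remain well-posed). Recovery is scored by pairwise
Fisher–Lee circular correlation and circular RMSE of phases, Pearson
correlation of magnitudes, mask Jaccard indices (with their
independence-model chance levels), the circular-mean arteriovenous phase
separation, and its concentration (mean resultant length of pooled
pixel-vs-other-compartment phase contrasts). Because control masks still
select vessel pixels — cardiac amplitude is high there — "chance overlap"
is assessed by the *discrimination* index (own-compartment minus
cross-compartment Jaccard), which is ~0.75 in normal runs and ~0 under
mixing.

## Numerical notes and limitations

* The FFT convolution path agrees with a definition-level correlation sum
  to ~10⁻¹⁵ relative; Otsu agrees exactly with exhaustive search (the
  tie-toward-lower rule is applied over the floating-point plateau of
  maximal between-class variance).
* During the first seconds of bolus onset the envelope's relative growth
  rate is large and the instantaneous phase of any single-scale analytic
  filter is transiently biased (~0.3 rad at zero noise); once a pixel's
  coefficient magnitude reaches ~20 % of its peak the demodulation identity
  holds to <0.05 rad. Phase statistics therefore weight by magnitude
  (time-summed coefficients) or gate on that floor.
* The pairwise form of the Fisher–Lee circular correlation is used because
  the mean-deviation form degenerates on the antipodal bimodal
  arterial+venous phase mixture. Its value is bounded by the ratio of true
  within-compartment phase variance to recovery-error variance, so with
  tight assigned spreads (sd 0.3 rad) even excellent recovery yields ~0.75,
  while RMSE stays ~0.25 rad at SNR 3 and ~0.007 rad at zero noise.
* What the phantom does *not* emulate: anatomically realistic vascular
  trees, x-ray physics (scatter, beam hardening), patient or table motion,
  contrast recirculation, and frame-time jitter beyond the optional beat
  jitter. Passing tests therefore demonstrate correctness of the signal
  chain under the stated model, not robustness to those real-data effects.
* Nonuniform DICOM frame timing beyond 10 % of the frame period is
  rejected rather than resampled; biplane geometry and motion correction
  are out of scope.
* The trace-to-frame alignment assumes the clinical recording rig
  introduces no unknown latency; `t0` offsets on both containers are the
  escape hatch when it does.
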