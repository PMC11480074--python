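# Methods

## Transport model

Alpha particles are transported in the continuous-slowing-down
approximation (CSDA) along straight tracks in unit-density liquid water.
No energy-loss straggling, delta-ray escape or multiple scattering is
modelled, and the medium is homogeneous — in tissue geometries the packing
gaps and intervening cells are water like everything else.  These are the
standard assumptions for cellular alpha dosimetry at the 1–100 μm scale:
alpha tracks are nearly straight, straggling is a few percent of range,
and delta-ray ranges are sub-micrometre.

The range-energy relationship R(E) is a monotone piecewise-cubic (PCHIP)
interpolant in log-log space through an embedded ~25-row CSDA table
(`data/alpha_water_csda_range.tsv`, 0.1–10 MeV).  The table is an
approximate compilation in the ICRU-90 / ASTAR lineage; its header states
its provenance and accuracy intent.  The fitted curve is resampled onto a
dense shared-node log-log grid so that the forward and inverse maps are
piecewise-linear exact mutual inverses (round-trip error ~1e-15; the
inverse's resolution floor, R below ≈0.02 μm ↔ E < 1e-8 MeV, maps to
zero energy).  The coefficient of determination of the fit against the
table is ≥ 0.999 by construction and asserted in tests.  Energy deposited
over a chord is `ε = E(R₀−s_entry) − E(max(R₀−s_entry−chord, 0))`, which
makes deposition exactly additive along a track.

## Geometry and conditioned sampling

Cells are concentric spheres (nucleus r_n, cell r_c) with the target
nucleus at the origin.  Tissue is a simple-cubic lattice of identical
cells with spacing 2·r_c ("packed" is interpreted as the simplest
non-overlapping arrangement; the packing type is isolated in
`TissueLattice` should variants be needed).  The lattice holds every cell
whose centre lies within `d_max = R(E₀) + 2 r_c` of the target.

Isotropic emission conditioned on geometrically hitting the nucleus is
uniform over the cone of half-angle `θ_max = arcsin(r_n/d)` (π inside the
nucleus), with per-point hit probability `w(d) = (1 − cos θ_max)/2`.
Rather than weighting scored events, the emission-point sampler absorbs
the weight: the radial coordinate is drawn with density ∝ `d² · w(d)`
over the region's radial support (truncated at the reachable distance
`R(E₀) + r_n`), directions uniformly on the sphere, and — for tissue
regions, whose support is not spherically symmetric — membership in the
region (nearest-lattice-cell test) is enforced by rejection.  Scored hits
are therefore equal-weight draws from the true conditional distribution;
an unbiasedness test compares chord-length distributions against naive
uniform-point/isotropic-direction rejection sampling (KS at 10⁵ events).
The radial inverse CDF is tabulated on a 2048-point grid per design; the
resulting quadrature bias is far below Monte Carlo noise.  Tracks that
exhaust their range before entering the nucleus deposit nothing and are
discarded: a "hit" requires ε > 0.  The region-averaged geometric hit
probability over the physical (uniform) source distribution is estimated
on a side batch and recorded in simulation metadata so absolute hit
frequencies can be reconstructed.

Perinuclear-shell tissue sources place activity between 1.25·r_n and the
cell membrane; at cell-to-nucleus ratio 1.25 that shell is empty, so the
tissue grid omits those combinations.

## Dataset

2270 design points at the default composition: a 160-point suspension
grid (4 regions × 8 therapeutic alpha energies × 5 representative
(r_n, r_c) pairs (2,3), (3,5), (5,10), (6,12), (10,15) μm), 160 random
suspension designs uniform over E₀ 3.97–8.78 MeV, r_n 2–10 μm,
r_c 3–15 μm with r_c > r_n, and a tissue grid (4 regions × 10 energies ×
13 nucleus radii × ratios 1.25/1.5/1.75/2, cell radii kept in
2.5–20 μm).  Each design is simulated with 2×10⁴ scored hits (configurable);
per-design RNG streams are spawned from one seed, so builds are
deterministic and order-independent.

Targets are `z_max` (strict maximum of the scored specific energies; a
percentile mode exists for noise robustness but the default is the strict
maximum) plus the 20 unit-area density bins in Gy⁻¹.  The training
transform is `t₀ = ln(1 + 4·z_max)`, `t_k = ln(1 + f_k)`: the log
symmetrises the highly skewed densities, the +1 offset keeps empty bins
at 0, and the ×4 factor lifts z_max (typically 0.05–4 Gy) onto the same
numeric scale as the densities (typically 0.4–40 Gy⁻¹) so the MSE loss
weights the 21 outputs comparably.  Densities are kept per Gy rather than
per cGy: with realistic magnitudes this is what makes the ×4 ratio
argument work, and the density values then sit in the printed 1–10 window.
The split is a uniformly random 70/15/15 partition.

The source region enters the network as a single numeric code 1–8 (the
4-input architecture precludes one-hot encoding).  This forces eight
qualitatively different geometry families onto one ordered axis and is a
known expressiveness bottleneck, kept for fidelity to the architecture.

## Surrogate and training

The network is a 4-10-26-21 MLP, tanh hidden layers, linear output,
903 parameters.  (A fully biased 4-10-26-21 network has 903 weights and
biases; the frequently quoted 876 corresponds to a 20-output network —
the drawn 21-output architecture is implemented.)  Inputs are min-max
normalised to [−1, 1] with training-partition bounds stored in the model;
targets stay in transform space, and all RMSE values are reported there.

Training is Levenberg–Marquardt on the analytic residual Jacobian:
`(JᵀJ + λI) δ = −Jᵀr`, λ starting at 1e-3, ÷10 on an accepted step
(training MSE strictly decreased), ×10 on rejection with up to 12 retries
per epoch, stall at λ > 1e10; at most 1000 epochs with validation early
stopping and the best-validation snapshot returned.  The patience default
is 20 consecutive epochs without a new validation minimum: the classical
6 (typical for gradient trainers) proved too short here because the λ
oscillation of LM produces transient validation plateaus longer than 6
epochs in mid-descent, and with the best-snapshot rule a longer patience
can only improve the returned validation optimum.  Initialisation is layer-wise
uniform scaled by fan-in, U(±sqrt(3/n_in)); a Nguyen–Widrow mode (unit
weight vectors scaled to 0.7·H^(1/n), biases tiling the active range) is
available but in our experiments converged to flatter memorisation
minima on small fixtures without improving full-scale fits.  LM on this
loss surface is sensitive to the initial basin, so final fit quality
varies noticeably with the training seed; an optional multi-restart mode
(`TrainConfig.n_restarts`, child RNG streams, lowest validation MSE wins)
is available, though pooled validation MSE is only loosely coupled to
z_max accuracy, so the default is a single run.  `JᵀJ` is accumulated
with a symmetric rank-k BLAS update and the damped system solved by
Cholesky factorisation.

The hidden-size grid search trains one network per (h₁, h₂) over
h₁ 10–20, h₂ 10–40 and reports the validation-RMSE table and its argmin.

## Evaluation

RMSE and pooled predicted-vs-actual regressions (OLS of predicted on
actual; R² as squared correlation) are computed per partition for two
output groups: the single z_max output and the 20 spectral outputs
pooled.  Moment errors compare midpoint-rule moments — bin k contributes
at z = (k−½)·z_max/20 — of the predicted spectrum (inverse-transformed,
negative densities clipped, renormalised to unit area) against the paired
Monte Carlo spectrum, as per-record percent differences summarised by
mean, SD and a percentile (2.5–97.5) 95% interval; the percentile form is
used because the reference intervals are asymmetric about their means.
Using the midpoint rule on both sides cancels the binning bias (a
degenerate spectrum at c has midpoint mean (39/40)·c) so the comparison
probes the surrogate only.

## Problem sizes and reproduction

`scripts/acceptance.py` runs the full pipeline: 2270 designs × 2×10⁴
hits (~1.5 min of vectorised MC on one CPU), then best-of-3 LM training
capped at 300 epochs per restart (~3–4 min; validation early stopping
typically fires near 100 epochs).  The test suite uses a 60-design ×
2000-hit corpus for surrogate tests plus one full-scale end-to-end run.

## Known limitations

* CSDA with straight tracks: no straggling or delta-ray escape, so
  spectra lack the few-percent smearing of a full track-structure code.
* The embedded range table is an approximate compilation; absolute ranges
  carry a few-percent uncertainty (spectra scale accordingly), while all
  internal consistency properties are exact.
* Simple-cubic packing is one of several plausible "packed grid"
  readings; packing fraction affects tissue-region spectra at the few
  percent level.
* The single numeric region code limits the network's expressiveness
  across geometry families; relative errors concentrate at small-z_max
  corner designs (large nuclei, near-equal r_n ≈ r_c), where the
  ln(1+4z) transform's error amplification (1+4z)/(4z) is largest.  The
  per-record moment-error SDs — especially for ⟨z₁²⟩, which compounds the
  z_max error quadratically — are dominated by a handful of such designs.
* Synthetic Monte Carlo targets mean that passing tests demonstrate
  self-consistency of the pipeline and surrogate on CSDA physics, not
  agreement with measured microdosimetric spectra.
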