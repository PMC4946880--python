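# Methods

This note documents the models, estimators and synthetic study designs the
package implements, the parameter choices behind them, and what the
validation studies do and do not demonstrate.

## Scan simulator

Molecules are point emitters performing Brownian dynamics in a reflecting
box, observed through a 3D Gaussian point spread function (PSF) with
lateral waist `w0` (default 0.25 µm) and axial waist `wz = 3·w0`, and
detected by an ideal photon counter: pixel counts are Poisson with mean

    background + Σ_m A_m · exp(−2Δr²_lat/w0² − 2Δz²/wz²).

**Brightness convention.** A species' `brightness_per_unit` ε is the
*apparent* molecular brightness in counts/pixel-dwell/molecule — the
quantity N&B reports as B−1 and the unit used on instrument calibration
sheets. The renderer converts it to a peak detection rate `A = ε·2^{3/2}`;
the factor is the shape factor γ = 2^{−3/2} of the 3D Gaussian volume
(∫q²/∫q). Under this convention a simulated monomer of ε = 0.28 reads back
B−1 ≈ 0.28, and a homodimer (two fluorophore units) reads 2ε.

**Time discretisation.** Particles take one diffusion step per scan line
(variance 2·D·Δt per axis) and are frozen within a line. For D ≤ 10 µm²/s
at the recommended raster timings, intra-line motion is ≪ w0 and the
approximation is exact for all row-lag statistics. For solution scans of
fast dyes (D = 78 µm²/s), where motion between pixels of the same line
matters, the renderer supports per-pixel time resolution with the
trajectory sampled at the pixel dwell.

**Barriers.** Walls are planes perpendicular to the scan axis with
directional transmission probabilities (p_forward, p_reverse); rejected
crossings reflect. The step size must resolve the wall spacing
(RMS step < gap/4), enforced at simulation time. The axial domain is a
slab of thickness 6·wz. Confined species (used to emulate
chromatin-associated complexes) reflect inside a cube around their seed
position.

Photobleaching, optical aberrations and analog-detector excess noise are
not modelled; the S-factor machinery still applies as a pure rescaling.

## RICS

The spatial autocorrelation `G_S(ξ,ψ) = ⟨δI(x,y)·δI(x+ξ,y+ψ)⟩/⟨I⟩²` is
computed per frame by zero-padded FFT (no wraparound, per-lag overlap
normalisation) and averaged over frames; it equals the direct O(n⁴)
shifted-product sum to 1e−10. Before correlation, the immobile fraction is
removed by subtracting from each frame the mean of the 11-frame window
centred on it (frames i−5…i+5) and re-adding the series grand mean; the
first and last 5 frames are dropped. The fitted model is the one-component
3D Gaussian form

    G_S = G0 · (1 + 4Dτ/w0²)⁻¹ (1 + 4Dτ/wz²)^{−1/2}
             · exp(−((ξδx)² + (ψδx)²) / (w0²(1 + 4Dτ/w0²))),

with τ = τ_pixel·|ξ| + τ_line·|ψ|. Fitting is bounded least squares over
(D, G0), D ∈ [10⁻³, 10³] µm²/s, multi-started at D0×{0.1, 1, 10}, with the
(0,0) lag excluded (shot-noise spike). A fit passes QC when the ACF peak
is at least 3× the largest residual. PSF calibration fits the same model
on a homogeneous dye-solution scan with D clamped to 78 µm²/s, solving
for w0 (wz tied at 3·w0); the moving-average step is skipped there since
a solution has no immobile fraction.

Validation: across D ∈ [1, 10] µm²/s at the recommended timings (64-px
images, 40 frames — scaled from 256 px to keep runtimes at desk scale),
the median relative error of recovered D is well under 15%, and recovered
w0 is within 10% of truth.

## pCF

Pair correlation at pixel separation δr, `G(τ,δr) =
⟨F(t,0)F(t+τ,δr)⟩/(⟨F(t,0)⟩⟨F(t,δr)⟩) − 1`, is evaluated by FFT at
log-spaced delays (32 points/decade from one line time to n/10 line
times). The period-averaged display view (800-line blocks) is separate
from the analysis series; bleaching is flagged on a monotone >20% decline
of the per-period mean, with an optional tail trim.

**Automated arch call.** The paper-style call is visual; here it is a
permutation test. The statistic is the maximum over delayed τ
(10–1000 lines; crossing delays at cellular distances sit well below a
second) of the lightly smoothed pair correlation averaged over every
wall-straddling column pair. Columns within 2 px of the wall are excluded:
a molecule pressed against an impermeable barrier bleeds into the first
columns on the far side through the PSF tail and would mimic a crossing.
Both columns are detrended (8000-line moving average) to remove slow
occupancy drift. The null distribution circularly time-shifts the far
columns by random offsets far outside the correlation band (200 draws),
preserving marginal and autocorrelation structure exactly while destroying
cross-column delay structure. Because the shift draws overlap, the
effective number of independent null samples is only about
(series length)/(band width); the raw empirical 95th percentile is
therefore noisy on shorter series, and the decision threshold instead uses
a Gumbel location-scale fit to the null sample (the statistic is a max
over roughly independent lags), evaluated at the 95% point. The call is 1
iff the statistic exceeds that threshold. The Movement Index is the mean of calls over
δr ∈ {5, 7, 9} within a replicate, averaged over replicates.

**Study design.** Line scans use 0.25 µm pixels, 0.5 ms line time and up
to 2×10⁵ lines (the full acquisition protocol), with sparse bright
molecules (24 molecules, ε = 8 counts/dwell — the single-molecule contrast
regime pCF needs) diffusing at 6 µm²/s in a thin channel (±0.4 µm in y and
z) along the scanned line, two cells and one wall running through the
centre of column 16. For unidirectional studies the domain is a
source-sink system: molecules start upstream and any molecule leaving the
domain downstream is reinjected upstream, sustaining the flux that a
continuously producing tissue provides (a closed box would drain its
upstream compartment within seconds at these diffusivities). Drift
checking compares the wall-marker profiles of the reference images taken
before and after the series — the marker is the only structure static over
the acquisition. The thin channel stands
in for the cytoplasmic strip the line is positioned along; without it,
three-dimensional dilution of the crossing signal would demand far longer
acquisitions than a desk-scale study permits. Consequences: the detection
*power* measured here is optimistic relative to a full 3D cytoplasm, while
the false-positive calibration is unaffected.

## N&B and cross-N&B

Per pixel, over K frames: mean ⟨k⟩, population variance σ² (divisor K),
apparent brightness B = S·σ²/⟨k⟩ and apparent number N = ⟨k⟩²/σ². The same
11-frame moving-average detrend as RICS is applied first; the residual
variance is divided by (1 − 1/11), which makes the estimator exact for
frame-independent noise — pure Poisson input reads B = 1 regardless of
intensity. The S-factor is 1/median(raw B) over background-only pixels,
placing the background at exactly B = 1.

Monomer calibration takes ε as the mode (KDE, narrow bandwidth) of B−1
over fluorescent pixels — pixels above shot noise carrying real signal —
after 3×3 boxcar smoothing of the map (per-pixel variance estimates are
right-skewed at K ~ 100, and neighbouring pixels sample the same
molecules). The cursor spans the central 95% of the monomer distribution,
clipped to 0.9·ε so the monomer and dimer windows cannot overlap. A
bimodal brightness distribution aborts calibration. Classification counts
pixels in the monomer window (centre 1+ε) vs the dimer window (centre
1+2ε — brightness above background doubles, the shot-noise unit does not),
as percentages of monomer+dimer pixels.

Cross-N&B computes the per-pixel cross-variance σ_cc² of detrended
fluctuations, B_cc = σ_cc²/(⟨G⟩⟨R⟩) and N_cc = ⟨G⟩⟨R⟩/σ_cc². Pixels are
called complexed when smoothed B_cc exceeds the 95th percentile of a
temporal-shuffle null (red channel frames permuted); among complexed
pixels with red brightness in the red monomer window, green brightness in
the monomer vs dimer window distinguishes 1:1 from 2:1 stoichiometry.

**Study design.** Pixel-cursor counting is only meaningful when brightness
varies across the image. Freely mixing species average into every pixel
identically, so the oligomer and complex studies simulate entities as
*confined* diffusers (0.25 µm reflecting excursion box, local D 1 µm²/s,
homes near the focal plane) — emulating the chromatin/nuclear association
of SHR homodimers and SHR-SCR complexes — at ~150 entities per 6.4 µm
field (about one entity per PSF-sized spot, which makes pixel fractions
track entity fractions), ε = 2 counts/dwell/unit. Under these conditions a
92.5/7.5 monomer/homodimer mixture reads back 7–9% homodimer, recovery is
monotone in the true fraction over 0–20%, and an 85/15 complex mixture
reads back a 2:1 share between 10 and 20%. What passing these studies does
*not* show: unbiased recovery for fast-diffusing (non-confined) oligomer
pools, or at densities far from one entity per resolution spot.

## SHR/SCR model

Six ODEs (time unit: hours) for vascular SHR (Sv), endodermal SHR monomer
(Se), homodimer (S2e), SCR (C), and the 1:1 (SC) and 2:1 (S2C) complexes:

    dSv/dt  = k1 − a1·Sv + a2·Se − d1·Sv
    dSe/dt  = a1·Sv − a2·Se − d2·Se
    dS2e/dt = k2(C)·Se² − d3·S2e,   k2(C) = L/(1+e^{−k(C−C0)})
    dC/dt   = k3·(K1D²C + K1D·SC + S2C) /
              (K1D²K2D + K1D·K2D·Sv + K1D²C + K1D·SC + S2C) − d4·C
    dSC/dt  = k4·Se·C − d5·SC
    dS2C/dt = k5·S2e·C − d6·S2C

Wild type has a2 = 0; the SCR-knockdown variant clamps dC/dt = 0 (SCR held
below the homodimer threshold) and sets a2 = D2/A2. Transport rates are
measured diffusion coefficients over cell areas, converted to 1/hr
(a1 = 2.45 µm²/s / 100 µm² = 88.2 hr⁻¹), which puts SHR equilibration on a
sub-minute timescale. The monomer equation carries no consumption terms
for dimerisation or complex formation — kept exactly as formulated; it is
a modelling simplification, not corrected here. Composition metrics are
entity-wise (S2e/(Se+S2e)), matching what pixel-wise N&B counts.
Integration uses LSODA at rtol 1e−8; nonnegativity comes from tolerances,
never clipping. The wild-type system needs C(0) > 0 (SCR production is
autocatalytic through the Hill term); the default initial state is empty
except for a small SCR seed (C(0) = 10).

**Default parameters.** The packaged table mixes provenance (flagged per
row): measured rates (D1, D2, the logistic constants L = 0.5, k = 0.1,
C0 = 360), cell areas and kinetic constants chosen so the model reproduces
the reported dynamic structure — SHR steady within minutes, SCR rising
strongly over the first hours, homodimer and 2:1 complex appearing only
after SCR crosses its threshold, and the full system settling between 18
and 24 h — and two derived constants. Notably, at steady state both
composition measurements depend on the single combination x = k2(C)·Se/d3
(S2C/SC = (k5·d5/(k4·d6))·x), so both targets are simultaneously
attainable by tuning {d2, K2D, L} only if the fixed complex-sector rates
satisfy k5·d5/(k4·d6) = (15.2/84.8)/(7.5/92.5) ≈ 2.211. The defaults
therefore set k5 = 2·k4 (a homodimer presents two equivalent binding
interfaces) and fix d6 from that ratio — the relative 2:1 balance is
derived from the measured stoichiometry, and the table says so.

**Calibration.** Cyclic coordinate descent over {d2, K2D, L} (k3, d4 held
fixed), each step a log-grid line search plus golden-section refinement,
at most 3 cycles, minimising the larger absolute deviation of the two
steady-state percentages from their targets (tolerance 0.5 points). C0 is
re-tied to 60% of the running SCR steady state each cycle. The search is
restricted to the directions that reach the constraints — d2 upward, K2D
and L downward — which also keeps it off a degenerate branch where
collapsing SCR itself (K2D → ∞) zeroes the homodimer while contradicting
the observed SCR accumulation. The procedure is deterministic given the
defaults; it lands within 10⁻³ points of both targets.

## Sobol sensitivity

Radial design: independent N×15 draws A and B from the parameter space,
plus C_i (A with column i from B); outcomes are trapezoidal time-integrals
of the six states over [0, 24 h]; the total-effect index uses the Jansen
estimator S_Ti = [(1/2N)Σ(f(A)−f(C_i))²]/V(Y). Failed integrations are
excluded pairwise. The varied set is {k1, a1, a2, d1…d6, k3, k4, k5, K1D,
K2D, L}; the logistic shape constants k and C0 are held fixed. Bounds are
[0.25×, 4×] each default, except the transport rates a1, a2 — the least
constrained quantities, since they fold in cell geometry — which are
explored log-uniformly over [⅛×, 8×] (a2 around the measured knockdown
value D2/A2, as the question is how reverse transport would matter if
present). Replicates are z-normalised across parameters per outcome before
averaging; parameters are flagged influential per outcome when pairwise
Wilcoxon rank-sum tests with the Steel-Dwass critical-range adjustment
(studentized-range critical value at α = 0.10) separate them from more
than half of the rest without being beaten by any. With fewer than ~8
replicates the adjusted test cannot reach significance even under complete
separation, so flags require the full replicated run.

## Problem sizes

Validation studies run at reduced sizes chosen once for desk-scale
turnaround: 64-px rasters (40 frames for RICS, 100 for N&B), 10⁵–2×10⁵
scan lines for pCF, N = 48–1000 with 2–10 replicates for Sobol. The
acceptance script's quantities (model compositions, background
brightness) are insensitive to these choices; the imaging recoveries are
statistical statements at the stated sizes.

## Known limitations

* The scan simulator's line-frozen motion model slightly understates
  intra-line decorrelation for D ≳ 20 µm²/s unless pixel-resolution
  rendering is requested.
* The pCF thin-channel geometry overstates detection power relative to a
  full 3D cytoplasm (see above).
* The arch call's false-positive rate is calibrated on 5×10⁴ to 2×10⁵
  line acquisitions; far shorter series leave too few independent shift
  positions for even the parametric null-tail estimate.
* Oligomer-fraction recovery degrades above ~20% dimers (fringe overlap
  between bright spots biases pixel counts upward).
* The ODE model inherits the formulation's lack of monomer consumption;
  absolute concentrations are in arbitrary units and only composition
  percentages are compared to measurement.
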