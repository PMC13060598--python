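# Methods

This note records the models implemented in `sptstates`, the numerical
choices behind them, what the synthetic-data generator does and does not
emulate, and the known limitations. Units are micrometres and seconds
throughout the library; localization tables use nanometres at I/O only.

## Multi-state free diffusion and the trajectory generator

Trajectories are modelled as 2D Brownian motion with a hidden Markov
state: during the frame in which state *s* is active, each axis increment
is Gaussian with variance 2·D_s·Δt, and the state switches only at frame
boundaries according to a row-stochastic per-frame transition matrix T.
Observed positions add independent Gaussian localization error (default
σ = 9 nm per axis, the magnitude measured for fixed-cell data). The
apparent per-axis step variance is therefore 2·D_s·Δt + 2·σ².

The reference models ship with the published apparent diffusion
coefficients at 50-ms frames:

- interphase, three states (bound / liquid-like / dissociated):
  D = 0.0354, 0.114, 1.85 µm²/s, stationary occupancies 0.30/0.60/0.10;
- metaphase, two states (bound / liquid-like):
  D = 0.0463, 0.125 µm²/s, occupancies 0.30/0.70.

The per-frame transition percentages are not available as machine-readable
values, so the reference transition matrices are constructed by detailed
balance around the published stationary occupancies, with the
liquid-like ↔ dissociated exchange carrying the largest flux (the
dominant transition in the published state graph):

    interphase T = [[0.89, 0.10, 0.01],
                    [0.05, 0.89, 0.06],
                    [0.03, 0.36, 0.61]]      metaphase T = [[0.93, 0.07],
                                                            [0.03, 0.97]]

Track lengths follow 2 + Geometric attrition (default mean 20 detected
points, minimum 2), a standard model for photobleaching/defocus-limited
track survival; the real track-length law of the source experiments is
not published, so this is an assumption, not a measurement. Initial
states are drawn from the stationary distribution (steady-state
sampling), tracks start uniformly in the field of view, and diffusion is
not confined to it. Motion blur within the exposure, blinking
photophysics, and 3D motion are deliberately not modelled; passing tests
therefore validate estimator correctness under additive white Gaussian
localization error, not robustness to blur or defocus effects present in
real recordings.

## MSD analytics

`compute_msd` time-averages squared displacements over all overlapping
start times within a track and pools tracks (time-and-ensemble average);
per-cell curves are retained when a `cell` column is present so the
mean ± SD among cells is computable. MSD uses the 2D convention
MSD = 4·D·Δt; the isotropic 3D estimate multiplies the 2D value by
exactly 1.5 (4·D·Δt → 6·D·Δt). D is fitted by least squares through the
origin; the anomaly exponent α is the slope of log MSD vs log Δt
(log-log least squares — the estimator is not otherwise pinned down by
the source material, so this documented choice applies). Default fit
ranges are 0.05–1 s for pooled data and 0.05–0.5 s for per-state curves.
Fitted D values are apparent: no localization-error or blur correction is
applied. Localization precision is estimated from fixed emitters as the
mean of the per-axis Gaussian SDs of deviations from each track centroid;
the per-track centroid subtraction biases the estimate low by the factor
√(1 − 1/n_frames), negligible at the 50-frame default.

## Richardson–Lucy deconvolution of displacement distributions

The van Hove self-correlation Gs(r, Δt) of step magnitudes is binned on
linear r bins (default 200) and represented as a planar density
(counts / (N·2π·r_c·Δr)), so that Σ Gs·2π·r_c·Δr = 1 exactly. For 2D
Brownian steps with single-molecule MSD M, the displacement kernel is
q(r, M) = exp(−r²/M)/(πM), and Gs = ∫ q(r, M) P(M) dM. The RL iteration

    P_{n+1}(M) = P_n(M) · ∫ 2π r q(r, M) [Gs(r)/Gs_n(r)] dr

is discretized with trapezoid quadrature on a log-spaced M grid (default
120 points over [1e−5, 10] µm²). The discrete kernel columns are
normalized by c_j = Σ_r 2π r Δr q(r, M_j) so that an exact discrete
forward model is an exact fixed point of the update; every iterate is
clipped non-negative and renormalized to ∫P dM = 1. The iteration is the
EM algorithm for a mixture of displacement kernels, so the KL divergence
between data and model Gs is non-increasing (up to the ~1e-8 float drift
introduced by the per-iterate renormalization). Iteration stops when the
L1 difference between successive iterates falls below 1e−6 or at 20,000
iterations. The cap matters: RL locks onto peak positions quickly but
sharpens peaks slowly, and with the two slow states only 0.5 decade apart
(4·D·Δt = 0.0071 vs 0.0228 µm²) at least ~2×10⁴ iterations are needed
before the peaks separate cleanly; the `converged` flag records honestly
whether the tolerance or the cap terminated the run. The result is
insensitive to the initial-scale parameter M0 across at least two
decades (verified by test).

State counting fits Gaussian mixtures over log10 M to the deconvolved
P(M) for k = 1..k_max and selects k by BIC. Because the mixture fitter
is sample-based, P is converted to a seeded weighted resample (20,000
points, uniform within-grid-cell jitter), which makes the fit
deterministic for a fixed seed. Two post-selection rules convert the
BIC-best mixture into a state count: components carrying < 2% of the
mass are ignored (BIC occasionally spends a vanishing-weight component
on an empty tail), and components whose means lie within 0.15 decade are
merged (BIC occasionally splits one sharp, slightly non-Gaussian RL peak
in two). Both thresholds are far from the smallest real peak separation
in scope (0.43 decade, the metaphase pair).

## HMM state classification

The classifier is a hidden Markov model over per-frame displacement
steps: emission of state *s* is a zero-mean isotropic 2D Gaussian with
per-axis variance 2·D_s·Δt; hidden states follow the per-frame
transition matrix. Parameters are estimated by maximum-likelihood
Baum–Welch EM (exact M-steps: D_s from posterior-weighted mean squared
displacement, transitions from expected counts), with 10 seeded restarts
keeping the best log-likelihood (ties to the lowest restart index), and
the number of states chosen by BIC over 1..max_states (the analysis caps
are 3 for interphase and 2 for metaphase data). This is a
maximum-likelihood stand-in for the variational-Bayes classifier used in
the original analyses: inputs (tracks with > 4 frames, i.e. ≥ 5 detected
points), the state cap, and outputs (per-state D, per-frame transition
percentages, per-step annotations) are the same; the interface leaves
room for a VB backend. Localization noise is not an emission parameter,
so fitted D values are apparent, matching the convention of the source
analyses. States are reported sorted by ascending D, making the
bound < liquid-like < dissociated ordering deterministic. Per-step
labels come from the Viterbi path; per-step posteriors from
forward-backward are retained. Occupancy fractions are reported as
posterior-expected step fractions (mean per-step posterior): hard
most-probable-path shares systematically overcount the dominant state
when emissions overlap (about +4.5 percentage points on a 60% state for
the bound/liquid pair, whose D ratio is only 3.2 — the bias persists
even when decoding with the exact generating model), whereas the
posterior mean is nearly unbiased. Hard-label shares remain available
(`viterbi_fractions`), and hard labels drive track splitting.

`split_by_state` turns maximal single-state runs of ≥ 2 points into
sub-tracks and computes per-state MSD curves over 0.05–0.5 s by default.

## PALM spatial statistics

Density maps bin localizations into 32.5-nm pixels; a centered square
crop (220 px for nuclear-interior analyses) avoids the nuclear
periphery. Pixels are ranked into four equal-occupancy intensity classes
(quartiles) with a stable tie-break in row-major order, so the many tied
empty pixels split evenly and class occupancies are equal to within one
pixel; a constant map is classified but flagged degenerate. Enrichment
is the fraction of a state's step midpoints per class; 0.25 per class is
the spatially random reference, and per-cell results can be averaged.

Ripley's K follows the uncorrected estimator
K(r) = (S/(N−1))·(1/N)·Σ_i Σ_{j≠i} 1[d_ij ≤ r] with L = √(K/π), exactly
as printed in the source analysis, with the observation area S an
explicit input (the source derived it from a segmentation mask, which is
out of scope here; for synthetic windows S is the window area). No edge
correction is applied, so K is biased low as r approaches the window
size (for CSR at r = 5% of a square window the bias in L(r)−r is about
−0.01·r/0.5 µm); analyses and tests are restricted to small r, and
envelope comparisons use Monte Carlo envelopes computed with the same
estimator, which carry the same bias.

## Mean-field model of stable vs dynamic H1 binding

The lattice model places N nucleosomes (in chains of K) on N0 sites; H1
is stably dyad-bound (count n, energy −(ε+δ)), dynamically bound
(count m, energy −ε, multivalent coupling −J·[1 − (1 − ρ)^z] to
neighbors), or free (chemical potential μ), with all energies in kBT.
The free energy per site f = (E − T·S)/N0 uses the printed energy and
entropy expressions (see the module docstring). One convention is worth
flagging: S_H1 references each species count to the lattice size N0
(dilute-mixing form −Σ k·log(k/N0)), which differs from the Stirling
form of log[N!/(n!m!(N−m−n)!)] by N·log(N0/N) — a term independent of
(m, n) at fixed N. The choice therefore shifts f by a constant and
cannot move the minimizer; the test suite validates the combinatorial
content of the entropies against exact log-gamma factorials with that
reference constant removed.

The landscape is evaluated on a (b, x) grid — binding ratio
b = (n+m)/N ∈ (0, 1], mobile fraction x = m/(n+m) ∈ [0, 1] — using the
continuous relaxation of (m, n) (every term is extensive, so f per site
is independent of N0 in this form). The global minimum comes from an
exhaustive grid scan (default 200×200, minimum 50×50) followed by
Nelder–Mead refinement; grid scan rather than pure local descent because
the landscape can be multi-modal near phase boundaries. A minimizer on
the grid boundary is flagged (at the reference parameters and high
density the minimizer sits at b* = 1: every nucleosome carries an H1).
With the reference parameters (K = 1000, z = 6, δ = 1.5, ε = μ = J = 1)
the mobile fraction at the minimum x* exceeds 0.5 for ρ ≳ 0.4 and grows
with ρ — the multivalent energy and entropy terms stabilize dynamic
binding in dense chromatin — while large δ with J = 0 drives x* below
0.5 (stable dyad binding dominates). x* is monotone non-increasing in δ
and non-decreasing in ρ (verified by tests).

## Problem sizes used in tests and the acceptance script

Parameter-recovery runs use 2,000 tracks of mean 20 steps (~4×10⁴
steps) for HMM fitting, 5,500 tracks (~10⁵ steps) for RL state
counting, 10⁴ step midpoints for the enrichment baseline, and 100 CSR
replicates of 10⁴ points for the L-function envelope; these sizes give
Monte Carlo errors several times smaller than the tolerances being
checked while keeping a full run to a few minutes on one core. Each
check's tolerance states the published value it targets (10% relative
on D, ±5 percentage points on occupancies, ±0.01 on enrichment
fractions, the pointwise 95% Monte Carlo envelope for L(r)−r).

## Known limitations

- The generator's geometric track-length law and the detailed-balance
  transition matrices are plausible stand-ins, not published values;
  parameter-recovery results certify the estimators under the model's
  own assumptions.
- Localization error is additive white Gaussian; no motion blur, no
  blinking-driven track fragmentation, no drift.
- RL state counting was validated for peak separations ≥ 0.43 decade
  (the published two- and three-state configurations); closer states
  will merge.
- The HMM models free diffusion only — no confined or directed states,
  and no dwell-time survival analysis.
- Ripley's K without edge correction is only meaningful at small r.
- The mean-field landscape reports a mean-field minimum; fluctuation
  corrections and kinetics are out of scope.
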