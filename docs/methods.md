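# Methods

`tweezfold` reconstructs, as tested code with synthetic ground truth, the
single-molecule analysis chain used to dissect cAMP-driven activation of the
PKA regulatory subunit by optical tweezers: pulling/hopping trajectory
simulation, rip detection, worm-like-chain (WLC) contour-length analysis,
rupture-force → lifetime kinetics, Bayesian hidden-Markov hopping analysis,
cooperative two-site binding fits, and free-energy dissection. Because the
original raw trajectories are not publicly deposited, every analysis stage
is validated against a kinetic Monte-Carlo generator whose parameters are
the experiment's published values; the analyses then have exact ground
truth to recover.

## Mechanical model of the tether

A pulling experiment is modeled as a serial mechanical circuit: a harmonic
trap (stiffness `k_trap`, default 0.1 pN/nm), one effective DNA-handle WLC
(contour 260 nm, persistence 10 nm — a single chain standing in for the two
350+30 bp handles), the unfolded polypeptide as an inextensible
Marko–Siggia WLC (persistence 0.65 nm, the community-standard value), and
the folded cores as rigid bodies. Chain elasticity uses the Marko–Siggia
interpolation only: forces here stay below ~25 pN, where enthalpic backbone
stretching is negligible.

Bookkeeping convention: a folded domain's end-to-end distance d_NC is a
constant rigid offset in the chain; unfolding adds the released contour
ΔLc = n_residues·l_aa − d_NC (l_aa = 0.365 nm) to the polypeptide WLC. The
extension gain at fixed force is then exactly ΔLc·ξ(F), which is also the
model every fitting routine assumes (Δx(F) = ΔLc·ξ(F); hopping
ΔLc = Δx/ξ(F)). The alternative — removing d_NC from the chain at rupture
— would make the simulator and the fitting convention disagree by
d_NC·(1−ξ) ≈ 1–3 nm.

At each trap position X the tension solves
X = F/k_trap + L_handle·ξ_h(F) + L_unfolded·ξ_p(F) + Σ d_NC; the map is
precomputed per folding state on a fine force grid and inverted by
interpolation (error ≪ measurement noise).

## Kinetic Monte Carlo

Transitions follow first-order kinetics with Bell (default) or
Dudko–Hummer–Szabo (ν = 1/2, 2/3) force dependence; unfolding rates grow
with force, refolding rates fall. Within each sampling step
(Δt = 1/sample_rate, 5 ms at the default 200 Hz) rates are frozen
(Gillespie-with-drive): the cumulative hazard along the deterministic force
path is integrated stepwise and the event time read off by inverse-CDF
sampling, which is exact for the frozen-rate process. Rates change by <1%
per step at 75 nm/s, so the discretization bias is negligible (verified:
sampled rupture-force densities match quadrature of
p(F) = [Ḟτ(F)]⁻¹ exp(−∫[Ḟτ]⁻¹) by χ² across seeds).

Measurement noise is bead-position noise δ ~ N(0, σ): recorded
force = F + k_trap·δ and extension = x − δ, so the two channels carry
anti-correlated noise, as they do on a real instrument. Default σ = 1 nm
for ramps, 2 nm for clamp traces.

Generator defaults are the study's conditions: 75 nm/s, 200 Hz, refolding
hold 10 s at 2 pN, 20 °C; clamp recordings at 10–12 pN, 1000 Hz (wild-type)
or 500 Hz (mutant). Canonical constructs (`tweezfold.constructs`) encode
the published numbers:

* apo kinetics τ0,F = 1.1–1.6·10³ s, Δx‡(F→U) = 4.5–5 nm, which under the
  default mechanics put apo ruptures at ~7–9 pN;
* τ0,U chosen so R·T·ln(τ0,F/τ0,U) equals the measured apo stabilities
  (9.4 kcal/mol CNB-A, 7.6 kcal/mol CNB-B);
* cAMP and neighbor effects applied as the measured lifetime fold-changes
  (×30/÷4 for CNB-B with cAMP, ×7/÷4 for CNB-A, ×4/÷150 and ×160/÷10 for
  the neighbor contributions);
* released contours 50 nm (CNB-B), 45 nm (apo CNB-A), 30 nm (cAMP-bound
  CNB-A, N3A destabilized), 13 nm (N3A); the cAMP-bound CNB-A barrier
  distance (2.5 nm, unpublished) was set analytically so the Bell–Evans
  modal force lands at the measured 17.4 pN;
* N3A hopping kinetics specified by dwell times at 11 pN (τ_F = 0.5 s,
  τ_U = 0.3 s wild-type-like; 1.0 s / 0.15 s for the R241A-like variant,
  the measured 2× contrasts).

What the generator does not emulate: instrument drift, feedback-loop
filtering and colored noise, bead hydrodynamics, tether-to-tether handle
variability, and multi-state intermediates within one rip. Passing
recovery tests therefore demonstrate correctness of the analysis chain
under idealized (white-noise, stationary) conditions, not robustness to
every artifact of real recordings.

## Rip detection

Rips are zero-crossings of the smoothed extension derivative exceeding a
robust threshold (median + k·MAD, k = 4, smoothing window 3 samples),
co-gated by a concurrent force change of at least 0.4 pN with the correct
sign (drop for unfolding, rise for refolding); candidates within 25 ms are
clustered, keeping the larger force step (favoring the cooperative-unit
reading). Detection performance on simulator output: recall and precision
≥ 0.99 for rips ≥ 10 nm at 1 nm noise.

Δx measurement: extension and force baselines on either side of the event
are fitted against *time* — regressing extension on measured force would
suffer an errors-in-variables bias because bead noise is shared
(anti-correlated) between the two channels, which at realistic noise
levels systematically shrinks the recovered ΔLc. The branch carrying the extra unfolded
contour (compliant branch) is read off at the event time and the stiffer
branch — nearly linear in force, its compliance dominated by trap and
handles — is extrapolated to the same force. Extrapolating the compliant
branch instead would bias large rips upward (its WLC curvature over the
2–3 pN extrapolation is substantial); a quadratic extrapolation removes
that bias only on essentially noiseless data and is gated accordingly.
ΔLc = Δx/ξ(F) with the protein persistence (0.65 nm); events re-crossed
two or more times in one ramp are flagged reversible. The loading rate is
the slope of a 50 ms force fit ending at rupture.

## Rupture-force kinetics

The rupture-force histogram transforms to force-dependent lifetimes bin by
bin: τ(F_i) = [(h_i/2 + Σ_{k>i} h_k)ΔF]/[h_i·Ḟ_i]. The estimator's
validity region excludes bins where survival is dominated by the half-bin
term (deep tail) and near-empty bins (the conditional-on-occupied density
there is severely overestimated); defaults of 0.1–0.25 pN bins keep the
per-bin error below a few percent in well-populated bins.

Bell (ν=1) fits are weighted least squares on log τ vs F; DHS fits use the
same residuals with the ν = 1/2 or 2/3 lifetime law. Weights start from
per-bin counts (Poisson error on log τ ≈ 1/√n) and are then replaced by
model-expected counts over three reweighting rounds: observed-count weights
share noise with the lifetime estimates themselves (the same h_i sits in
the weight and the denominator of τ̂_i), which at realistic event counts
biases the extrapolated τ0 downward and degrades CI coverage;
expected-count weights restore near-nominal coverage (asserted in the
regression suite).
Zero-force extrapolations carry seeded multinomial-bootstrap 95% CIs
(default 1000 resamples). Reconstructed densities
p(F) = [Ḟτ]⁻¹exp(−∫[Ḟτ]⁻¹) integrate to 1−survival(F_max) on the grid.

## Hopping (BHMM)

Force-clamp traces are fitted with a two-state Gaussian hidden-Markov
model, exactly two states by construction. The Gibbs sampler alternates
forward-filter backward-sampling of the state path (numba-compiled kernel),
conjugate normal–inverse-gamma draws of the two means and the shared noise
variance (priors: means N(ȳ, (10 s_y)²), σ² ~ InvGamma(2, s_y²)), and
Dirichlet(1,1) per-row transition draws. Label switching is resolved by
ordering means; burn-in defaults to 20% of draws; a split-chain diagnostic
on the mean separation warns above 1.05. Point estimates are posterior
medians with percentile 95% intervals.

Dwell lifetimes come from the transition probabilities,
τ = −Δt/ln(p_stay), per draw (the transition-probability route; draws with
p_stay = 1 are excluded with a warning). ΔLc = (μ_U − μ_F)/ξ(F_clamp)
propagates the posterior directly. Degenerate traces (no two-level
structure) are rejected via the lag-1 autocorrelation of the extension
(< 0.05, or zero variance): a one-state trace with white measurement noise
has none, while genuine hopping sampled far above the switching rate is
strongly autocorrelated.

Calibration (regression suite, scaled sizes): nominal 95% intervals cover
the generating Δx in ≥ 17/20 seeded traces across SNR 1.5–5; wild-type and
mutant ΔLc (9.5/6.5 nm) and the 2× dwell contrasts are recovered from
120 s traces at 2 nm noise.

## Liganded-species classification and binding fit

Classification of a simultaneous-pulling cycle uses the signatures the
titration experiments rely on, with generous windows because crowded rips
carry 10–20% ΔLc error: a small (6–20 nm) transition near 8–14 pN —
reversible, seen as a mid-stretch refolding step, or as a separate small
rip — marks the fully bound state (only A1B1 has an independently folding
N3A unit); a 23–36 nm rip at ≥ 11 pN marks cAMP on CNB-A only (N3A
destabilized, no hopping because refolding requires the cAMP-bound CNB-B);
otherwise two full-length ruptures totalling ~95 nm split into
CNB-B-elevated (≥ 9.2 pN ⇒ A0B1) vs all-apo-window (⇒ A0B0); anything else
is reported unclassified and excluded from the likelihood rather than
forced. The 9.2 pN split is the equal-error point between the simulated
apo and cAMP-bound CNB-B rupture-force distributions.
Per-species accuracies on simulator output are bounded in the regression
suite (0.65–0.8 depending on species); the residual confusion (mostly A0B1 ↔ A0B0 in the force
overlap) is inherent to the signature overlap, not to the detector.

The binding model is the sequential two-site partition function
Z = 1 + L/K_A + L/K_B + γL²/(K_A·K_B) with one shared cooperativity factor
γ (second-site Kd = K/γ for either order), which closes the thermodynamic
cycle identically. Counts are fitted by maximum likelihood under
independent multinomials per concentration (counts are small, so count
noise matters more than fraction noise), optimized by L-BFGS-B with an
analytic gradient in log-parameter space; 95% CIs by seeded parametric
bootstrap (500 resamples). At the study's scale (12 concentrations × 100 molecules) the K_A and K_B
intervals are close to nominal while the γ percentile interval is slightly
anticonservative — a known property of percentile bootstraps on ratio-like
parameters; reflected intervals fared no better, so the simpler percentile
form is kept and the regression suite asserts coverage with an allowance
for this.

## Energetics

ΔG_eq = R·T·ln(τ0,F/τ0,U) at 293.15 K (two-state assumption; no
work-distribution estimators). Dissection per domain:
ΔG_ligand = ΔG(isolated, holo) − ΔG(isolated, apo) and
ΔG_interdomain = ΔG(selective, holo) − ΔG(isolated, holo); the
decomposition identity holds exactly by construction. Lifetime
fold-changes combine as ΔΔG = R·T·ln(fold_F · fold_U). Landscape summaries
normalize the unfolded state to zero; absolute barrier heights require an
attempt-rate convention (default 10⁶ s⁻¹), always reported alongside,
since only lifetime ratios are measured.

## Structure utilities

Contact maps use all heavy atoms (hydrogens ignored), minimum inter-residue
atom distance ≤ cutoff (8 Å convention), |i−j| ≥ 2 to drop trivial backbone
neighbors, with pairs partitioned by named regions (hub = first declared
region, e.g. the N3A motif). Coordinates come from standard PDB files via
Biopython or from plain residue→coordinate mappings; tests use synthetic
mini-structures and an independent brute-force distance oracle. Expected
contour release: ΔLc = n_residues·l_aa − d_NC.

## Problem sizes and determinism

All randomness flows through explicitly seeded `numpy.random.Generator`
instances; identical seeds give bit-identical outputs. The regression
suite runs scaled-down versions of the recovery studies (e.g. 30 titration
replicates with 250-resample bootstraps; 20 BHMM coverage traces of 30 s at
500 Hz; 120–200 ramp cycles), sizes chosen so that the default suite stays quick
while leaving every conclusion statistically meaningful;
`scripts/acceptance.py` runs the full-size versions (120 s clamp traces at
1000 Hz; 200 ramp cycles).

## Known limitations

* The rupture-force → lifetime transform degrades in survival-starved tail
  bins and near-empty leading bins; fits mitigate this by expected-count
  weighting but extremely sparse histograms (< ~300 events) will still
  show τ0 scatter spanning a factor of ~2 (τ0 is an exponential
  extrapolation to zero force).
* The γ bootstrap interval is mildly anticonservative (see above).
* The classifier's A0B1/A0B0 split degrades when the cAMP-bound CNB-B
  ruptures in the apo force window (~10% of cycles).
* No drift correction beyond the linear local baselines; no multi-state
  rips; no feedback-loop noise model for clamp traces.
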