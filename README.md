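# tweezfold

Single-molecule force-spectroscopy analysis of cAMP-driven allosteric
activation in the regulatory subunit of protein kinase A (PKA).

The PKA regulatory subunit carries two cyclic-nucleotide-binding domains,
CNB-A and CNB-B, that bind cAMP sequentially and cooperatively; a ~30
residue helical element of CNB-A, the N3A motif, acts as a cAMP-responsive
conformational switch. Optical-tweezers experiments probe all of this
mechanically: force-ramp pulling produces force-extension curves whose
rupture "rips" report domain stability and released contour length (ΔLc),
force-clamp recordings show the N3A motif hopping between folded and
unfolded states near 11 pN, and titrating cAMP while classifying unfolding
trajectories counts the four liganded species (A0B0, A1B0, A0B1, A1B1)
molecule by molecule.

`tweezfold` implements the full analysis chain for such experiments, plus a
kinetic Monte-Carlo simulator that generates every kind of input data with
known ground truth (the raw trajectories of the original study are not
deposited, so all validation is recovery of generator truth):

| module | what it does |
|---|---|
| `simulate` | kinetic MC force-ramp / force-clamp trajectories (serial trap–handle–protein compliance, Bell/DHS kinetics) and multinomial titration counts, with ground truth |
| `trace_io` | plain-text trace formats (`.fec.tsv`, `.fct.tsv`, `.counts.tsv`), result tables with SHA-256 manifest |
| `wlc` | Marko–Siggia force law `F = (kBT/P)[1/4(1−ξ)⁻² − 1/4 + ξ]`, its inverse, and ΔLc estimation from (F, Δx) pairs |
| `ripscan` | rip/zip detection in force-extension curves, rupture statistics, unfolding-force histograms |
| `forcekinetics` | Dudko-style histogram → lifetime transform `τ(Fᵢ) = [(hᵢ/2 + Σ_{k>i}h_k)ΔF]/[hᵢḞᵢ]`, Bell/DHS fits `τ(F) = τ0·e^(−FΔx‡/kBT)`, force-distribution reconstruction |
| `hopping` | Bayesian two-state hidden-Markov (Gibbs/FFBS) analysis of clamp traces: state means, dwell lifetimes `τ = −Δt/ln p_stay`, hopping ΔLc with credible intervals |
| `titration` | liganded-species classification and global multinomial fit of the sequential two-site model `Z = 1 + L/K_A + L/K_B + γL²/K_AK_B` |
| `energetics` | `ΔG = RT·ln(τ0,F/τ0,U)`, ligand vs inter-domain dissection, landscape summaries |
| `structmap` | residue contact maps (8 Å heavy-atom cutoff, region partition) and structure-based expected ΔLc |
| `constructs` | the canonical domain definitions (published kinetics, stabilities, contours) used throughout |

The numbered scripts under `analysis/` run the study end to end
(simulate → rips → kinetics → hopping → titration → energetics) and write
tables under `results/`; `docs/methods.md` documents the models,
conventions, and known limitations.

## Worked example

Simulate a wild-type-like N3A hopping trace at 11 pN and recover its
contour-length change:

```python
from tweezfold.constructs import domain_from_delta_lc, kinetics_for_clamp
from tweezfold.simulate import simulate_force_clamp
from tweezfold.hopping import fit_bhmm, dwell_lifetimes, delta_lc_from_hopping

unfold, refold = kinetics_for_clamp(0.5, 0.3, clamp_force=11.0)
n3a = domain_from_delta_lc("N3A", 9.5, unfold, refold, n_residues=30,
                           reversible=True)
trace, truth = simulate_force_clamp(n3a, clamp_force=11.0, duration=120.0,
                                    sample_rate=1000.0, noise_sd=2.0, seed=5)
post = fit_bhmm(trace, n_samples=1500, seed=7)
dlc = delta_lc_from_hopping(post, clamp_force=11.0)
dw = dwell_lifetimes(post)
print(f"dLc = {dlc.value:.2f} +- {dlc.se:.2f} nm")
print(f"tau_F = {dw.tau_folded:.3f} s, tau_U = {dw.tau_unfolded:.3f} s")
```

prints (the generator used ΔLc = 9.5 nm, τ_F = 0.5 s, τ_U = 0.3 s):

```
dLc = 9.50 +- 0.02 nm
tau_F = 0.486 s, tau_U = 0.303 s
```

i.e. the posterior median contour-length change lands on the generating
9.5 nm with a ~0.02 nm posterior scale, and the dwell lifetimes recover the
half-second folded and 0.3 s unfolded dwells the trace was generated with.

Running the analysis drivers, e.g.

```
python analysis/03_hopping_bhmm.py
python analysis/04_titration_fit.py
```

prints the wild-type vs R241A-like hopping comparison (ΔLc 9.52 ± 0.02 vs
6.47 ± 0.04 nm; folded-lifetime ratio 1.73, unfolded 2.19, generated 2.0)
and the binding fit from 1200 simulated molecules across 1–150 nM cAMP
(K_A = 15.2 nM CI 12.1–19.5, K_B = 9.2 nM CI 7.6–11.3, γ = 2.82 CI
2.16–3.83 against generating values 17, 10, 3).

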