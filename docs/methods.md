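# Methods

## Kinetic model

The aggregation of tau4R is described by two moments of the fibril length
distribution, the number concentration P(t) and the mass concentration
M(t), both in µM with time in minutes:

    dP/dt = kn·m^nc + km·M
    dM/dt = 2·kp·(KE·m/(KE + m))·P

New fibrils form by primary nucleation from nc monomers and by
fragmentation of existing fibril mass; fibril mass grows by monomer
addition at both ends with Michaelis–Menten-like saturation in the free
monomer concentration m. The factor 2 counts the two growing ends per
fibril. Secondary (surface-catalysed) nucleation and length-resolved
master equations are deliberately out of scope, as is any explicit
treatment of the heparin trigger — its effect is absorbed into the
effective rate constants.

Assumptions worth stating explicitly:

- the ThT signal is proportional to fibril mass, and chaperones do not
  change the ThT accessible in solution;
- nc is a fixed model setting (default 2), never fitted;
- free monomer is eliminated algebraically, m = m0 + M0 − M. This halves
  the ODE system and makes mass conservation exact by construction. The
  simulator clamps m at 0 inside the right-hand side to absorb numerical
  overshoot near full conversion.

Parameters and units:

| parameter | meaning | units | typical scale here |
|---|---|---|---|
| kn | primary nucleation rate | µM^(1−nc)·min⁻¹ | 2e-9 |
| kp | elongation rate | µM⁻¹·min⁻¹ | 50 |
| km | fragmentation rate | min⁻¹ | 4e-6 |
| KE | elongation saturation constant | µM | 5 |
| nc | critical nucleus size | — | 2 |

Integration uses LSODA (stiff-capable, switching to BDF as the system
stiffens near full conversion) with rtol 1e-8 / atol 1e-10 by default;
the fitting objective relaxes to rtol 1e-6 / atol 1e-9 for speed. The
simulator is validated against an independent fixed-step fourth-order
Runge–Kutta integrator at 10× finer steps (agreement better than 1e-6
relative).

## Trace preparation

Raw ThT signals are baseline-subtracted (no-trigger wells, linearly
interpolated onto the trace grid where grids differ), optionally smoothed
by binning 2–5 consecutive points (arithmetic mean of both time and
value; a trailing partial window is averaged as-is), and converted to
fibril mass by anchoring the long-term plateau of the
highest-concentration trace: M_i(t) = m_max·S_i(t)/S_max∞. S_max∞ is the
mean of the final 10% of that trace (the window share is configurable).

The half-saturation time is the linearly interpolated first crossing of
half the per-trace plateau, with the plateau estimated from the final 10%
of points. A trace is rejected as unsaturated when the regression slope
over that final window exceeds 1% of the peak growth rate *and* exceeds
three times its own standard error — the second condition prevents pure
measurement noise from disqualifying a genuinely flat plateau, while
truly rising traces exceed it by orders of magnitude.

The scaling exponent γ is the ordinary least-squares slope of log10(t½)
against log10(m0); a second-degree fit supplies a curvature coefficient,
flagged significant when it exceeds twice its standard error and an
absolute floor of 1e-8 (guarding against flagging floating-point
curvature on exact power laws). Saturating elongation with KE inside the
measured concentration range produces a positive, significant curvature;
uniformly deep saturation (KE far below every concentration) flattens the
plot again, so the flag diagnoses a saturation *transition* within the
range — the experimentally relevant case.

## Two-step global fitting

Unseeded mass curves are invariant under (kn, kp, km) → (c·kn, kp/c,
c·km): they constrain only k'n = kn·kp, k'm = km·kp and KE. Step one
therefore fixes kp ≡ 1 and minimises the unweighted sum of squared
residuals over all points of all unseeded traces simultaneously
(per-trace weighting is available as a setting). The amplitude of each
trace is never fitted; it is fixed by that trace's total monomer
concentration. Optimization runs in log10-parameter space with bounded
differential evolution (default bounds k'n, k'm ∈ [1e-8, 1], KE ∈
[1e-2, 1e3]) followed by a trust-region least-squares polish; the DE seed
is recorded in every report and makes fits bit-reproducible.

Step two fits seeded traces (initial conditions M0, P0 = M0/L) with kp as
the only free parameter, tying kn = k'n/kp and km = k'm/kp so the
step-one composites are preserved exactly. Because the objective is
smooth and effectively unimodal in log kp, a deterministic coarse
log-grid scan refined by bounded scalar minimization is used for this and
every other single-parameter fit. The absolute scale of kp trades off
against the assumed seed length L (P0 = M0/L), so kp/L is the robustly
determined quantity; L itself comes from the DLS module (default 100
monomers).

Rate uncertainties are estimated by refitting independent replicate sets:
half the absolute difference for two sets, the standard deviation for
more.

## Chaperone mechanism dissection

Chaperone effects never enter the ODEs explicitly; each chaperone
concentration is summarised by multiplicative scale factors on individual
microscopic rates relative to the chaperone-free baseline, fitted
independently per concentration. Single-rate hypotheses (kn-only or
kp-only; km held fixed because chaperone addition leaves fibril length
distributions unchanged) use the 1-D scan; the joint hypothesis fits
(fn, fp, fm) — or (fn, fp) with an identifiability warning when no seeded
traces are available — by differential evolution plus polish. Hypotheses
are ranked by total RMSE over the shared traces, with fewer free
parameters winning ties (parsimony). On synthetic data with kp suppressed
tenfold, the kp-only hypothesis beats kn-only by an order of magnitude in
RMSE, and vice versa for nucleation suppression, reproducing the logic by
which each chaperone's target step is identified.

## DLS seed sizing

The intensity autocorrelation is fitted as g2(τ) = 1 + β·exp(−2Dq²τ)
with the baseline fixed at exactly 1 (no floating offset). Internally the
fit parameter is the decay rate Γ = 2Dq², which is numerically well
scaled; D = Γ/2q² follows. q = (4πn/λ0)·sin(θ/2) with n = 1.334 by
default; laser wavelength and scattering angle are instrument-specific
and required. The Stokes radius is Rs = kB·T/(6πηD) with kB = 1.38e-23
J/K, T = 298 K, and η defaulting to 0.89e-3 Pa·s (water at 25 °C; the
actual buffer viscosity is configurable).

The seed is modelled as a prolate ellipsoid of long axis a (the full
fibril length) and short axis b (fibril thickness, default 10 nm from
cryo-EM fibril polymorph dimensions). Equating ellipsoid friction
6πηa/ln(2a/b) with sphere friction 6πηRs gives a/ln(2a/b) = Rs, solved by
Brent root finding on the elongated branch [b·e/2, 1000·Rs] followed by
one Newton polish (residual < 1e-9·Rs). The friction function attains its
minimum b·e/2 at the branch point, so a solution exists iff Rs ≥ b·e/2,
with the tangent case a = Rs handled exactly. With a 2 nm axial rise per
tau monomer, L = a/2 nm; Rs = 55 nm and b = 10 nm give a ≈ 204 nm and
L ≈ 102 monomers.

## Binding analysis

Anisotropy titrations are fitted with the hyperbolic one-site form
r(c) = r_free + (r_bound − r_free)·c/(KD + c), appropriate because the
labelled species (0.1 µM) is far below the µM-scale dissociation
constants; the exact ligand-depletion (quadratic) form is available for
tight binders. A fit is declared unidentifiable — the "no binding
observed" outcome — when the amplitude actually spanned over the measured
concentration range is below three times the residual noise; judging the
spanned rather than the extrapolated amplitude prevents a weak apparent
trend with an unbounded KD from masquerading as binding.

Chemical shift perturbations combine amide shifts as
Δδ = sqrt(ΔδH² + (ΔδN/5)²); residues with Δδ above mean + 1 SD are
significant. Intensity ratios I/I0 flag residues below mean − 1 SD, with
an auxiliary strong-attenuation flag below 0.5. The SD is computed over
all quantified residues including the binding region (an iterative
outlier-excluding variant is a configuration away); for the 1-SD
intensity threshold, the SD of the ratios and the SD of the signal loss
1 − I/I0 are identical, so the choice is immaterial. Binding regions are
maximal runs of at least 3 consecutive significant residues, bridging
single-residue gaps (both configurable).

## Synthetic data

The generators are pure functions of (specification, seed) and return the
generating truth with the data. The default aggregation scenario mirrors
the study design the analyses assume: unseeded monomer series over
2.5–40 µM sampled every 2 min for 700 min, chaperone dose series of
0–10 µM against 10 µM tau, seeded companions (1 µM of length-100 seeds)
sampled every 15 s for 45 min, three replicates, and independent
additive Gaussian noise of 1% of each trace's total amplitude
(heteroscedastic signal-proportional noise is available). The default
baseline rates (kn = 2e-9, kp = 50, km = 4e-6, KE = 5; i.e. k'n = 1e-7,
k'm = 2e-4) put the system in the fragmentation-assisted,
saturation-limited regime characteristic of heparin-triggered tau4R:
half-times of a few hours, a shallow concentration scaling (γ ≈ −0.37)
and positive log-log curvature.

What the generators do *not* emulate: plate-position and optical
artifacts, gain drift, ThT binding non-linearity, polydisperse or
multi-species DLS signals, ligand depletion in titrations, and NMR
footprints with soft (non-rectangular) edges. Passing recovery tests
therefore demonstrate correctness of the estimators under the model's own
assumptions — identifiability, optimizer adequacy, threshold logic — not
robustness to instrument systematics.

## Problem sizes and runtime

The test suite fits 15-trace unseeded datasets (351 points per trace) and
single-concentration chaperone series; a full two-step fit takes tens of
seconds at the default optimizer budget (differential evolution, popsize
10–12, ≤40 generations) on one CPU, and the complete demo workflow about
a quarter of a minute. These budgets are settings, not limits: tighter
tolerances and larger populations are a `FitSettings` away.

## Known limitations

- Unseeded-only data cannot separate kp from kn and km; all absolute-rate
  statements inherit the assumed seed length L (kp/L is what the seeded
  data determine).
- Hypothesis ranking uses raw RMSE with a parsimony tie-break; no formal
  model-selection criterion or posterior sampling is attempted.
- The plateau detector assumes traces end near saturation; chaperone
  conditions that never aggregate are excluded from half-time analysis by
  design and surface as warnings.
- The one-site binding fit reports lmfit's asymptotic standard error; for
  titrations truncated well below saturation the KD uncertainty is
  underestimated.
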