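# taukinetics

Quantitative analysis of how molecular chaperones (HSPB1, DNAJA2, DNAJB1)
suppress amyloid formation by the tau four-repeat domain (tau4R).

Aggregation of tau into amyloid fibrils underlies tauopathies such as
Alzheimer's disease, and ATP-independent "holdase" chaperone activity can
delay it. This package provides the full analysis chain needed to say *which
microscopic step* of aggregation a chaperone inhibits, starting from routine
biophysical readouts: Thioflavin-T (ThT) plate-reader kinetics, dynamic light
scattering (DLS) of sonicated seeds, fluorescence anisotropy titrations, and
per-residue NMR observables. A synthetic-data module generates every input
with known ground truth, so the whole pipeline is testable end to end.

## The kinetic model

Fibril mass M(t) and number P(t) concentrations (µM, minutes) follow a
nucleation / saturating-elongation / fragmentation moment model:

```
dP/dt = kn·m^nc + km·M
dM/dt = 2·kp·(KE·m / (KE + m))·P,      m = m_tot − M
```

with primary nucleation rate `kn` (nucleus size `nc = 2`), elongation rate
`kp`, saturation constant `KE`, and fragmentation rate `km`. Free monomer
`m` is eliminated by mass conservation, so the simulator integrates two ODEs
and conserves mass exactly.

Unseeded ThT data determine only the composites `k'n = kn·kp` and
`k'm = km·kp` (plus `KE`), so fitting is two-step: a global fit of the
unseeded concentration series with `kp ≡ 1`, then a seeded fit
(`P0 = M0/L`, seed length `L` from DLS) that pins `kp` and hence absolute
rates. Chaperone mechanisms are identified by refitting each dose with a
single rate allowed to scale (`kn`-only vs `kp`-only, `km` fixed), ranking
hypotheses by residuals, with a joint seeded+unseeded fit for chaperones
that perturb several rates at once.

Seed length comes from DLS: a single-exponential fit
`g2(τ) = 1 + β·exp(−2Dq²τ)` gives D, Stokes–Einstein gives
`Rs = kB·T/(6πηD)`, and equating prolate-ellipsoid friction
`6πηa/ln(2a/b)` with sphere friction yields the fibril length `a`, hence
`L = a / 2 nm`. Binding is quantified by one-site anisotropy fits
(`r(c) = r_free + Δr·c/(KD+c)`) and mapped on the sequence through chemical
shift perturbations `Δδ = sqrt(ΔδH² + (ΔδN/5)²)` and intensity ratios
`I/I0` with one-standard-deviation significance thresholds.

## Worked example

```python
import numpy as np
from taukinetics import ellipsoid_long_axis, seed_length_monomers
from taukinetics.synthetic import (
    ScenarioSpec, NoiseSpec, generate_aggregation_dataset, generate_titration,
)
from taukinetics.fitting import UnseededGlobalModel, SeededGlobalModel, FitSettings
from taukinetics.traces import extract_half_time, fit_scaling_exponent
from taukinetics.binding import fit_one_site

# seed sizing from a measured 55 nm Stokes radius, 10 nm fibril thickness
a = ellipsoid_long_axis(55.0, 10.0)
L = seed_length_monomers(a, 2.0)
print(f"seed long axis a = {a:.1f} nm, length L = {L:.1f} monomers")

# synthetic study: 2.5-40 uM tau, 1% noise, 3 replicates, 1 uM seeds
spec = ScenarioSpec(seed_spec=(1.0, 100.0))
dataset, truth = generate_aggregation_dataset(
    spec, NoiseSpec(sigma=0.01, kind="relative", rng_seed=11))

pairs = [(tr.condition.m0, extract_half_time(tr).t_half)
         for tr in dataset.unseeded]
scaling = fit_scaling_exponent(pairs)
print(f"scaling exponent gamma = {scaling.gamma:.2f} +/- {scaling.gamma_stderr:.2f}")

settings = FitSettings(rng_seed=1, max_iterations=40, popsize=10)
reduced = UnseededGlobalModel(dataset.unseeded).fit(settings)
print(reduced.summary())
absolute = SeededGlobalModel(dataset, reduced, L=100.0).fit(settings)
print(absolute.summary())

curve, _ = generate_titration(7.6, noise=NoiseSpec(sigma=0.02, kind="relative",
                                                   rng_seed=2))
print(fit_one_site(curve).summary())
```

prints

```
seed long axis a = 204.0 nm, length L = 102.0 monomers
scaling exponent gamma = -0.37 +/- 0.01
          Unseeded global kinetic fit (kp == 1)
==========================================================
kn_prime       1.01508e-07              uM^(1-nc).uM^-1.min^-2 (kn.kp)
km_prime       0.000199163              uM^-1.min^-2 (km.kp)
KE                 4.97864              uM
----------------------------------------------------------
n_obs                 5265
RMSE              0.208767              uM
rng_seed                 1
settings      2c5804603808
       Seeded global kinetic fit (L = 100 monomers)
==========================================================
kn             2.01779e-09              uM^-1.min^-1
kp                 50.3069              uM^-1.min^-1
km             3.95897e-06              min^-1
KE                 4.97864              uM
----------------------------------------------------------
n_obs                 2715
RMSE              0.217565              uM
rng_seed                 1
settings      2c5804603808
One-site binding fit
====================================
KD              7.485 ± 0.515  uM
r_free       0.048852
r_bound       0.20121
```

The seed geometry lands on a ~200 nm ellipsoid (~100 monomers at 2 nm per
monomer); the shallow negative exponent (−0.37) with positive log-log
curvature is the signature of fragmentation-assisted aggregation with
saturating elongation; the two-step fit recovers the generating rates
(k'n = 1e-7, k'm = 2e-4, KE = 5 µM, kp = 50 µM⁻¹min⁻¹) to a few percent;
and the titration fit recovers the 7.6 µM fibril affinity.

A config-driven workflow with the same stages is available from the shell:

```bash
taukinetics demo --seed 1 --out demo    # synthetic bundle + config.yaml
taukinetics run --config demo/config.yaml
```

## Layout

- `taukinetics.kinetics` — model and forward simulator
- `taukinetics.traces` — ThT trace preparation, half-times, scaling exponent
- `taukinetics.fitting` — two-step global fits, chaperone mechanism fits
- `taukinetics.hydrodynamics` — DLS autocorrelation, Stokes–Einstein, seed sizing
- `taukinetics.binding` — anisotropy one-site fits, CSP and intensity-ratio maps
- `taukinetics.synthetic` — ground-truth data generators
- `taukinetics.workflow` / `taukinetics.cli` — config-driven orchestration

See `docs/methods.md` for the modelling assumptions and numerical choices.
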