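# pax6rd

Reaction-diffusion modelling of the Pax6/Fst/Tgfb2 gene network that
self-organises the primary (proximal-distal) axis of the vertebrate optic
vesicle — the hemispherical forebrain outgrowth that becomes the retina.

The package is aimed at developmental and systems biologists who want to
simulate, perturb and quantify this Turing network *in silico*: how a noisy,
initially uniform Pax6 field spontaneously polarises; why larger tissues
form more Pax6 poles rather than bigger ones; how a collapsed explant
re-polarises along its longest axis; and how a ventral-high Shh gradient
orients — and its loss de-represses — the Pax6 pole.

## The model

Five species live on a 1D line or a 2D explant-shaped domain:

| symbol | species | transport |
|--------|---------|-----------|
| P | Pax6 (transcription factor) | immobile |
| F | follistatin (Fst), Tgfβ antagonist | diffuses slowly (D_F) |
| T | free Tgfβ2 ligand | diffuses slowly (D_T) |
| C | Fst:Tgfβ2 sequestration complex | diffuses fast (D_C ≫ D_F) |
| B | active Tgfβ2:receptor complex | immobile, B ≤ R_tot |

With effective Pax6 activity P* = P/(1 + βB) (receptor-activated Smad3
blocks Pax6–DNA binding) and Shh attenuation h = 1/(1 + γS):

    ∂P/∂t = h·[ρ_P (P*)ⁿ/(Kⁿ + (P*)ⁿ) + σ_P] − δ_P P
    ∂F/∂t = ρ_F P* − k_on F·T + k_off C − δ_F F + D_F ∇²F
    ∂T/∂t = ρ_T P* − k_on F·T + k_off C − k_b T(R_tot − B) + k_u B − δ_T T + D_T ∇²T
    ∂C/∂t = k_on F·T − k_off C − δ_C C + D_C ∇²C
    ∂B/∂t = k_b T(R_tot − B) − k_u B

Pax6 drives both its own expression and the morphogens Fst and Tgfb2.
Locally, Fst sequesters Tgfβ2 (positive feedback on Pax6); the fast-moving
Fst:Tgfβ2 complex exports the ligand and releases it at a distance, where
it activates receptors and inhibits Pax6 (long-range negative feedback).
This is an activator-inhibitor Turing network whose instability hinges on
the counter-intuitive condition D_C > D_F — complexes outrunning free Fst.

Model variants: **A** (Pax6 frozen as a prescribed regional pattern),
**B** (full self-organising network, 1D), **C** (same kinetics on a 2D
explant-shaped capsule), **D** (adds a static Shh gradient suppressing
Pax6). Loss-of-function switches mimic pharmacology: `tgfb_lof` (β=0,
SIS3-like), `shh_lof` (γ=0, cyclopamine-like), `double_lof` (both).

## Worked example

```python
import numpy as np
from pax6rd import (reference_parameters, homogeneous_steady_state,
                    dispersion_relation, Grid1D, SolverSettings, integrate,
                    summarise)
from pax6rd.scenarios import noisy_homogeneous_ic
from pax6rd.stability import default_k_values

params = reference_parameters()
steady = homogeneous_steady_state(params, variant="B")
disp = dispersion_relation(params, steady, default_k_values(50.0, 0.05), variant="B")
print(f"classification: {disp.classification}")
print(f"max growth rate: {disp.max_growth_rate:.4f} at k = {disp.k_max:.3f}")
print(f"pattern wavelength: {disp.lambda_pattern:.3f}")

grid = Grid1D(n_points=32, dx=1.2 / 32)            # baseline explant-scale line
ic = noisy_homogeneous_ic(steady, noise_amplitude=0.05, seed=1, geometry=grid)
result = integrate(params, ic, grid, variant="B",
                   settings=SolverSettings(t_end=200.0, snapshot_interval=4.0))
final = result.final_state
summary = summarise(final.P, final.B, grid)
print(f"outcome: {summary.outcome_class} ({summary.pole_count} Pax6 pole)")
print(f"polarisation index: {summary.polarisation_index:.3f}")
print(f"Pax6/receptor correlation: {summary.pax6_receptor_correlation:.3f}")
```

prints

```
classification: turing
max growth rate: 0.0924 at k = 3.324
pattern wavelength: 1.890
outcome: polarised (1 Pax6 pole)
polarisation index: 0.401
Pax6/receptor correlation: -0.954
```

Reading: the homogeneous state is linearly stable without diffusion but a
band of finite wavelengths grows (a Turing instability) with preferred
wavelength ≈ 1.89 space units. On a domain of the baseline (single-spot)
size, 5% multiplicative Pax6 noise resolves into exactly one Pax6 pole
whose activated-receptor field is strongly anti-phase (r ≈ −0.95) — the
simulated analogue of a distal Pax6⁺ pole flanked by receptor-active
proximal tissue.

## Command line

```bash
pax6rd simulate  --config src/pax6rd/configs/fig4D.yaml --out run.h5
pax6rd metrics   --in run.h5 --out summary.csv
pax6rd stability --out dispersion.csv
pax6rd suite     --out suite_out/      # all nine canonical scenarios
pax6rd sweep     --param D_C=0.01:1:9 --out sweep.csv
```

`suite` reruns the nine canonical scenario configs (prescribed-source run,
de-novo polarisation at baseline and 4× tissue size, explant
repolarisation, Shh orientation/reversal, and the three loss-of-function
regimes), writes per-run HDF5 + CSV and a master summary, and exits
non-zero if any run violates its shipped expected outcome.

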