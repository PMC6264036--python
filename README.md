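# flipdg

Reaction–diffusion simulation and parameter calibration for **FLIP**
(fluorescence loss in photobleaching) experiments on multi-compartment cell
geometries, aimed at quantifying the transport of aggregation-prone proteins
— diffusion, nucleo-cytoplasmic exchange, and binding/release at protein
aggregates (inclusion bodies) — directly from live-cell image series.

In a FLIP experiment a small spot (here: a disc inside the nucleus) is
bleached repeatedly while the whole cell is imaged; the spatio-temporal
pattern of fluorescence loss everywhere else carries the transport
parameters.  `flipdg` models the observed intensity as the sum `c = u + u_b`
of a diffusing free pool and an immobile hindered pool:

    u_t     = ∇·(α∇u) + k_off u_b − k_on(x) u − θβu   on Ω_B
    (u_b)_t =            k_on(x) u − k_off u_b − θβu_b on Ω_B

with `k_on(x) = γ·u_b⁰(x)`, `k_off = γ·u⁰` derived from the pre-bleach
frame, a semipermeable (`J·n = p⟦u⟧`) or active (`k_cn`/`k_nc`) nuclear
membrane, and conservative first-order exchange (`k₁`/`k₂`) across aggregate
boundaries.  The PDE is discretized with piecewise-linear interior-penalty
discontinuous Galerkin elements on a region-labeled triangle mesh (compartment
boundaries coincide with mesh edges) and advanced by backward Euler with two
pre-factored system matrices (bleach on/off).  Unknown parameters are
estimated by Nelder–Mead minimization of the misfit

    E = (1/n) Σᵢ ∫_Ω |c(tᵢ,x) − c_g(tᵢ,x)|² dx

against the goal function `c_g` — the blurred image series represented in
the same broken finite-element space.  See `docs/methods.md` for the full
numerical account.

## Worked example: recovering known parameters from noisy data

The package validates its calibration end to end: it forward-simulates the
semipermeable model with known parameters on a synthetic cell (~460
triangles: circular cell, off-center nucleus with a 1.4 μm bleach disc,
three cytoplasmic aggregates), adds zero-mean Gaussian noise with variance
equal to 10% of the maximum intensity, and re-estimates the parameters from
standard initial guesses `(α₀, β₀, γ₀, p₀, k₁₀) = (25, 20, 0.5, 0.05, 0.001)`.

```python
from flipdg import GroundTruthSpec, parameter_recovery_experiment
from flipdg.calibration import CalibrationConfig

report = parameter_recovery_experiment(
    GroundTruthSpec(seed=1), CalibrationConfig(max_iterations=600))
print(report.truth)
print(report.recovered)
print(report.result.E_initial, "->", report.result.E_final)
```

prints (seed 1):

```
{'alpha': 17.0, 'beta': 36.0, 'gamma': 0.2, 'p': 0.3, 'k1': 0.0718}
{'alpha': 16.252, 'beta': 37.548, 'gamma': 0.2038, 'p': 0.3034, 'k1': 0.07245}
1092.7 -> 244.9
```

Every parameter returns within a few percent of its true value — the
diffusion constant α (μm²/s), bleach rate β (1/s), hindrance constant γ,
membrane permeability p (μm/s) and aggregate binding rate k₁ (1/s), with
the release rate tied through the measured pre-bleach equilibrium ratio
k₂ = k₁/K — while the misfit falls from 1093 to the noise floor of ~245.
The residual few-percent scatter is the statistical limit set by the noise
at this mesh/frame count, with β the softest direction (the misfit is nearly
flat in β above ~16 s⁻¹ for a 2 s bleach: the disc is fully bleached either
way).

The same machinery runs from the shell:

```sh
flipdg synth   --out data/                 # mesh (MSH) + noisy TIFF + truth JSON
flipdg recover --out report.json           # the recovery experiment above
flipdg calibrate --mesh cell.msh --stack flip.tif --mode permeable --out fit.json
flipdg export-scan --out scan.json         # nuclear-export inhibition scenario
```

`flipdg export-scan` simulates export inhibition with the active membrane
model (lowering k_nc at fixed k_cn) and reports the final nucleus/cytoplasm
intensity ratio.  With the bleach spot sitting *inside* the nucleus the
nucleus ends dimmer than the cytoplasm, but slowing export monotonically
retains more protein there:

```
k_nc = 0.342  ->  nucleus/cytoplasm = 0.227
k_nc = 0.200  ->  nucleus/cytoplasm = 0.246
k_nc = 0.050  ->  nucleus/cytoplasm = 0.271
```

## Layout

| module                          | contents                                          |
|---------------------------------|---------------------------------------------------|
| `flipdg.mesh_geometry`          | synthetic cell mesher, Gmsh MSH I/O, edge classes |
| `flipdg.dg_core`                | broken-P1 space, SIPG + interface operators, backward Euler |
| `flipdg.flip_model`             | parameters, hindrance rates, bleach protocol, forward simulation |
| `flipdg.goal_function`          | TIFF stacks ↔ DG fields, misfit                   |
| `flipdg.calibration`            | parameter reduction, Nelder–Mead                  |
| `flipdg.synthetic_experiment`   | ground-truth generator, recovery experiment       |
| `flipdg.cli`                    | `flipdg` command-line entry points                |
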