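# perfusim

Spatiotemporal simulation of PET radiotracer (FDG-like) uptake in a 2-D
solid-tumor tissue slab, driven by an explicit microvascular network.

The pipeline couples three physical layers on a rectangular domain
(default 6.72 cm x 6.09 cm) containing a centered circular tumor
(default diameter 2.3 cm):

1. **Vasculature** — either extracted from a color capillary micrograph
   (green channel, CLAHE, thresholding, small-object removal, contours,
   skeleton-to-graph reduction) or generated synthetically: four parent
   vessels spanning the domain plus a seeded stochastic capillary tree
   with separate target length densities inside and outside the tumor.
2. **Steady fluid flow** — Poiseuille/Kirchhoff blood pressures on the
   vessel graph, coupled through Starling filtration
   `phi_b = L_p (S/V) w(x) (P_b - P_i - sigma_s (pi_b - pi_i))` and a
   lymphatic sink (normal tissue only) to a Darcy interstitial pressure
   problem `-div(kappa grad P_i) = phi_b - phi_L`; interstitial velocity
   `v = -kappa grad P_i`.
3. **Tracer transport** — a three-compartment convection–diffusion–reaction
   system (extracellular free `C_i`, intracellular free `C_e`, phosphorylated
   `C_m`) with a Patlak transvascular flux, driven by a configurable
   arterial input function; operator-split integration (implicit diffusion,
   upwind convection, sub-stepped kinetics).

Analytic oracles (matrix-exponential solution of the well-mixed compartment
system; modified-Bessel radial interstitial-pressure solution) back the
validation suite.

## CLI

All stages are exposed through one entry point (`perfusim` or
`python -m perfusim.cli`), configured by a YAML file (see
`perfusim.config.CaseConfig` for the schema and defaults; units are in the
field names):

```bash
perfusim --seed 1 --outdir out synth            # network, mask, rendered image
perfusim --outdir out extract out/vessel_image.png --pixel-size 2e-5 --threshold 0.5
perfusim --config case.yaml --outdir out flow        # steady P_b, P_i, IFV fields
perfusim --config case.yaml --outdir out transport   # tracer time course
perfusim --config case.yaml --outdir out report      # region tables, TACs, maps
perfusim --config case.yaml --outdir out convergence --factors 1,2,4
perfusim validate                                    # oracle self-checks
```

Outputs are NPZ arrays, ASCII VTK structured grids, and CSV tables
(region medians/means of all compartments, probe time-activity curves).

## Layout

```
src/perfusim/
  imaging.py     image -> mask -> contours -> centerline graph
  synth.py       seeded synthetic networks, rasterization, rendering
  flow.py        vessel Poiseuille + Starling + Darcy coupling
  transport.py   three-compartment CDR integrator
  aif.py         arterial input function models
  oracles.py     closed-form reference solutions
  reporting.py   region stats, probe TACs, normalized maps
  pipeline.py    case runner, benchmarks, mesh-convergence study
  config.py      YAML case configuration
  fixtures.py    canonical benchmark cases
  cli.py         command-line interface
```
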