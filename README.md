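# spportrait

Stochastic phase portraits for chemical reaction networks.

Deterministic phase portraits draw the drift field `f(x)` of an ODE model.
For stochastic reaction networks the quantity that marks where probability
accumulates is instead the **convective field**

```
alpha_i(x) = f_i(x) - (1/2N) * sum_k dD_ik/dx_k
```

built from the drift `f = S·nu` and diffusion matrix `D = S·diag(nu)·S^T` of
the Fokker-Planck description (`S` = stoichiometric matrix, `nu` =
concentration-space propensities, `N` = system size).  Stable (unstable)
fixed points of `alpha` are candidates for maxima (minima) of the stationary
probability distribution wherever the probability current vanishes.  This
package constructs those fields symbolically from a reaction specification,
draws stochastic phase portraits, finds and classifies fixed points, locates
stochastic bifurcations — including the *nullcline-gap bifurcation*, where
the convective flow between two nullclines near a state-space boundary
reverses and a boundary probability maximum appears or disappears — and
validates the predictions with exact Gillespie simulation and a closed-form
1D stationary-density oracle.

## Modules

| module | contents |
| --- | --- |
| `spportrait.reaction_network` | reaction grammar + YAML model files, stoichiometric matrix, propensities (falling factorials), integer conservation laws |
| `spportrait.fields` | symbolic drift / diffusion / convective field, probability current, symbolic or finite-difference derivative policies |
| `spportrait.phase_portrait` | multistart damped-Newton fixed points with classification, marching-squares nullclines, orthant-clipped trajectories, limit-cycle detection with speed profiles, boundary-maximum candidates |
| `spportrait.bifurcation` | eigenvalue-crossing, nullcline-gap, and nullcline-detachment bisection; parameter sweeps |
| `spportrait.gillespie` | direct-method SSA, time-weighted stationary histograms with 1/N-aligned bins, mode extraction |
| `spportrait.stationary_1d` | conservation-law reduction to 1D, closed-form stationary density `p ∝ (1/D) exp(2N∫f/D)`, extrema consistency report |
| `spportrait.models` / `spportrait.cli` | built-in fixtures (`foraging_colony`, `rosenzweig_macarthur`) and the command line |

## Command line

```bash
# phase portrait with field grid, nullclines, fixed points (+ optional PNG)
spportrait portrait -m rosenzweig_macarthur --set N=50 -o out/ --plot

# fixed points of the convective field
spportrait fixedpoints -m rosenzweig_macarthur --set N=80 -o out/

# nullcline-gap bifurcation over system size
spportrait bifurcate -m rosenzweig_macarthur --n-range 10 1000 -o out/

# exact SSA run + stationary histogram
spportrait simulate -m foraging_colony --t-max 100 --seed 1 -o out/

# closed-form 1D stationary density along the conservation line
spportrait stationary1d -m foraging_colony --set r=15 -o out/

# round-trip a model file
spportrait export -m rosenzweig_macarthur -o out/
```

Models are either fixture names or YAML files of the form

```yaml
species: [X, Y]
parameters: {beta: 0.8, delta: 0.2}
reactions:
  - "X -> 2 X @ beta"
  - "X + X -> X @ delta"
  - "X + Y -> 2 Y @ d/(1 + A*X)"   # rates may be expressions of species concentrations
  - "0 -> X @ q"
system_size: 80
```

Every CLI run writes a JSON provenance record (parameters, seed, versions)
next to its outputs.

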