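# cavitydiff

Water transport in viscous saccharide matrices, end to end:

* **`droplet_fickian`** — forward spherical-shell Fickian model of water
  transport in an aqueous-organic droplet after a relative-humidity step
  (equal-solute-mass shells, instantaneous gas–surface equilibrium,
  explicit conservative time stepping), stretched-exponential (KWW)
  characterization of size-response functions, and simultaneous
  multi-curve inverse fitting of a polynomial `log10 D_w(a_w)`
  parameterization including the dry-matrix intercept `D_w_org`.
* **`se_divergence`** — Stokes–Einstein prediction
  `D = C k_B T / (eta a)`, divergence quantification in orders of
  magnitude, fractional-exponent (`D ∝ eta^-alpha`) fitting in log–log
  space, and joining of independently parameterized `D(a_w)` and
  `eta(a_w)` axes.
* **`cavity_hopping`** — tracer-trajectory analysis of the hopping
  mechanism: Einstein-relation MSD diffusion coefficients,
  Gaussian-emission hidden Markov models (state-count selection by
  held-out likelihood, relaxation timescales with bootstrap credibility
  intervals), Boltzmann-inversion PMF maps, frozen-matrix cavity
  probing, transition-state-theory barrier/rate conversion, hop
  statistics and matrix position autocorrelation times.
* **`free_volume`** — grid-insertion occupied/free volume fractions of
  packed configurations under periodic boundaries.
* **`synthetic_data`** — generators for every input class with known
  ground truth (shell-model response curves, multi-well overdamped
  Langevin trajectories with slow matrix-like depth modulation, exact
  two-state jump processes, random sphere packings), so every analysis
  stage is testable by parameter recovery.
* **`io` / `pipeline` / `cli`** — XYZ / GRO / CSV trajectory formats with
  periodic unwrapping, CSV+JSON sidecar formats for curves and packings,
  and a seeded end-to-end pipeline.

Units: nm / ps / k_B·T inside trajectory code; m / s / m² s⁻¹ for
droplet transport; Pa s for viscosity (see `cavitydiff.constants`).

## CLI

```sh
cavitydiff --help
cavitydiff se predict --eta 1e-3             # SE diffusion coefficient
cavitydiff hop tst --barrier 6.42            # TST barrier -> hop rate
cavitydiff synth --config spec.yaml --out data.csv
cavitydiff fickian fit-kww response.csv
cavitydiff fickian fit-d r1.csv r2.csv --order 2 --out d.json
cavitydiff se table --d-json d.json --eta-coeffs 9,-14,2 --out table.csv
cavitydiff hop msd traj.csv
cavitydiff hop hmm traj.csv --n-states 2 --out model.json
cavitydiff fv frac packing.csv --spacing 0.05
cavitydiff run --config configs/demo.yaml --out pipeline_out
```

`cavitydiff run` executes synthesize → fickian fit → SE table → hopping
→ free volume from a YAML config (see `configs/demo.yaml`), writes all
artifacts plus `report.json`, and derives every stage's randomness from
the single global seed through named substreams.

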