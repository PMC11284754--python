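# starwrap

Coarse-grained simulation of cell-membrane wrapping of spiked nanostars
versus ligand-patched spheres, with the analysis observables needed to
compare their uptake kinetics.

The model couples:

- an implicit-solvent 3-bead lipid bilayer (1 head + 2 tail beads per
  lipid; FENE bonds, harmonic 180° angle, WCA excluded volume, cosine
  tail–tail attraction with width w_c = 1.5σ),
- rigid bead-shell nanoparticles — a spiked star (7σ core, 5σ tips,
  3σ→1.5σ frustum profile, 12σ maximum radius) or a 12σ sphere — built on
  deterministic Fibonacci lattices,
- reversible ligand–receptor Morse bonds (well depth 30ε, r₀ = 1σ,
  α = 1σ⁻¹) with single-valence bookkeeping: unbound pairs within 1.3σ
  bond with 50% probability at each kinetics sweep; bonds longer than 4σ
  break,
- Langevin (BAOAB) dynamics at T = 1 ε/k_B, γ = 1 τ⁻¹, dt = 0.01τ, with
  a zero-tension barostat rescaling the periodic XY box (Z is open).

All quantities are in reduced units (σ, ε, τ). Everything is generated —
no external data. Numba-compiled kernels keep desk-scale systems
(10³–10⁴ beads) tractable on one CPU; a cell-list/Verlet pair path is
cross-checked against an all-pairs oracle in the test suite.

## CLI

```bash
starwrap build-particle --shape star --out star.xyz        # surface as XYZ
starwrap run --config run.toml --seed 1 --out out/         # wrapping replicas
starwrap table2 --config run.toml --seed 1 --out out/      # star vs 7 sphere layouts
starwrap analyze --checkpoint state.npz --out thickness.csv
starwrap report --run-dir out/
```

Configs are flat TOML with dotted sections; `scale_preset = "paper"`
selects the full protocol (10,452 lipids in a 77σ × 77σ box, 5 replicas
of 10⁴τ), `"reduced"` a desk-scale variant. Unknown keys are rejected,
and every run directory receives the fully materialized config, so runs
are reproducible from `(config, master_seed)` alone. Example:

```toml
scale_preset = "reduced"
replicas = 3

[particle]
shape = "sphere"
n_patches = 20
ligands_per_site = 14

[integrator]
dt = 0.01
```

## Observables

- wrapping fraction (|Σ Morse bond energy| normalized by the all-bound
  maximum) and wrapping time (first sustained crossing of the completion
  threshold, default 0.9 held for 100τ),
- binned membrane thickness maps (0.5σ bins, per-leaflet head
  projection, linear interpolation of empty bins),
- vesicle lipid identification and per-window lipid displacement,
- sphere/star wrapping-time ratios across the seven 280-ligand patch
  layouts (56×5 … 10×28),
- the transwell apparent-permeability utility P_app = (V/(A·C₀))·(ΔC/Δt).

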