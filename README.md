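# hiphopsim

Chromatin dynamics with a heteromorphic polymer (HiP-HoP-class) model:
multivalent bridging proteins that switch between binding and
non-binding states, cohesin-like loop extrusion stalled at convergently
oriented CTCF sites, and a fiber whose mechanics vary along its length
with chromatin state. The package is for quantitative chromatin
biologists and biophysical modelers who want to ask how transcription-
associated protein binding and fiber structure shape the *motion* of a
gene locus — not just its average contacts — without needing any
external data: a synthetic-locus generator reproduces the statistical
structure of real inputs (binding sites embedded in open-chromatin
domains, sparse convergent CTCF anchors with variable occupancy).

## Model in brief

A locus is a bead-spring chain (1 kbp/bead, bead diameter
σ = 17.6 nm, time unit τ = 2.07 ms, both calibrated). Langevin dynamics
(BAOAB, kT = 1, γ = 1 τ⁻¹) evolve beads, diffusing protein spheres and
extruder springs in a periodic box at interphase-like crowding:

* proteins switch binding ⇌ non-binding at k_sw = 10⁻³ τ⁻¹ ≈ 0.48 s⁻¹
  and, when binding, feel a 6 kT short-range well toward binding-site
  beads — multivalency makes them bridges, and bridging drives cluster
  formation;
* extruders grow loops at k_ex = 2 bp τ⁻¹, unbind at
  k_off = 2.5×10⁻⁵ τ⁻¹, and stall direction-dependently at CTCF beads
  weighted by occupancy;
* compact chromatin carries bending stiffness and next-nearest-neighbor
  crumpling springs; open (H3K27ac) chromatin carries neither.

From sampled trajectories the package computes per-bead mobility
M = MSD(10⁴ τ ≈ 20.7 s), local density (particles within
3 σ ≈ 53 nm), extruder occupancy φ_e, interaction localness L (contacts
< 100 kbp vs ≥ 100 kbp at 3.5 σ ≈ 62 nm), simulated CaptureC profiles
and FISH separation distributions, subdiffusion exponents α from
log-log MSD fits, and the configuration vector
**X** = (x_UP, x_UD, x_PD) of three probe separations with its
shape-change parameter S(t) and variability √det cov(**X**). Two
alpha-amanitin models are built in: A (remove all binding sites) and
B (freeze all current protein–chromatin bonds).

See `docs/methods.md` for the full model description, parameter table
and design rationale.

## Worked example

Generate a synthetic locus, simulate it at desk scale, and analyze:

```bash
hiphopsim fixtures --outdir demo --seed 1 --n-beads 400
hiphopsim simulate --config demo/demo_config.yaml --out demo/run.h5
hiphopsim analyze --traj demo/run.h5 --probes demo/probes.bed \
    --outdir demo/analysis --mobility-lag-tau 200 --viewpoint 200
```

which writes bedGraph tracks (`mobility`, `local_density`, `localness`,
`extruder_occupancy`, `capturec_200`), FISH separation TSVs,
configuration vectors and the S(t) curve. A library session on the same
locus:

```python
import numpy as np
import hiphopsim as hh

tracks, ann = hh.generate_toy_locus(n_beads=400, seed=1,
                                    n_open_domains=4, n_ctcf_pairs=2)
params = hh.SimulationParameters(n_proteins=40, n_extruders=2,
                                 t_equil=600.0, t_sample=3000.0,
                                 n_frames=150, seed=7)
traj = hh.run_simulation(ann, params)

m = hh.mobility_profile(traj, lag_tau=200.0)        # sigma^2 per bead
rho = hh.local_density(traj)                        # neighbors within 3 sigma
print(round(np.corrcoef(m.values, rho.values)[0, 1], 2))
print(round(float(np.median(m.values[ann.is_binding_site])), 1),
      round(float(np.median(m.values[~ann.is_binding_site])), 1))
```

prints

```
-0.74
7.5 27.2
```

a strong mobility–density anticorrelation across the locus, and
protein-binding sites moving far less (median per-bead MSD at a 200 τ
lag of 7.5 σ²) than the rest of the chain (27.2 σ²): bridging proteins
cluster at the binding sites, making them the dense, slow anchors of
the locus — the central qualitative behavior of the model at desk
scale.

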