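# Methods

## Model

`hiphopsim` simulates a chromatin locus as a bead-and-spring polymer in
which each bead represents 1 kbp of chromatin and one bead diameter
(σ) maps to 17.6 nm. Three mechanisms organize the locus:

1. **Bridging proteins.** Diffusing spheres (diameter 1 σ) represent
   complexes of transcription factors and polymerase. Each protein
   switches stochastically between a binding and a non-binding mode at
   rate k_sw (default 10⁻³ τ⁻¹ ≈ 0.48 s⁻¹); in the binding mode it is
   attracted to binding-site beads (accessibility peaks) through a
   truncated-shifted Lennard-Jones well (depth ε_b = 6 kT, cutoff
   1.8 σ). Because the well reaches several beads at once, proteins are
   multivalent and bridge distal sites; this *bridging-induced
   attraction* drives the spontaneous formation of protein clusters at
   groups of binding sites, and mode switching keeps the clusters
   dynamic.
2. **Loop extrusion.** A fixed number of extruders (default one per
   400 kbp) act as harmonic springs (rest length 1.5 σ) between two
   anchor beads. Anchors step outward stochastically so that the loop
   grows at k_ex = 2 bp τ⁻¹ in total (rate k_ex/2 per side per bp);
   extruders unbind at k_off = 2.5×10⁻⁵ τ⁻¹ (mean residence 4×10⁴ τ)
   and are instantly re-loaded at a random adjacent bead pair, keeping
   the count constant. An anchor landing on a CTCF bead whose motif
   orientation faces it (forward sites block the left-moving anchor,
   reverse sites the right-moving anchor, so convergent pairs trap
   extruders) stalls permanently for that binding event, with
   probability equal to the site's occupancy weight.
3. **Heteromorphic fiber.** Compact (unmarked) chromatin carries a
   cosine bending potential (K_θ = 4 kT) and next-nearest-neighbor
   "crumpling" springs (k = 20 kT/σ², rest 1.5 σ). Open chromatin
   (H3K27ac-marked) carries neither, so it is the thinner, more
   flexible fiber state. We realize heteromorphism purely through
   these mechanical terms; a two-bead-size fiber geometry is out of
   scope.

All particle pairs interact through a purely repulsive WCA potential at
diameter 1 σ; chain neighbors are bonded by stiff harmonic springs
(k = 100 kT/σ², rest 1 σ) and are excluded from the nonbonded terms, so
a bonded pair at rest length feels zero net force. Energies are in kT;
forces are exact negative gradients of the potentials (verified against
a finite-difference oracle in the tests). The attraction well is
energy-continuous at its cutoff; its force has the usual truncation
step there.

## Integration and schedule

Dynamics are overdamped-Langevin in an implicit solvent, integrated
with the BAOAB splitting at kT = 1, friction γ = 1 τ⁻¹, bead mass 1 and
dt = 0.01 τ. Pair interactions use minimum-image distances in a cubic
periodic box sized so the beads occupy a target volume fraction
(default 0.1, an interphase-like crowding level); neighbor search is a
cell list with a 0.4 σ Verlet skin. Coordinates are stored unwrapped,
so displacement-based observables need no boundary handling, while all
contact observables apply the minimum image.

The chain starts in a compact, mitotic-chromosome-like conformation: a
serpentine raster (straight 1 σ-spaced runs folded row by row and layer
by layer into a dense block) with a small seeded jitter. Consecutive
beads stay within [0.9, 1.1] σ and no two beads start closer than
0.8 σ. Proteins are placed uniformly at random with half of them
initially binding (the steady state of symmetric switching); a short
push-off phase (500 steps with per-step displacements capped at
0.05 σ) resolves random-placement overlaps before normal dynamics.

A full-scale run discards t_equil = 7×10⁵ τ of relaxation and then
samples 400 frames evenly over t_sample = 7.96×10⁵ τ (≈ 27 min of real
time; frame interval ≈ 4 s). Protein switching and extrusion events are
applied between integration blocks of 10 τ; at the default rates the
per-block event probabilities are ≪ 1, so the discretization error of
the event kinetics is negligible (the exponential residence and
waiting-time statistics are verified in the tests). Desk-scale
configurations used in the test suite shrink the locus (400 beads, 40
proteins, 2 extruders) and the schedule (≈ 600 τ equilibration,
2–3×10³ τ production, 100–150 frames); these sizes were chosen so every
qualitative behavior of the model (clustering, stalling, mobility
contrasts) is measurable with comfortable statistics.

Randomness derives from one root seed per run, split into independent
streams for the thermostat, protein switching and extrusion, so results
are bit-reproducible and robust to subsystem reordering.

## Unit calibration

Simulation units map to physical units through two independent fits,
both implemented in `calibration`:

* σ (nm): grid search plus bounded golden-section refinement for the
  length scale minimizing the mean two-sample Kolmogorov–Smirnov
  statistic over nine matched probe-separation distributions (three
  probe pairs × three cell states).
* τ (s): least-squares fit, in log-log space, of the time-axis scale
  aligning the bead-averaged simulated MSD curve with a reference
  motion-tracking MSD curve, after σ is fixed.

Both routines recover planted scales on synthetic inputs to grid/fit
resolution. The package ships the calibrated defaults σ = 17.6 nm and
τ = 2.07×10⁻³ s with provenance `default_paper`; reference experimental
distributions are not bundled.

## Observables

* **MSD / mobility.** Time-and-origin-averaged MSD per bead or per
  probe region (center-of-mass or bead-averaged). Mobility M is the MSD
  at a fixed lag, 10⁴ τ ≈ 20.7 s at full scale (desk-scale analyses use
  a lag scaled to the production span). M is an MSD and is therefore
  reported in length-squared units — σ² with a µm² conversion alongside
  — with the lag recorded in the track metadata.
* **Local density ρ.** Count of other particles (beads + proteins)
  within 3 σ ≈ 53 nm, averaged over frames. Reported as counts per
  sphere, not a projected areal density.
* **Extruder occupancy φ_e.** Fraction of frames in which a bead lies
  within ±1 bead of an active extruder anchor (the beads the extruder
  spring attaches to); ±1 is our operationalization of "vicinity".
* **Localness L.** Per bead, contacts (< 3.5 σ ≈ 62 nm, same locus
  copy) are split at 100 kbp of genomic separation;
  L = near/(far + 1), pooled over frames, with log₂ L exported. The +1
  pseudocount keeps L finite where far = 0.
* **Simulated CaptureC.** Per viewpoint bead, the fraction of
  (frame, copy) observations with a bead within 3.5 σ, pooled across
  copies sharing the viewpoint's source annotation; viewpoint ±1
  masked; raw contact frequency without distance-decay or
  fragment-length normalization.
* **Simulated FISH.** Euclidean probe center-of-mass separations per
  frame, in nm, with median/IQR summaries.
* **Contact kinetics.** Run-length decomposition of the two-probe
  contact time series (threshold 3.5 σ); first/last episodes are
  flagged as censored.
* **Configuration space.** For three probes (upstream enhancer, gene,
  downstream enhancer) the configuration vector X collects the three
  pairwise separations. The shape-change parameter
  S(t) = ⟨|X(t₀+t) − X(t₀)|²⟩ averages over origins within each
  trajectory (never across trajectory boundaries) and then over
  trajectories. Locus variability is the generalized-s.d. volume
  √det cov(X) (nm³ for three probes) — the "size of the
  configuration cloud" has no unique definition, so per-component
  standard deviations are exported too and the metric is named in the
  output metadata.

## Perturbation models

Transcription inhibition is modeled two ways. **Model A** removes every
protein-binding site from the annotation (complexes no longer bind
anywhere) and re-equilibrates. **Model B** freezes the system at the
moment of treatment: every binding-mode protein within the attraction
range (1.8 σ) of a binding-site bead acquires a permanent harmonic bond
to it, with the rest length set to the pair's separation at treatment
time so the freeze is strain-free (a protein may bond several beads,
freezing its bridges); fixed proteins stop switching, and the run
continues from the treated state
without re-equilibration — an acute treatment. The untreated arm shares
the equilibrated state with model B, so matched-seed comparisons differ
only by the intervention. Only protein/binding-site bonds are frozen;
proteins incidentally near non-binding beads are left free. Sweeps over
k_sw, protein number, extrusion rate, extruder count and CTCF density
(adding fully occupied sites at random positions) run the full pipeline
per value and seed and emit a tidy table.

## Synthetic loci

`synthetic_locus` generates annotation tracks with the statistical
structure of real regulatory-locus inputs: log-normal open-chromatin
domains placed without overlap (free length distributed by a Dirichlet
draw), Poisson numbers of 1-kbp binding sites uniform within domains
plus a rate-controlled fraction of orphans outside, and convergent CTCF
anchor pairs (forward left of reverse, spans 100–400 kbp) with
Beta-distributed occupancies. The generator reproduces the *embedding
structure* that the model's mechanisms respond to; it does not mimic
real peak width/strength distributions, sequence context, or any
specific genome build, so passing tests demonstrate mechanism-level
behavior, not locus-specific predictions.

## Homogeneous-chain benchmark

The engine's polymer dynamics are validated against Rouse scaling: for
a flexible chain the internal motion of interior beads is subdiffusive,
MSD ∝ t^0.5, between the segmental time (~1 τ here) and the Rouse time
τ_R = ζ / (12 kT/b² sin²(π/2N)) (≈ 1.35×10³ τ for N = 200; the
long-wavelength modes are entropic with spring constant 3 kT/b²
regardless of the microscopic bond stiffness). A short free chain adds
two finite-size artifacts an effectively infinite chain does not have:
center-of-mass diffusion (slope 1) leaking into the lab-frame MSD, and
saturation of the internal MSD near τ_R. The benchmark therefore
measures the interior-bead MSD in the chain's center-of-mass frame
(the standard polymer g2), pools several independent trajectories, and
fits the log-log slope over [30 τ, τ_R/2] — above the segmental time
and below the onset of plateau curvature (excluded volume slows the
relaxation, making the τ_R/2 cut conservative). Protocol:
`validation.measure_rouse_exponent`, 200 beads, no proteins, extruders,
bending or crumpling, 2×10³ τ equilibration and 10⁴ τ production
(10⁶ integration steps) per trajectory, 1000 frames, three
trajectories.

## Numerical choices and degenerate inputs

* Tracks flag a bead on ≥ 1 bp overlap; a trailing partial bead is
  dropped with a warning; CTCF occupancy scores are normalized to
  [0, 1] by the per-track maximum (missing scores → 1); opposite-strand
  CTCF evidence on one bead blocks both directions with the maximum
  weight.
* Concatemerization places one unmarked 1,000-bead spacer after each
  copy (at full scale: 10 × 3,000-bead copies + 10 spacers = 40,000
  beads), with a seeded random copy order so each copy samples a
  similar surrounding context across repeats.
* A mobility lag that is not a multiple of the frame interval snaps to
  the nearest available lag, recorded in the track parameters; a lag
  beyond the production span is an error.
* Proteins may optionally bind open (non-peak) beads through a weak
  well (`eps_weak`); this is off by default.
* Extrusion stepping is stochastic (rate-exact) by default; a
  deterministic fixed-interval mode is available
  (`deterministic_extrusion`).
* Singular configuration-cloud covariance (e.g. collinear probes)
  yields variability 0 with a warning; S(t) lags beyond a trajectory's
  span are omitted with a warning.
* An integration step moving any particle by > 0.5 σ raises an
  instability error naming the frame reached and advising a smaller dt.
* Trajectory frames are stored float32 (positions to ~10⁻⁶ relative);
  all analysis accumulates in float64.

## Known limitations

* No hydrodynamic interactions; free-draining Langevin dynamics only.
* Fiber thickness is uniform: open chromatin differs mechanically, not
  geometrically.
* Extruder kinetics use a constant-count ensemble with instantaneous
  re-loading; loading-rate-limited regimes are not represented.
* Desk-scale runs carry finite-size effects (center-of-mass diffusion,
  early MSD saturation, chain-end parking of extruder anchors); the
  benchmark protocols are designed around them, and quantitative
  full-scale observables (e.g. real-locus contact maps) require
  full-scale runs with real annotations.
* Because heteromorphism is purely mechanical here, the intrinsic
  open-fiber mobility advantage (~1.4× on a protein-free chain) is
  smaller than the slow-down bridging imposes on peak-bearing open
  domains (~2×), so on a bridged locus open chromatin does not outrun
  compact chromatin; reproducing that ordering requires the thick-fiber
  (bead-size) heteromorphism that is out of scope. Fiber-structure
  mobility signs are therefore demonstrated on protein-free
  heteromorphic chains.
* The alpha-amanitin models bracket the biology (pure loss vs pure
  stabilization); mixtures are not simulated.
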