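# Methods

## Model

The membrane surface layer is a system of N finite electric dipoles in a
plane.  Dipole *i* has centre `r_i` (nm) and in-plane angle `alpha_i`; its two
tip charges `+e`, `-e` sit at `r_i +/- a_i` with
`a_i = (l/2)(cos alpha_i, sin alpha_i)`.  The pair energy is the exact Coulomb
sum over the four tip-charge pairs plus a 12-6 Lennard-Jones (LJ) term acting
on the centre distance; the system's binding energy is the sum over unordered
pairs.  Kinetic degrees of freedom are not propagated: configurations are
sampled by the Metropolis rule (downhill always, uphill with probability
`exp(-dE_p/k_B T)`), which is sufficient for the equilibrium and
quasi-kinetic (fixed-sweep-budget) questions the model addresses.

Boundaries are free.  The simulated patch is a small piece of membrane whose
edges are part of the physics (textures nucleate at edges; gaps open against
vacuum, not periodic images).  Electrostatics is plainly truncated at
`r_cutoff`; the stochastic thermal moves blur the truncation artefact.

### Moves and the mobility parameter k

One elementary step draws one dipole uniformly, rotates it by an angle
uniform on `(-dalpha_max, +dalpha_max)` and displaces it by a magnitude
uniform on `(0, dx_max)` in a uniform direction — a single coupled move, not
alternating move types.  With uniform proposals, `<|dx|>/<|dalpha|> =
dx_max/dalpha_max`, so the constraint `dx_max = k l dalpha_max / pi` realises
the mobility ratio `k = (pi/l) <dx>/<dalpha>` exactly.  `dalpha_max` defaults
to pi/2, a moderate width that keeps rotor acceptance useful across the whole
k grid.  One sweep is N elementary steps; rejected proposals count as steps.

### Units and default potential parameters

Reduced units: `C = e^2/(4 pi eps0 eps_r) = 1` (energy x length), `e = 1`,
`k_B = 1`, lengths in nm, `l = 0.5` nm (phosphatidylcholine head-group
scale), lattice spacing `s = 2l = 1` nm.  An SI preset computes C in zJ nm
from `eps_r` (default 80, aqueous interface).

The LJ parameters control which phase wins, and were chosen so that the model
exhibits both of its regimes:

* `sigma = 1.5 l = 0.75 s`.  The head group's hard core is wider than its
  charge separation but narrower than the lattice spacing.  This is
  essential: if the LJ minimum sits at the lattice spacing itself
  (`sigma ~ 0.9 s`), the close-packed lattice maximises LJ coordination and
  is the *global* optimum at every mobility — mobile dipoles then have
  nothing to aggregate into, and no gel/liquid-crystal transition can occur.
  With `sigma = 0.75 s`, mobile dipoles can approach below `s` into a
  strongly Coulomb-bound head-to-tail contact (pair minimum about `-2.2 C/s`
  at `r ~ 0.72 s` versus `-0.82 C/s` at the lattice spacing), so the fluid
  phase is Coulomb-dominated, the gel phase LJ/lattice-dominated.
* `eps = C/(4s) = 0.25`.  Keeps the six-fold LJ lattice cohesion weak
  relative to the chain contact so that aggregation is favourable, while
  still providing the repulsive wall.
* Core clamp `d_min = 1.1 l`.  The four-charge Coulomb term is singular
  wherever a tip-charge pair coincides, which is geometrically possible for
  *any* centre distance up to `l` (and the LJ term, acting on the centre
  distance, cannot bound the tip-tip distance).  Moves that would bring any
  centre pair below `1.1 l` are therefore rejected outright; with
  `sigma = 0.75` the LJ wall already dominates the residual Coulomb
  attraction everywhere above the clamp, so pair energies are bounded below.
* `r_cutoff = 6 l = 3` nm for protocol runs (plain truncation applied to the
  whole pair term).  Pairwise energies beyond 3 nm are dipole-dipole tails
  of order `10^-2 C/s` and do not change the texture phenomenology; the
  cutoff keeps the move kernel O(neighbourhood).  Library calls accept
  `r_cutoff=None` for exact small-system work, and all invariance tests run
  both ways.

### Temperatures (reduced)

The natural energy scale is the head-to-tail Coulomb bond `2/3 C/s`.

* k-scan bath temperature `T = 0.2`: cold enough that the `k -> 0` lattice
  survives the run intact (the gel anchor at k = 0.1 stays essentially
  gap-free), warm enough that mobile dipoles rearrange into the aggregated
  state within the sweep budget.
* Ramp schedule: geometric, `0.05 -> 0.40` over 8 points (400 equilibration
  + 400 recording sweeps each).  0.40 is just below the rotor disordering
  scale; heating across this range repeatedly precipitates the system out of
  metastable domain arrangements (visible as abrupt energy changes along the
  ramp).
* Final equilibration after the ramp: staged descent
  `0.20, 0.17, 0.15, 0.13, 0.11, 0.09, 0.07, 0.05, 0.035`, 3000 sweeps per
  stage.  A hard single-temperature quench re-traps domain walls; the staged
  descent lets walls anneal out while the temperature is still comparable to
  the wall energy.  With this schedule the 15x15 pinned lattice reaches the
  staggered antiparallel ground state (order > 0.8 and energy within 5% of
  the directly computed perfect-stripe energy) in about 8 of 10 seeds; the
  failures land in the nearly degenerate vortex-like manifold ~2% above the
  stripe state, a real feature of planar dipolar lattices rather than a
  sampling artefact.

### Protocols and their outputs

* `run_temperature_ramp`: one Markov chain heated through the schedule,
  equilibrated and recorded at each temperature (per-point mean/std of E_p,
  acceptance, configuration snapshot), then the staged final equilibration.
  Pinned mode: translations identically zero.
* `run_k_scan`: one independent simulation per (k, replicate), each from
  lattice positions with fresh random orientations (fresh seed per point by
  default; a fixed-seed option exists for variance reduction).  The recorded
  quantity is the mean binding energy over the post-equilibration recording
  window; per-dipole and initial-state-normalised variants are also stored.

## Observables

* **Staggered antiparallel order**: max over the stagger patterns
  `(-1)^row, (-1)^col, (-1)^(row+col)` of the norm of the stagger-weighted
  mean orientation vector.  1 for perfect alternating stripes, O(1/sqrt(N))
  for random angles.  Off-lattice configurations are assigned to nearest
  lattice sites (with a warning when contested).
* **Domains**: connected components of the graph joining dipoles closer than
  `neighbor_radius` (default 1.5 s) with orientation difference folded to
  `[0, pi]` below `angle_threshold` (default 45 deg).  Polar similarity by
  default, so antiparallel neighbours are different domains; a nematic
  variant folds angles mod pi.
* **Gap fraction**: dipole centres are rasterised onto a grid of pitch
  `cell_size` (default s) whose cells are centred on the *initial* lattice
  bounding box (stored with the configuration and preserved under moves);
  the gap fraction is the fraction of empty cells.  An intact rectangular
  lattice scores exactly 0; on hexagonal matrices the square raster over the
  triangular packing leaves a small constant baseline, so gap values are
  comparable within a symmetry, not across symmetries.
* **Textures**: deterministic PNG rendering, one oriented segment per dipole,
  hue encoding angle, fixed px-per-nm scale.
* **estimate_kc**: the replicate-averaged energy curve is 3-point smoothed;
  k_c is the midpoint of the grid interval with maximal |dE/dk| (middle
  interval on exact ties).  Detection requires that slope to exceed the 95th
  percentile of maximal slopes from flat parametric-null curves with noise
  matched to the replicate standard errors; the reported interval is the
  2.5–97.5 percentile of k_c over bootstrap resamples of replicates.  Flat or
  pure-noise curves yield "no transition detected" rather than a number.

## ESR module

`tau = 5.95 * dH0 * (sqrt(I0/I+1) + sqrt(I0/I-1) - 2) * 1e-10 s` from the
three-line amplitudes and the central peak-to-peak linewidth (gauss); the
partition parameter is `F = P/H`, the aqueous high-field amplitude over the
lipid low-field amplitude, exactly in that orientation (the inverse
convention is deliberately not provided).  Line parameters are extracted from
two-column derivative spectra as max-minus-min within user-supplied,
non-overlapping field windows; the central linewidth is the field separation
of the window's extrema.  An optional Savitzky-Golay smoothing window makes
extraction robust to noise (1% additive noise leaves amplitudes within ~5%
and the extracted tau within ~10%).  The fixture generator sums
first-derivative Lorentzians parameterised directly by peak-to-peak amplitude
and peak-to-peak width, plus seeded Gaussian noise; it emulates the line
geometry of fast-motion nitroxide spectra, not anisotropic/slow-motion line
shapes, hyperfine structure, or instrument drift — so extraction tests
validate the arithmetic pipeline, not a full spectral simulation.

## Numerical design

* The sweep kernel is numba-compiled, maintains the running energy through
  per-move deltas (drift < 1e-8 relative over hundreds of sweeps; verified
  against the independent vectorised-numpy energy path), and uses a Verlet
  neighbour list (radius `r_cutoff + skin`, skin >= max(sigma, 2.1 dx_max))
  rebuilt whenever any dipole accumulates skin/2 of displacement, so no
  interacting pair is ever missed.
* All randomness flows from integer seeds through `numpy` generators; the
  kernel draws from a seeded stream derived from the state's generator.
  Identical seeds give bit-identical trajectories within a platform.
* Degenerate inputs: N = 1 systems have zero energy and a single-cell gap
  map; zero-length schedules, non-positive temperatures, overlapping ESR
  windows and malformed configuration files raise typed errors.

## Study sizes

Desk-scale defaults are used throughout: 20x20 matrices for the k-scan
(rather than 30x30) with 3 replicates per grid point and 500+500 sweeps, and
the 15x15 rotor lattice for the ramp.  These sizes were chosen as the
smallest at which the texture phenomenology (domains versus chains-with-gaps,
and the k_c estimate's stability across seeds) is reproducible.

## Limitations

* The transition located by the k-scan is a fixed-budget (quasi-kinetic)
  threshold: the steepest change of the final-state energy within the
  prescribed sweep budget, not an equilibrium phase boundary.  Under the
  default conditions it sits at k_c ~ 0.12-0.15 on both lattice symmetries.
* Dipoles are strictly in-plane; no out-of-plane tilt, no bilayer coupling,
  no explicit water, no polarisability, and no Ewald electrostatics.
* The gap measure is a raster occupancy fraction; it quantifies contrast
  between phases but not absolute defect areas.
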