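# Methods

## The problem

A van der Waals (Lennard-Jones) fluid below its critical temperature
separates into coexisting vapor and liquid.  The coexistence (binodal)
curve bounds the two-phase region; inside it, the spinodal curve separates
the *metastable* band — where droplets form by rare nucleation events and
can persist — from the *unstable* interior, where any fluctuation grows
(spinodal decomposition).  Biological condensates formed by liquid–liquid
phase separation live in the metastable band, so locating **both** lines
matters, and for complex fluids no trustworthy equation of state exists.
`vdwphase` implements estimators that read all four boundary densities at
a temperature directly from NVT molecular-dynamics trajectories:

* **rho_L** (liquid binodal): partition the box into cubic bins of side
  ~2 sigma and pool occupancy counts over the analysis window.  The
  probability `P0` of an empty bin decays with density and vanishes at the
  liquid binodal; `rho_L` is the density where `P0` first drops below a
  small threshold (default 0.005), linearly interpolated between scan
  points.  The threshold and the interpolation define "vanishes"
  operationally; both are exposed as parameters.
* **rho_V** (vapor binodal): the mean size of the per-frame largest
  cluster, `<n_lar>/n_m`, grows rapidly on entering the two-phase region.
  The estimator reports the density of steepest discrete growth of
  `log <n_lar>` on the low-density side of the curve's half-maximum
  (midpoint-of-interval convention).  The log scale is used because
  cluster sizes span orders of magnitude across the transition.
* **rho_sL** (liquid-side spinodal): the mean size over *all* clusters
  `<n>` rises rapidly at a distinctly higher density; the density of
  steepest growth of `log <n>` is the primary estimate, cross-checked
  against the density of the steepest *decrease* of the specific heat.
  A discrepancy beyond two grid spacings is reported as a consistency
  warning, never silently resolved.
* **rho_sV** (vapor-side spinodal): inside the unstable region the
  specific heat shows tall spikes as a function of density.  The estimator
  takes the tallest local maximum on the low-density side of the C_v
  drop that exceeds twice the low-density baseline median.

Two auxiliary estimators:

* **Specific heat** `C_v = var(E) / (k_B T*^2)` per system from total
  (kinetic + potential) energy fluctuations over the analysis window.
  Total energy is used because in Nose-Hoover dynamics its fluctuations
  approximate the canonical ensemble and the estimator has lower variance
  than a potential-only variant plus the analytic kinetic term; the
  potential-only form is available via a switch.
* **Surface tension** from droplet shape fluctuations, by energy
  equipartition: `sigma_ten = k_B T* / u^2`, with `u^2` the time variance
  of the largest non-spanning droplet's radius of gyration.  Droplets
  smaller than 50 particles or ever spanning the box are refused (the
  estimator returns "undefined" rather than extrapolating).

## Model and protocol

Reduced units throughout: epsilon = sigma = m = k_B = 1, time in
tau_LJ = sqrt(m sigma^2/epsilon).  Pairs interact through the 6–12 LJ
potential truncated at r_c (6.85 sigma at full scale) with *plain*
truncation — no energy shift, no tail correction — matching the stated
simulation protocol; phase-boundary locations are sensitive to this
choice (see "Known limitations").  Bead–spring chains add a stiff
harmonic bond `U = k_b (r - sigma)^2`, `k_b = 75000 epsilon/sigma^2`,
between consecutive beads; directly bonded pairs are excluded from the LJ
sum (the minimal exclusion consistent with bonds sitting at sigma, where
the LJ core is strongly repulsive), all other intra-chain pairs are not.

Integration is velocity-Verlet, dt = 0.005 tau_LJ for monomers and
0.001 for chains (the bond frequency is ~550/tau_LJ, so the smaller step
resolves it).  Temperature control is a three-link Nose-Hoover chain —
the form used by common MD engines — with masses Q_1 = g k_B T tau^2,
Q_2 = Q_3 = k_B T tau^2 (g = 3(n-1) after momentum removal; damping
tau = 1 tau_LJ for monomers, 10 for chains), integrated with the
reversible Martyna–Tuckerman–Klein half-step splitting.  A single
Nose-Hoover variable is not ergodic for weakly coupled systems — it fails
to thermalise an ideal gas at all — whereas the chain reproduces
canonical kinetic-energy fluctuations (verified against `(3/2) n k_B` in
the test suite).  The thermostat rescales all velocities uniformly, so
the exactly-zero total momentum set at initialisation is preserved.

A full-protocol run is 1e6 steps for monomers / 5e6 for chains
(5000 tau_LJ either way); the first two thirds are discarded as
equilibration and analysis uses the final third (~1666 tau_LJ).  Frames
are sampled every 100 steps (monomers) / 500 (chains), i.e. every
0.5 tau_LJ.

### Initial configurations

Random insertion rejects pairs closer than 0.85 sigma (attempt budget
100 n); at densities where that fails the builder falls back to a simple
cubic lattice.  Velocities are Maxwell–Boltzmann, shifted to exactly zero
total momentum and rescaled so the kinetic energy equals
(3/2)(n-1) k_B T*.  Chains grow as self-avoiding random walks with bond
length exactly sigma.  Because the stiff bond-stretch modes exchange
energy with the soft bath only on very long (Landau–Teller) timescales, a
chain built with all bonds at exactly sigma would keep its stretch modes
at roughly half their canonical energy for thousands of tau_LJ; each
bond therefore receives an independent Gaussian relative-velocity kick
along the bond at initialisation, sized so the mode starts with its full
canonical mean energy (total momentum unaffected).  The stretch variance
then relaxes near k_B T/(2 k_b), though per-mode energies still wander
slowly; the corresponding test asserts factor-two agreement, not a tight
tolerance.

### Numerical choices

* Neighbour lists: half list with 0.4 sigma skin, rebuilt when any
  particle moves more than half the skin; built from a cell grid when at
  least three cells fit per box side, otherwise an all-pairs scan.  Each
  pair's periodic image shift is recorded at build time and positions are
  only rewrapped at rebuilds, which keeps the recorded image exact and
  removes all minimum-image arithmetic from the force loop.
* Plain truncation makes the *bookkept* energy discontinuous (it jumps by
  Phi(r_c) when a pair crosses the cutoff), so NVE conservation is
  diagnosed with the optional cutoff-shifted potential (identical
  forces); production runs keep plain truncation.  An NVE run aborts if
  the relative energy drift exceeds 1%.
* `r_cut = 0` disables pair interactions entirely (ideal gas), used for
  thermostat validation.
* If a requested cutoff does not fit the box, it is clamped to
  box/2 − 1e-6 with a logged warning.
* Occupancy grid: floor(box / bin_side) bins per axis anchored at the
  origin; the residual sliver is merged into the last bin per axis (the
  effective bin side, box/m, is what the Poisson reference
  `P0 = exp(-rho V_bin)` uses).  Fewer than 8 bins is an error.
* Cluster identification: contacts are minimum-image pairs within
  1.3 sigma, found with a periodic k-d tree; clusters are connected
  components (SciPy sparse graph).  Chains cluster through the quotient
  graph (chains adjacent iff any inter-chain atom contact).  Singletons
  count as clusters of size 1, keeping cluster sizes a partition of the
  system at every density.  Gyration radii are computed on coordinates
  unwrapped by BFS over the contact graph; a cluster is "spanning" if its
  unwrapped extent reaches the box side along an axis *or* a contact edge
  closes a loop around the box (the second test catches rings whose
  discrete extent is just under the box length).  Ties for "largest
  cluster" break to the lowest minimum particle index.
* Critical point: with both binodal branches over >= 2 temperatures, fit
  the mean-field law (rho_L − rho_V)^2 = A^2 (T_c − T) linearly in T
  (beta = 1/2, the van der Waals exponent; the Ising value is out of
  scope) and the rectilinear diameter (rho_L + rho_V)/2 = rho_c +
  b (T_c − T) evaluated at T_c.  Temperatures violating rho_V < rho_L
  are excluded with a warning.
* Boundary ordering rho_V < rho_sV <= rho_sL < rho_L is validated on
  every assembled temperature; violations are flagged in the output, not
  silently fixed.

## Scaled-down ("desk") conditions

The full protocol (4000 particles, r_c = 6.85 sigma, 1e6 steps per state
point, hundreds of state points) is a cluster-scale computation.  The
package ships a "desk" preset — n = 1000, r_c = 4 sigma, 5e4 steps —
that runs a single state point in about 1.5 minutes and a
15-density temperature slice in well under an hour.  The test suite uses
this preset for its end-to-end checks (one T* = 1.1 slice over
rho* in [0.01, 0.9]); the thermodynamic-consistency and conservation
tests use n = 100–500 systems with cutoffs of 2.5–4.5 sigma, sized so the
default suite completes in a routine run.

Two systematic effects of the desk scale are worth knowing:

* The shorter cutoff weakens the attraction, lowering the critical
  temperature and narrowing the coexistence region: at T* = 1.1 the
  desk-scale empty-bin crossing sits near rho* ≈ 0.53–0.55, below the
  0.64 of the full-cutoff fluid.  This is a real thermodynamic shift, not
  insufficient sampling: a configuration prepared *with* a cavity at
  rho* = 0.58 closes it under the desk protocol.  The four-boundary
  *ordering* and the qualitative shapes of all estimator curves are
  unchanged.
* 250 tau_LJ of desk simulation leaves less room for slow nucleation than
  the 5000 tau_LJ protocol; deep in the metastable band the desk
  estimates lean toward the spinodal side.

The synthetic-data generators used by the tests (uniform ideal-gas
configurations, hand-built multi-cluster blobs, cube-corner geometries,
synthetic estimator tables built from an exact mean-field parabola)
emulate the *statistical* structure the estimators consume — Poisson bin
occupancy, known partitions, known gyration radii, known boundary curves
— not the dynamics of a real fluid.  Tests passing on them validate the
estimator algebra and the locator logic; the desk-scale MD slice is what
ties the chain together end to end.

## Known limitations

* Plain truncation means binodal/spinodal locations depend on r_c; only
  the full r_c = 6.85 sigma protocol reproduces literature coexistence
  densities.  The desk preset is for method validation and qualitative
  maps.
* A global thermostat cannot equilibrate the stiff chain bond modes on
  accessible timescales; the canonical-energy initialisation mitigates
  but does not eliminate this (per-mode energies drift slowly).
* C_v from total-energy fluctuations in Nose-Hoover dynamics is an
  approximation to the canonical C_v; near transitions its spikes are
  strongly seed-dependent at desk scale.
* The surface-tension estimator tracks the largest non-spanning cluster
  per frame; droplet identity across frames is not otherwise tracked, so
  exchange events add variance to u^2.
* No finite-size scaling, no solid phases, no long-range corrections.
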