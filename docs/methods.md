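# Methods

## Model

All quantities are in reduced Lennard-Jones units: unit mass = bead mass,
unit length = effective bead diameter, unit energy = kBT (so T = 1 and
β = 1 throughout). The full-scale geometry is a 54.29 × 64.44 × 20 box,
periodic in x and y, with implicit planar walls at z = 0 (the tethering
surface) and z = H; the production bead count is 45,510 at overall number
density n = 0.65.

Bead taxonomy: repulsive coating beads R (anchors `R_tethered`, immobile and
exactly at z = 0, exempt from both walls), water w, hydrophobic protein
beads H, polar protein beads P, and attractive beads A (backbone-doped) or
`A_ligand` (immobile, at fixed altitude z_lig). The interaction matrix is
WCA for every pair except

- H–H: truncated-shifted LJ with ε = 120, rc = 1.19. The truncation makes
  the *effective* well depth ≈ 10.5 kBT, not 120 — a strong but physically
  sensible hydrophobic attraction. Both parameters are config-exposed
  (`system.hh_pair`).
- P–A and P–A_ligand: εLJ1.5 with ε ∈ {1, 3} (`system.ap_pair`), the doping
  attraction toward the protein's polar part.

Bonds are FENE (k = 30, R = 1.5) plus the WCA pair term between bonded
neighbours; 1-2 pairs are excluded from the type-pair table (the standard
bead–spring convention — so bonded H–H neighbours do *not* get the deep
attraction). Walls use the integrated 9-3 form; coating/water/A beads feel
the purely repulsive truncation at (2/5)^(1/6) ≈ 0.858, protein beads an
attractive εWzc well. The shift constant in the 9-3 potential uses zc (the
energy must vanish at the cutoff). Because the interaction matrix is
ambiguous about whether polar beads feel a 9-3 or an LJ-form z-wall, the
default gives both H and P the 9-3 wall ("protein beads are attracted by the
surface as a whole"); `system.p_wall_style: lj` switches P beads to a 12-6
z-wall.

The effective wall strength I = ∫₀^zc exp(−W(z)) dz is computed by adaptive
quadrature (scipy `quad`, relative tolerance 1e-9) on (δ, zc], with δ chosen
by bisection as the point where W > 700 — below it exp(−W) underflows to
exactly 0 in double precision, so nothing is lost. For ε = 0 the integral is
zc exactly and is returned analytically.

## Construction

Anchors sit on a jitter-free near-square lattice (the (nx, ny) grid with
nx·ny ≥ G whose cell is closest to square); chains start rodlike normal to
the surface at the FENE+WCA equilibrium bond length 0.9609. A straight rod
of N = 50 beads (height ≈ 47) cannot fit under the wall at H = 20, so chains
that would not fit are started as a vertical serpentine (arms joined by
1.05-wide lateral turns) under a configurable height cap; `fold=False`
restores the strict rod-or-error behaviour.

Doping retypes exactly one bead per chain: the 1-based index ⌈N/2⌉ for
`middle` (bead 25 for N = 50), the free end for `terminal`, a uniformly
chosen non-anchor bead (free end allowed) for `random`. Ligand doping places
round(σ_lig·A) immobile A beads on a uniform xy lattice at z = z_lig = 3,
each replacing the nearest unclaimed water bead, so every doping mode
conserves the total bead count.

Water insertion guarantees pairwise distance ≥ 1 (wrapped in xy) for all
non-bonded pairs. The default mechanism is a jittered cubic lattice whose
spacing enforces the minimum distance by construction, progressively
densified (down to the spacing-1 limit) because candidate sites within 1 of
existing beads are discarded; plain rejection sampling is available
(`method="random"`) but is practical only well below n = 0.65, which sits
near the random-sequential-addition jamming density. The lattice start is
slightly ordered; the first few thousand MD steps melt it.

Protein conformations come from single-chain collapse runs: one HP chain
(seeded random sequence with exactly round(hp·Np) H beads) starts rodlike in
an elongated xy-periodic water slab (cross-section 9 × 9, repulsive walls)
and runs NVT until Rg is stationary; each of the Gp library copies uses its
own sequence and run.

A caveat discovered during validation: plain NVT at T = 1 traps a
substantial fraction of random sequences in metastable multi-cluster
("pearl-necklace") states at Rg ≈ 3.5 that survive 10⁶-step runs — each
missing H–H contact costs ~10 kBT, so these states have negligible
equilibrium weight but an enormous escape barrier. The
`equilibrate_single_protein` protocol is therefore adaptive: a plain NVT
collapse segment (t = 1000); then, *only while* the trailing Rg stays above
2.5 (the gap separating the globule at ~1.9–2.1 from the necklace at
≳ 2.7), heat/quench rounds of t = 100 at T = 2 — where the well is
effectively half as deep and cluster merging proceeds — followed by t = 400
of re-equilibration at T = 1, re-checked after every round (at most 4);
finally t = 750 of T = 1 production. Replicas that collapse on their own
are never heated (an unconditional anneal can melt an already-correct
globule and leave it uncollapsed within the window). The stationary Rg is
the square root of the trailing-30% mean of Rg² over the whole trace; that
window lies in the T = 1 production (and, after many anneal rounds, the
T = 1 tail of the last cool) — hot segments never enter the average. The
`equilibrated` flag requires a sub-threshold final Rg and 5% agreement
between the halves of the averaging window. Ensemble estimates over
replicas average ⟨Rg²⟩ over the replicas whose flag passes: a replica still
trapped after its annealing budget is measuring the metastable state, not
the stationary quantity. The flag conditions on convergence only, never on
the value itself. Copies are placed on a uniform xy grid above the measured
coating height with clearance 1.0, a random in-plane rotation, and overlap
retries (jittered) up to a bounded count.

## Dynamics

Velocity Verlet with Δt = 0.005. The Nosé–Hoover thermostat is a single
thermostat in the Martyna–Tuckerman–Klein splitting with coupling time equal
to the damping parameter (default 1) and Q = g·T·τ²; g counts 3 degrees of
freedom per *mobile* bead. A BAOAB Langevin integrator (friction 1/damping)
is provided as an ergodic alternative and, at T = 0, as a quench; it is
bit-reproducible given the seed. Neighbour search is an xy-periodic linked
cell list compiled to a half Verlet list (cutoff = max pair cutoff + 0.3
skin) rebuilt on half-skin displacement. Positions are stored unwrapped;
minimum image is applied inside the kernels, so chain metrics never need
re-unwrapping. A bead crossing z = 0 or z = H, an overstretched FENE bond,
or a velocity blow-up aborts the run with the completed step count rather
than continuing silently.

The compiled kernels (numba) are cross-checked in the test suite against a
brute-force O(n²) reference built directly from the scalar potential
functions.

## Umbrella sampling and WHAM

The steered protocol tethers the protein COM to the surface with a harmonic
z-spring of rest length lspring = 1 and varies the *stiffness* in equal
steps k_j = j·Δk (Δk = 0.005) from 0 up to 0.3 — beyond which the stationary
extension no longer changes — giving 61 windows; each window runs t = 500
saving the COM altitude every 10 steps (10⁴ samples). Windows run in
ascending k, each continuing from the previous window's final state, with
the first 10% of each window discarded as burn-in (both choices
config-exposed; the source protocol does not specify them).

WHAM iterates the standard coupled equations for the unbiased P(z) and the
window free energies f_j on bins of width 0.1 over (0, Lz), with the f_j
gauge fixed at f_0 = 0 (the PMF is invariant to a common shift), convergence
at max_j |Δf_j| < 1e-6, and PMF(z) = −(1/β) ln P(z)/P(z₀). The reference z₀
defaults to the sampled bin farthest from the lower wall (a bulk reference);
the weights g_j = (1 + 2τ_j)⁻¹ default to 1, with an optional estimator for
τ_j via Sokal-windowed integrated autocorrelation. Non-convergence returns
`converged=False`; adjacent windows without histogram overlap trigger a
warning naming the gap.

The estimator is validated against a synthetic oracle: biased windows drawn
*exactly* (multinomial over bin centres) from the Boltzmann weights of a
known double-well PMF, where every per-bin probability is available in
closed form. Recovery within 0.1 kBT over the sampled range bounds the
estimator bias by counting noise.

## Observables

Rg² = N⁻¹Σ(r_i − r_cm)², R² = (r_N − r_1)², h = max z_i per chain; ensemble
values report ⟨Rg²⟩^(1/2) and the mean height hmax = ⟨h⟩. The dry reference
height is hdry = σN/n. The coating regime is brush iff the measured Rg²
exceeds the area per chain Σ = 1/σ (the strict reading of the definition);
below Σ/2 it is called mushroom, between the two intermediate — the Σ/2
split is this package's quantification of "Rg² ≪ Σ".

Asphericity uses the gyration-tensor *eigenvalues* R1 ≥ R2 ≥ R3:
α = [(R1−R2)² + (R2−R3)² + (R3−R1)²] / [2(R1+R2+R3)²], which is rotation
invariant and gives exactly α = 1 for collinear chains and 0 for
R1 = R2 = R3. The raw-diagonal reading (not rotation invariant) is reported
alongside as a diagnostic of frame dependence.

A protein is adsorbed at a frame when COM_z < hmax − Rg_p. By default hmax
is recomputed per frame from the coating chains, because adsorption itself
shifts the coating height and a static reference would bias the fraction; a
fixed reference is available as a switch. Density profiles are counts /
(A·Δz·frames) with default Δz = 0.2, so the bin sum recovers the mean
selected-bead count. Stationary values average the trailing 30% of a series
and report mean ± standard error.

## Synthetic/miniature systems and what green tests establish

The fixtures (`dimer`, `ideal-gas-slab`, `mini-mushroom`, `single-protein`)
are deterministic miniatures: the mini coating uses 9 chains of 10 beads and
two 12-bead proteins started from a synthetic serpentine "globule" rather
than an MD-collapsed library. They exercise the full machinery — energy
conservation, thermostat accuracy, adsorption counting, format round-trips —
at seconds-to-minutes scale. They do not reproduce production physics:
chain lengths, protein sizes, box dimensions and run lengths are far below
the full-scale setup (10⁸ steps, 45,510 beads), so quantitative adsorption
percentages and density profiles from the minis are illustrative only. What
the scaled tests *do* establish quantitatively: the single-protein collapse
reaches the reference stationary Rg within its stochastic tolerance, and the
qualitative ordering of adsorption with wall strength holds as a rank
correlation across all 8 wall types.

## Numerical choices and limitations

- Overflow guard: pair/wall evaluations below separation 1e-6 raise instead
  of returning inf.
- NVE with the stiff H–H well (curvature ~6900 at the minimum) is marginal
  at Δt = 0.005 (~15 steps per period): energy error stays bounded and below
  1e-3 relative on the fixtures, but tighter conservation needs a smaller
  step.
- The Nosé–Hoover temperature oscillates (period ≈ 2πτ/√2) while a freshly
  built system relaxes; temperature acceptance uses time averages, and
  equipartition checks use the Langevin integrator.
- Velocities are initialised Maxwell–Boltzmann at T with the mobile-set net
  momentum zeroed.
- Electrostatics, barostats, bond constraints, 2-D umbrella sampling, MBAR
  and bootstrap error bars are out of scope; folding/unfolding with
  electrostatic interactions would need additional terms.
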