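# Methods

This note documents the models, estimators and numerical choices behind
`usb1mech`, and what the synthetic ground truth does and does not establish
about real systems.

## Scope and overall design

The package analyses the catalytic mechanism and substrate preference of
Usb1, a 3'->5' exoribonuclease of the 2H phosphodiesterase family that trims
the oligo-uridine tail of U6 snRNA by intramolecular transphosphorylation:
the 2'-OH of the penultimate (n-1) nucleotide, deprotonated by a histidine
base, attacks the adjacent phosphate while a second histidine protonates the
departing 5'-oxygen, leaving a 2',3'-cyclic phosphate.  Every stage of the
computational workflow around that chemistry is implemented at desk scale:
biased sampling on reaction surfaces, free-energy reconstruction, minimum
free energy paths, transition-state-theory rates and isotope observables,
transition-state hydration statistics, crystal-contact geometry,
single-cleavage saturation kinetics, and a secondary-structure-gated
trimming model.

The electronic-structure layer of a real QM/MM study is deliberately
replaced by analytic model surfaces with exactly known minima, saddles and
gradients (`usb1mech.surfaces`).  The acceptance surface of the package is
therefore *algorithm correctness* -- does the sampling/analysis machinery
recover known ground truth -- not the chemistry of any particular energy
function.  Passing tests demonstrate correct estimators and path analysis;
they do not validate a force field, a QM Hamiltonian, or the magnitude of a
real reaction barrier.

## Collective variables

Three CV kinds are implemented (`usb1mech.colvars`), all in Angstrom:

* **Antisymmetric stretch** `d(A,H) - d(H,B)` for a transferring atom H
  between donor A and acceptor B.  The three reaction coordinates are
  nucleophile deprotonation (O2'-H2'-NE2 of the base histidine), phosphoryl
  transfer (evaluated as `d(P,O5') - d(O2',P)`), and leaving-group
  protonation (NE2-HE2-O5' of the acid histidine).  Sign convention:
  every CV is negative in the reactant and positive in the product, so
  "reaction progress" reads uniformly left to right.
* **Relay zeta**: the mean of two consecutive antisymmetric stretches for a
  donor -> shuttle -> acceptor proton relay.  This is a deliberate
  simplification of the literature center-of-excess-charge coordinate: it
  preserves relay topology and monotonicity but is not the
  charge-weighted functional form, and no Fermi-weighting of protonation
  states is attempted.
* **Distance**, for monitoring contacts.

All gradients are analytic and tested against central differences at 1e-6.

## Model surfaces

`make_double_well(barrier, separation)` is the 1D quartic
`V = B((2x/s)^2 - 1)^2` -- the standard oracle for barrier recovery.

`make_mechanism_surface(deprotonation_cost d, main_barrier B,
asynchronicity a)` builds a 3D surface over (deprotonation x, transfer y,
protonation z), with basins at CV values +-0.8 A, as a sum of four terms:

1. a clamped quintic smoothstep in x rising by `d` (the deprotonation leg),
   plus a small quartic double well in x (depth `min(0.5, d/4)`) that
   keeps the reactant and the deprotonated shoulder as genuine, weakly
   separated minima -- the shoulder's reverse barrier is a fraction of a
   kcal/mol, i.e. "no appreciable reverse barrier";
2. a quartic double well of height `B - d` along the concerted diagonal
   `q = (y+z)/2` (the rate-limiting passage);
3. a transverse harmonic in `r = (z-y)/2` whose valley center is displaced
   by `a * cos^2(pi q / 1.6)` -- at the saddle the protonation CV leads the
   transfer CV by `2a`, so `a` tunes transition-state asynchronicity
   without changing the barrier;
4. an ordering coupling `B (1 - smoothstep(x)) (q + 0.8)^2` that makes
   moving the concerted pair before deprotonation cost more than the
   barrier itself, forcing the mechanism ordering.

All four listed features (reactant, shoulder, saddle, product) are exact
critical points of this analytic form: the smoothstep and `cos^2` envelopes
have vanishing value *and* slope at the basin coordinates, so the gradient
terms cancel identically there, not just approximately.  The reactant is
the unique global minimum (every term is non-negative and only their joint
zero set is the reactant).  The reaction as modelled is endothermic by `d`
(the product keeps the deprotonation cost); only barrier heights measured
from the reactant matter for the analyses here.

Defaults: `d = 6` kcal/mol (the deprotonated-shoulder cost is not an
experimentally fixed number; 6 kcal/mol is a plausible cost for moving a
proton onto a histidine and is comfortably below the barrier),
`B = 21.6` kcal/mol (the scale of the computed reaction barrier for this
chemistry), `a = 0`.

## Metadynamics sampler

Dynamics run *directly in CV space* (`usb1mech.metad`): each walker is a
Langevin particle with per-CV effective mass (default 50 amu) on
`surface + bias`.  This removes the atomistic engine while preserving the
bias/free-energy mathematics exactly.  Integrator: BAOAB splitting,
timestep 0.5 fs, friction 10 ps^-1, reflecting walls at the domain box.
Units: kcal/mol, Angstrom, ps (1 kcal/mol = 418.4 amu A^2/ps^2).

Hills are Gaussians of height 0.1 kcal/mol and width 0.1 A deposited every
200 steps -- standard fixed-height practice for stretch-type reaction
coordinates.  Multi-walker runs pool all walkers' hills synchronously at
deposition time; per-run reproducibility is bitwise for a fixed seed and
config.  Well-tempered scaling (`bias_factor`) is available but off by
default, matching the fixed-height protocol.

For speed the *in-run* bias force is looked up on an accumulation grid
(spacing `hill_width / 2.5`, nearest-node gradient).  This approximation
touches only the sampling dynamics; `bias_energy`, `bias_force` and all
reconstruction are exact Gaussian sums (reconstruction truncates each hill
at 6 sigma, relative error < 2e-8).

## Free-energy estimation

`reconstruct_fes` defaults to the textbook estimator `F = -V_bias`,
normalized to min 0.  For fixed-height hills this estimate oscillates
around the true surface with an amplitude (~1 kcal/mol under the default
hill parameters) that does **not** decay with longer sampling; we verified
this directly on the double-well oracle.  The `average_from=f` option
therefore implements the time-averaged bias estimator -- the average of
`-V_bias` over all deposition times after the first fraction `f` of the
log, which reduces to a per-hill height reweighting
`w_j = (n - max(j, n0)) / (n - n0)`.  Averaging over the post-fill half of
the log (`f = 0.5`) cancels the oscillation and recovers the double-well
barrier to about +-0.2 kcal/mol and the well-to-well asymmetry to under
0.3 kcal/mol at the default sampling budget (8 walkers x 2e5 steps); the
recovery pipelines use it.

Grid default: 0.02 A resolution over the hills' bounding box padded by
3 sigma (0.05 A for 3D grids, where 0.02 A would make the grid the
dominant cost).

## Path analysis

The minimum free energy path between grid nodes is the bottleneck-optimal
("minimax") path: among all grid-adjacent routes it minimizes the maximum
free energy en route, computed by Dijkstra on the max-metric with ties
broken by path length then lexicographic node order.  Adjacency includes
diagonal neighbors (3^d - 1 moves), which makes paths smoother without
changing the bottleneck value.  The barrier is referenced to the
reactant-basin minimum (steepest descent from the requested start node), so
it is invariant to additive offsets.  The implementation is verified
exactly against an independent threshold/connectivity bottleneck search on
random grids.

Basin finding uses a strict 3^d - 1 neighborhood minimum filter with
plateau components merged; a plateau adjacent to strictly lower ground is a
shelf, not a basin.  Mechanism ordering reports, per CV, the fraction of
its reactant-to-product displacement completed at the path maximum; the
transition state is called *tight* (associative) when the
phosphoryl-transfer CV sits in the central 25% of its range there, *loose*
only when supplied nucleophile/leaving-group distances exceed a threshold
(default 4.6 A), and *indeterminate* otherwise.

The classical toolkit reports the deprotonated shoulder's (small) classical
reverse barrier as-is; whether that state survives zero-point motion is a
quantum question outside scope.

## Rates and isotope observables

`eyring_rate` applies plain transition-state theory
`k = kappa (k_B T / h) exp(-dG/RT)` with CODATA constants, transmission
kappa = 1, and default T = 298.15 K (always echoed, since a reported rate
is meaningless without its temperature -- a 21.6 kcal/mol barrier gives
0.9e-3 s^-1 at 298 K and 3.8e-3 s^-1 at 310 K, which brackets measured
~1e-3 s^-1 turnovers for this chemistry).  `barrier_from_rate` is the
exact inverse.

`gross_butler` evaluates `k_n = k0 prod_i (1 - n + n phi_i)` on a uniform
D2O mole-fraction grid with the max chord deviation as a linearity score:
exactly one in-flight proton gives an exactly linear inventory, two or more
curve below the chord -- the classic counting diagnostic.

`semiclassical_kie` is a harmonic zero-point model for a stretch softened
at the TS, with deuterium frequencies idealized as `nu_H / sqrt(2)`.  Real
X-H/X-D ratios are ~1.35-1.41, so the model slightly overstates the
zero-point difference; it reproduces the ~1.4 scale of a partially retained
stretch (3000 -> 2524 cm^-1) and ~8 for a fully lost 3000 cm^-1 stretch.
It is a stand-in for path-integral free energy perturbation, which is out
of scope.

## Hydration and contact geometry

RDFs are normalized by `4 pi r^2 dr` shell volumes and a bulk density
estimated from the outer 20% of `r_max` when not supplied.  The first
solvation shell is the minimum of smoothed g(r) (5-bin moving average)
between the first prominent peak (relative prominence 0.5) and the next;
on a flat minimal plateau the plateau middle is taken, and featureless
profiles yield an explicit no-shell outcome.  The synthetic shell generator
places an exact planted occupancy, so shell-count recovery is tested
exactly up to background densities of 0.02 A^-3.

Distance time courses report per-trajectory traces, the pointwise mean
across trajectories, and the RMS deviation from the time-and-trajectory
mean as the fluctuation band.

Structure geometry reads mmCIF/PDB through gemmi.  Hydrogen bonds are
heavy-atom N/O pairs across residues within 3.5 A, flagged weak in the
3.3-3.5 A band -- the cutoff is bracketed by the observation that a 3.3 A
contact is a long hydrogen bond while 3.7 A cannot hydrogen bond; the
D-H...A angle (>= 120 deg) is tested only when hydrogens are present.
Glycosidic chi is O4'-C1'-N9-C4 (purines) / O4'-C1'-N1-C2 (pyrimidines)
with syn = (-30, 90] by the standard nucleic-acid convention.  Alternate
locations resolve to highest occupancy, ties to altloc 'A'.  RMSDs use
Kabsch superposition (SVD with determinant correction), cross-checked
against an independent rotational-alignment oracle.

## Kinetics and trimming

Michaelis-Menten fits are nonlinear least squares on
`v = Vmax S/(Km + S)`, initialized from a Hanes-Woolf linearization, with
asymptotic standard errors; `kcat = Vmax/E0` assumes fully active enzyme.
Km estimates outside `[min(S)/50, 50 max(S)]` are flagged ill-determined.
The packaged substrate table stores the measured single-cleavage constants
(kcat on the 1e-3 s^-1 scale, Km in uM); efficiencies `kcat/Km` are
reported on the 1e3 M^-1 s^-1 scale, with relative values computed from
unrounded efficiencies and rounded only for display (2 decimals / 2
significant figures).  The synthetic data generator uses the measured
seven-point dilution series (0.85-55 uM) and additive Gaussian noise
truncated at zero -- the error model of the real assay is not known, so
recovery statistics under this noise are indicative, not calibrated.

The trimming model encodes an active site that holds exactly two unpaired
nucleotides: the 3'-terminal residue is removed while (i) at least two
residues remain (floor configurable; default 1, since fully unpaired
substrates are degraded essentially completely), (ii) the last two
positions are both unpaired, and (iii) the n-1 residue carries a 2'-OH.
Pairing state is an *input* (dot-bracket); no secondary-structure
prediction is attempted.  On a 111-nt U6-like input paired through
position 106 this yields the observed 107-nt major product.

Distributive kinetics are a first-order sequential chain with one rate per
length, keyed by the terminal dinucleotide and gated by the same rules.
The deterministic mode exponentiates the bidiagonal generator; the
stochastic mode is a seeded Gillespie ensemble (for a pure chain,
cumulative exponential waiting times); the two agree to total-variation
< 0.02 at 1e4 replicates.  The default rate map anchors UA:22, AA:7.2,
AU:0.63, UU:1.0 to measured efficiency ratios; G- and C-terminal steps
carry placeholder relatives 0.5 and 0.1 that encode only the qualitative
A > U > G > C terminal preference and should not be used quantitatively.

## Problem sizes and tolerances

Recovery pipelines use 8 walkers x 2e5 steps (1.6e6 total steps, ~8000
hills) -- enough for the averaged estimator to reach its plateau accuracy
on both the 1D double well and the 3D mechanism surface with the barrier
scaled to 8 kcal/mol.  The simulation-study tolerances (median Km error
15% at 5% noise; RDF 5% at 200 frames; equipartition 5%) are set by the
sampling-noise scale of those budgets, not by external data.

## Known limitations

* CV-space Langevin dynamics has no atomistic detail: mass/friction are
  effective parameters, and kinetic observables other than barrier-derived
  TST rates are not meaningful.
* The relay-zeta CV is a topological stand-in for the
  center-of-excess-charge coordinate.
* The semiclassical KIE ignores tunneling and anharmonicity.
* The trimming model treats pairing as static; competition between
  refolding and trimming is not modelled.
* Contact-geometry conclusions about deposited structures require those
  coordinate files as input; the test suite exercises the machinery on
  synthetic models with exact geometry.
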