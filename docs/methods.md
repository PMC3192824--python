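# Methods

This note describes the models, algorithms and numerical choices behind
`pathmetad`, and what its synthetic validation systems do and do not
establish about real molecular systems.

## The problem

Large conformational transitions of membrane receptors — the outward
swing of TM6, the breaking of the R3.50–E6.30 "ionic lock", the rotamer
flip of the W6.48 "toggle switch" that together mark GPCR activation —
take place on timescales far beyond plain molecular dynamics.  The
toolkit implements a combined adaptive-biasing strategy: (1) find a
transition pathway with ratchet-biased (adiabatic-bias) dynamics, (2)
turn the pooled pathway samples into an ordered set of reference
conformations by agglomerative clustering, (3) define path collective
variables over those references and reconstruct the free-energy
landscape along them with well-tempered metadynamics, and (4) reweight
the biased trajectory onto any other order parameter (here, the three
activation descriptors).

## Units and constants

Distances in Å, energies in kcal/mol, time in ps, masses in amu,
temperatures in K, angles in degrees; k_B = 0.0019872041 kcal/(mol·K);
1 kcal/mol = 418.4 amu·Å²/ps² when converting forces to accelerations.

## Ratchet (adiabatic-bias) dynamics

The order parameter χ(R) is the Cα RMSD (after optimal superposition)
from the target conformation, expressed in nm so the elastic constant
carries its conventional kcal/(mol·nm²) units.  A harmonic penalty
½k(χ − χ₀ − m)² acts only when χ − χ₀ exceeds its running minimum m;
progress is free, backsliding is penalised, and m is updated whenever
the system improves.  Defaults: k = 10 kcal/(mol·nm²), χ₀ = 0, ten
independent runs.  This k is deliberately soft (the penalty for a 0.1 nm
backslide is 0.05 kcal/mol): the ratchet rectifies slow diffusion rather
than dragging the system, so runs must be long enough for thermal
motion to carry the transition.

The gradient of the fit-RMSD follows from the envelope theorem: at the
optimal rotation U, ∂d/∂xᵢ = (2/M)(x⁰ᵢ − Uᵀyᵢ) over the M masked atoms
(the rotation's own derivative vanishes at the optimum).

## Path collective variables

Given ordered references R₁..R_n and the metric d(R, R_j) = squared
fit-RMSD (Å²),

    s = Σⱼ (j−1)·e^{−γ d_j} / [(n−1) Z],   z = −(1/γ)·ln Z,
    Z = Σⱼ e^{−γ d_j},

so s runs from 0 (inactive end) to 1 (active end) and z measures
distance from the path.  An unnormalized dialect (Σ j e^{−γd}/Z,
spanning [1, n]) is available for compatibility with cluster-index
numbering.  Both are computed through log-sum-exp and never return
non-finite values.  γ defaults to 1/0.25 = 4 Å⁻².  With realistically
spaced references (consecutive d ≈ 0.1–1 Å²) the exponential weights
overlap; s is then a smooth, monotone reparameterisation of progress
rather than a staircase, which is the regime the method is designed
for.  `validate_path` reports consecutive distances, their coefficient
of variation, a recommended γ of order 1/mean(d), and s, z at every
reference; z < 0 at references flags overlap.

Each d_j uses its own optimal superposition onto R_j (standard path-CV
practice).  Gradients of s and z with respect to coordinates follow by
chain rule through the softmin weights p_j = e^{−γd_j}/Z.

## Well-tempered metadynamics

Gaussians of width σᵢ and height w_t' are deposited every τ ps along
the CVs; w_t' = w·exp(−V/(k_B ΔT)) with V the bias already accumulated
at the deposition point, and the free energy is estimated as
F = −(T+ΔT)/ΔT·V, min-shifted.  Defaults: w = 0.4 kcal/mol, τ = 8 ps,
ΔT = 10·T at T = 300 K (bias factor 11), σ_s = 0.1, σ_z = 1 Å².  The
toy-system studies deposit more frequently (τ = 0.25–0.5 ps) because
their diffusion times are picoseconds rather than nanoseconds; hill
height, widths and bias factor are unchanged.

Hill heights are computed from the exact Gaussian summation; the
dynamics reads bias forces from a grid cache (spacing σ/16, linear
interpolation of the analytic gradient, Catmull-Rom cubic interpolation
of the value) that grows automatically whenever a hill approaches its
edge — hills are never truncated.  Exact and gridded evaluation agree
to better than 10⁻³·w.

The progress variable is confined by one-sided quartic walls
(E = k(s−bound)⁴, k = 500) at s = −0.2 and 1.2, and z by an upper wall
where configured; wall positions are configuration, not physics.

## Langevin integrators

Inertial BAOAB (friction in 1/ps) and overdamped Euler–Maruyama
(diffusion coefficient D in Å²/ps) are provided; both are driven by a
single integer seed and are bit-reproducible.  Stability heuristics:
dt·ω ≲ 0.1 for the stiffest harmonic mode (BAOAB) and
(D/k_BT)·U''·dt ≲ 0.1 (overdamped).  The 1D/2D analytic-potential
studies use the overdamped integrator; the Cartesian bead systems use
BAOAB with friction 0.5–2 ps⁻¹, which reaches diffusive sampling much
faster than the overdamped limit for stiff networks.

## Reweighting

A metadynamics trajectory samples e^{−β(F+V)}; statistics over
unbiased observables need per-frame weights.  Two schemes:

* `final_bias`: w ∝ exp(+V_final(cv)/k_BT), appropriate once the
  well-tempered bias has nearly converged; the analysis discards an
  initial transient (first quarter to third of the run).
* `time_dependent`: w ∝ exp(+[V(cv,t) − c(t)]/k_BT) with the running
  offset c(t) = (1/β)·ln[∫e^{βγ/(γ−1)V}/∫e^{β/(γ−1)V}] (γ = bias
  factor) evaluated on a CV grid after every hill.  The integration
  domain is the sampled CV range; the domain choice shifts c(t) by a
  slowly varying constant which cancels in normalised weights to the
  extent it is time-independent.

Both normalise to mean 1 and are cross-validated against each other and
against brute-force unbiased sampling on tilted double wells.
Statistical errors for biased runs are quoted as standard errors over
independent replicas: frames within one run are correlated through the
shared bias history, so block errors within a single run underestimate.

Projections are weighted histograms, F = −k_BT·ln p, min-shifted;
unoccupied bins are flagged, never extrapolated; default 100 bins in 1D
and 60×60 in 2D; no Jacobian correction is applied to angular axes.
Basin analysis finds local minima by prominence (default threshold
0.2 kcal/mol); barriers are segment maxima in 1D and min-max
(union-find percolation) path heights in 2D; the most stable basin is
starred, with ties (< 0.05 kcal/mol) broken toward the lower first-axis
value.  Basin free-energy *differences* are computed from Boltzmann
populations of the basin regions, which is invariant under
reparameterisation of the progress variable (pointwise F(s) values are
not: a nonuniform s↦configuration mapping contributes k_BT·ln|ds/dq|).

## Pathway construction

Pooled frames are compared by fit-RMSD over the path mask; the
dissimilarity matrix is clustered with average linkage (UPGMA,
delegated to scipy).  By default the clustering input is the ratchet
runs' *progress envelope* — the frames at which χ set a new running
best — rather than the raw pool: a thermalised run dwells in basins,
so raw pooling over-represents them and the selected references clump
in basin noise; the envelope traces the transition itself and yields
nearly equidistant, monotone references.  Raw-pool clustering remains
available.  The tree is cut at 30 clusters; each cluster is
represented by its medoid (minimum mean dissimilarity member — stays in
sampled conformation space); medoids are ordered by the progression
coordinate RMSD(·, inactive) − RMSD(·, active); and 10 references are
selected at equal spacing in cumulative consecutive-medoid RMSD arc
length, always including the clusters nearest the two endpoints,
numbered j = 1 from the inactive end.

## Activation descriptors

* d_IL: distance between the centre of mass of {NH1, NH2} of R3.50 and
  {OE1, OE2} of E6.30.  (Glutamate's terminal carboxylate oxygens carry
  PDB names OE1/OE2 — formally ε-oxygens — although they are often
  loosely called δ-oxygens; selection is by those names.)
* χ_TS: the χ1 dihedral N–CA–CB–CG of W6.48, IUPAC sign convention.
* d_TM6/Δd_TM6: after rigid alignment onto the inactive reference over
  a configurable mask, the distance from the fixed midpoint
  M = ½[⟨R_2.41⟩ + ⟨R_6.35⟩] of the inactive structure to ⟨R_6.35⟩, and
  its change from the inactive value.  M is computed once from the
  inactive structure, never per frame.  Which atoms define the
  alignment is not standardised; the default is the Cα set excluding
  the mobile elements (for the mini-receptor, the static core helices
  2, 3 and 7), exposed as configuration.

## Synthetic systems and what they show

`make_double_well(b, a, w)` is the quartic U = b[(x/w)²−1]² + ax/(2w);
its exact tilted stationary points come from polynomial root-finding,
so barrier and minima offsets are known, not nominal.

The mini-receptor is a 28-bead seven-helix bundle with labelled
pseudo-residues (BW tags 2.41, 3.50, 6.30, 6.35, 6.48 and the atom
names the descriptors need).  Its two end states are built so the
descriptors hit exactly the canonical inactive (d_IL = 3 Å,
χ_TS = 163°, Δd_TM6 = 0) and active (12 Å, 55°, 5.9 Å) values, with a
TM6 swing, TM5-like tilts and an overall Cα rearrangement of ≈ 2.3 Å —
the magnitude of a real receptor's activation.  Its energy is a tilted
double well (default barrier 2.0, offset 1.0 kcal/mol) along the
linear inactive→active mode plus a uniform harmonic restraint
(k = 10 kcal/mol/Å², i.e. ≈ 0.4 Å thermal Cα fluctuations, matching a
folded core) on orthogonal motion.  Because the orthogonal stiffness is
identical everywhere, the free energy along the mode equals the
double well up to a constant — an exact ground truth for the sampling
stack.  The barrier was set low enough that unbiased 300 K dynamics
crosses in hundreds of ps, so pathway-finding and landscape
reconstruction are testable at desk scale; the softly-ratcheted runs
then sample the transition rather than being dragged through it.

The two-state bead chain (6 beads, ~4 Å fit-RMSD between states, stiff
k = 100 network, low outward barrier tilted toward the target) is the
fixture for the ratchet rule itself: runs must reach χ below 10% of its
initial value, which requires thermal fluctuations small compared to
the conformational change.

What these fixtures do **not** show: force-field realism, explicit
solvent or membrane effects, rugged many-basin landscapes, CV hysteresis
from genuinely orthogonal slow modes, or the nanosecond-to-microsecond
separation of timescales of a real receptor.  Passing tests establish
the correctness and convergence of the estimators on landscapes where
the truth is known, not the accuracy of any particular molecular model.

## Problem sizes used in validation

Analytic 1D studies: 4×10⁵ overdamped steps (dt = 0.002 ps, D = 1),
~1600 hills, three seeds; recovery RMS error is measured over the
region within 4 k_BT of the global minimum, where sampling is
meaningful.  Reweighting studies: four independent metadynamics
replicas against a 10×-longer unbiased run, with replica-scatter error
bars.  The pipeline study: ten 160-ps ratchet runs, clustering of their
~100–200 progress-envelope frames, four 800-ps path-CV metadynamics
replicas started
alternately from the two end states (start-state alternation cancels
initialisation bias in the basin-population estimate).  These sizes
were chosen so the estimators' statistical errors are comfortably
inside the documented tolerances.

## Known limitations

* The time-dependent reweighting offset assumes quasi-equilibrium at
  each bias level; during the initial filling phase this is violated
  and the scheme slightly underestimates deep-basin weights, which is
  why an initial transient is discarded.
* `find_basins_and_barriers` in 2D requires user-supplied basin seeds;
  unsupervised watershed analysis is out of scope.
* No block-analysis error bars on projected surfaces (future work);
  replica scatter is the recommended uncertainty estimate.
* The bias-grid gradient is linearly interpolated; forces are smooth to
  O((Δ/σ)²), adequate for sampling but not for energy-conservation
  studies.
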