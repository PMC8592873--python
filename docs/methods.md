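# Methods

This note records the models implemented in `dimerlink`, the defaults and
why they were chosen, what the synthetic generators do and do not emulate,
and the numerical decisions a maintainer would want to know.

## Dynamical contact network

Nodes are residues, located at the per-frame mass-weighted center of their
heavy atoms. Two residues are connected when the minimum distance over
their heavy-atom pairs is ≤ `contact_cutoff` (4.5 Å) in at least
`occupancy_min` (75%) of frames. Two different distances deliberately
coexist: the *contact test* uses the heavy-atom minimum distance, while
the *edge weight* uses the node-center distance series, matching the node
definition.

The default weight convention is the literal variance-over-mean form
C_ij = Var(r_ij)/⟨r_ij⟩. Because "coefficient of variation" conventionally
means sd/mean, a `sqrt_var_over_mean` convention is selectable; both are
recorded in edge metadata. The choice does not affect which contacts
exist, and it preserves the ordering of path weights whenever edge CVs are
scaled jointly (doubling all weights doubles all path weights and changes
no memberships — asserted as a property test).

Moments are population (1/F) averages: the frames are a time average of a
trajectory, not an n-sample estimator of anything.

Within a chain, contacts with |Δresnum| ≤ 1 are excluded by default
(configurable to 0). Covalently forced neighbor contacts have near-zero
distance fluctuation and would otherwise dominate every minimum-weight
path; excluding nearest neighbors is standard practice in dynamical
network analysis.

Edge betweenness is weighted Brandes centrality with *unnormalized*
unordered pair counts; co-optimal paths split their pair's count equally.
Critical edges are those with betweenness ≥ mean + kσ (k = 3 by default)
over the edge-betweenness distribution; when the distribution has zero
spread the inequality is strict, so a perfectly uniform graph flags
nothing. Minimum-weight paths enumerate all co-optimal routes (capped,
default 100) and order them lexicographically rather than silently picking
one, because floating-point near-ties are platform dependent.

No frame alignment is needed anywhere in the network stage: all inputs are
internal distances, and rigid-motion invariance is asserted to 1e-9.

## Ensemble statistics

RMSF is sqrt of the mean squared displacement about the mean position,
per Cα, on an ensemble aligned by mass-unweighted Kabsch superposition
(Cα selection by default — the reported quantities are Cα quantities).
PCA diagonalizes the 3A×3A population covariance of the flattened
selection coordinates; modes are sign-fixed (largest-magnitude component
positive) and orthonormal to 1e-8.

B-factor normalization (B′) is per chain and Cα-only, because flexibility
asymmetry *between* the two protomers is itself the quantity of interest.
The default is a robust z-score, (B − median)/(1.4826·MAD), which a single
mobile loop cannot inflate; the classic (B − mean)/sd form (sample sd) is
available. The exact normalization of external B-factor-comparison servers
is not reproduced.

## Structure comparison

Superposition is Kabsch on Cα pairs matched by (chain, residue number).
`iterative_reject` repeats the fit up to 5 cycles, discarding pairs whose
deviation exceeds 2× the current RMSD, and reports both the post-rejection
and the all-pairs RMSD: published RMSDs from molecular-graphics aligners
are post-rejection numbers, and the two can differ by a few tenths of an
Å, so both are always emitted. Whether a published alignment covered one
protomer or the dimer is often unstated; the pairing helper accepts a
chain subset so both protocols can be run.

SASA is Shrake–Rupley sampling with 960 deterministic golden-spiral points
per atom and probe radius 1.4 Å, over a Chothia-style radius table
(C 1.70, N 1.55, O 1.52, S 1.80 Å). The sphere points are expressed in a
molecule-fixed frame built from the principal axes of the heavy-atom cloud
with a deterministic sign convention, which makes the sampled area exactly
equivariant under rigid motion (asserted to 1e-9). For rotationally
degenerate point clouds the frame is arbitrary within the degenerate
subspace; such shapes are rotationally symmetric to within sampling error,
which the analytic sphere tests bound at ≤ 1.5%.

Relative accessibility divides residue SASA by the theoretical maxima of
Tien et al. (Gly-X-Gly); the interface threshold "> 10%" is interpreted as
10 *percentage points* of relative accessibility lost between the isolated
chain and the dimer, the common convention for accessibility differences.
Buried surface area is SASA(A) + SASA(B) − SASA(AB); the conventional
interface area BSA/2 is reported alongside.

Polar contacts use heavy-atom distance-only criteria — donor/acceptor
N/O–N/O ≤ 3.5 Å for hydrogen bonds, basic side-chain N to carboxylate O
≤ 4.0 Å for salt bridges — because ~2 Å crystal structures carry no
hydrogens and angle terms would rest on modeled positions.

## Mutation screen

Filters apply in a fixed order (interface membership → fold-stability gap
→ residue-type exclusion → charge preservation → binding ΔΔG), each record
annotated with its first failure. The predicates are mutually independent,
so the surviving set is order-invariant (asserted by shuffled
re-application); only the annotation depends on the order. Histidine
counts as neutral at pH 7, matching the protonation convention of the
simulation setup the tables accompany. The ΔΔG sign convention is
positive-destabilizing throughout.

## Measurement models

*Diffusion.* The decay exponent uses b = (γgδ)²(Δ − δ/3 − τ/2) with δ the
**total** bipolar-pair gradient duration (a stated half-duration of 4.3 ms
means δ = 8.6 ms), Δ = 70 ms and τ = 0.226 ms by default; gradients are
accepted in G/cm (×0.01 to T/m), γ defaults to ¹H. The two-parameter fit
is initialized from the log-linear slope and, on noiseless data, equals it
exactly (asserted).

*Dose-response.* Four-parameter logistic on log10 concentration with free
bottom (activity is normalized to a reference condition but the floor is
not pinned). The EC50 CI95 is profile-likelihood (F-based), because the
EC50 sampling distribution is strongly asymmetric on the linear scale;
coverage is verified at 95 ± 2% over 100 seeded replicates. Curve
comparison uses the extra sum-of-squares F-test between separate-curves
and one-shared-curve fits.

*Melting.* The ellipticity series must be on a uniform temperature grid;
it is smoothed and differentiated with an 11-point cubic Savitzky–Golay
filter and T_m is the interior extremum of |dθ/dT| refined by local
quadratic interpolation, so the estimate is not quantized to the grid. A
prominence check (interior extremum must exceed the boundary derivative)
rejects transition-free baselines.

*Dimer exchange.* The titration signal is modeled as the fraction of a
trace-labeled protomer residing in dimers under mass action 2M ⇌ D with
K_D = [M]²/[D] and equal homo-/heterodimer affinity, scaled between free
and bound plateaus. The instrument-specific functional form of exchange
measurements is not published in general; this quadratic mass-action model
is the minimal thermodynamically consistent choice, and protomer
conservation holds to 1e-10 at every point (asserted).

## Synthetic generators

Every generator is a pure function of (spec, seed) and emits a ground
truth record sufficient for all downstream assertions.

*Planted dimer ensembles* use two mirrored zig-zag chains (30 residues by
default, four heavy atoms each in a small rigid tetrahedron) separated by
5.6 Å, touching only at six interface columns whose residues carry an
extra atom reaching toward the opposite chain. By construction the contact
graph is two intra-chain "rails" (i ↔ i+2) plus one cross-chain contact
per interface column. Per-frame displacements are rigid per residue:
planted-path residues share a collective Gaussian displacement plus small
individual jitter (nominal distance CV 0.02 at the 4 Å rail distance),
all other residues move independently with larger amplitude (CV 0.065,
contrast 3.25×). The generator measures all rest-state heavy-atom
distances and rejects geometries that land in the ambiguous band around
the 4.5 Å cutoff, so the planted contact set and occupancies are
unambiguous. Because the crossing is planted at the interface column
nearest the path's end columns, any alternative route must spend at least
two extra rail hops plus a high-CV crossing, making the planted path the
strict minimum at any contrast > 1. The emitted expected weight is the
first-order value Σ 2σ²/d over path edges.

These ensembles emulate the *statistical structure* the network stage
consumes — occupancy-stable contacts with controlled distance CVs — not
protein physics: there is no excluded volume, no secondary structure, no
anharmonicity, and all fluctuations are Gaussian and frame-independent.
Passing the recovery tests therefore demonstrates that the pipeline
recovers a known minimum-weight path and cross-chain contact set under
realistic noise, not that any particular biological pathway is correct.
The headline trajectory-scale results (a seven-edge interprotomer critical
set, a nine-residue inter-site path of weight 0.27) require microsecond
MD ensembles and are out of desk-scale scope; the acceptance suite
substitutes exhaustive-enumeration oracles on small graphs plus the
planted-recovery study (20 seeds, 2000 frames, ≥ 19/20 required).

*Elastic-network ensembles* draw Gaussian frames from kT·H⁺ of a Hookean
(anisotropic) Hessian and emit analytic marginal variances; disconnected
networks (> 6 null modes) are rejected as infinite-variance.

*ΔΔG tables* plant every row to either pass all screen criteria with
≥ 0.5 kcal/mol margin or violate exactly one named criterion, so the
expected survivor set and first-failure annotations are known exactly.

*Curves* evaluate the closed-form measurement models on their standard
grids (the diffusion decay uses the 40-point 3.6–32.5 G/cm gradient grid
with δ/2 = 4.3 ms, Δ = 70 ms, τ = 0.226 ms) with stated noise models:
multiplicative Gaussian for the decay, additive Gaussian elsewhere.
Default planted parameter values are the study conditions of the
engineered-variant characterization (EC50 8.4/13.7/5.9 μM, T_m 67.8 and
70.5 °C, K_D 0.06 and 1.88 μM, D = 1.0e-10 m²/s).

## Problem sizes and reporting

The acceptance script (`scripts/acceptance.py`) uses 20 planted ensembles
of 2000 frames each, 50 noisy diffusion series, pooled triplicate
dose-response series per variant (mirroring a triplicate assay design),
100 replicates for CI coverage, and 20 titrations per dissociation
constant; dissociation constants and the diffusion bias are reported as
means over replicates because the single-series estimator's standard error
(≈ 5% for the tight-dimer K_D) is itself of the order of the tolerance of
interest.

## Known limitations

- The crystal-structure comparison tests require the deposited PDB entries
  to be present locally; no coordinate data ships with the package.
- Contact occupancy is computed per frame with a KD-tree; extremely large
  ensembles should be strided first (`load_ensemble(stride=...)`).
- The SASA local-frame construction assumes a generically shaped molecule;
  for exactly symmetric synthetic point clouds rotational equivariance
  holds only to sampling error.
- The exchange model assumes equal homo-/heterodimer affinity and a
  trace-labeled population; strongly unequal affinities need a different
  binding polynomial.
- No periodic-boundary handling: ensembles are assumed unwrapped,
  protein-only.
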