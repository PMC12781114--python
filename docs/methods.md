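# Methods

`nqogate` analyzes conformational gating in loop-gated flavoenzymes of the
NADH:quinone oxidoreductase (NQO) type, where a flexible loop plus an
extended domain act as a gate over the active site, and connects the
structural picture to steady-state and rapid-reaction kinetics.  Because
curated trajectory data for such systems is rarely distributable, the
package ships a synthetic-data layer that generates ensembles and kinetic
datasets with the statistical structure the analyses assume; every
analysis stage is validated by property-based tests and by parameter
recovery against the generators.

## Synthetic gate ensembles

`synthetic.simulate_gate_ensemble` emulates a protein whose gate distance
(the separation between two marker alpha-carbons, one on the mobile loop
and one on the facing domain) switches between a closed and an open
conformation:

* a hidden two-state Markov chain with per-frame transition probabilities
  `p_closed_to_open`, `p_open_to_closed` (defaults 0.02, giving dwell
  times of ~50 frames and a stationary occupancy of 1/2 for the symmetric
  chain);
* a gate distance drawn per frame from a Gaussian with the current
  state's mean and a shared fluctuation width.  Defaults encode the
  study conditions of the NQO system: closed 11.6 A, open 21.0 A (the
  wild-type and open-mutant gate separations), fluctuation 1.4 A;
* a toy topology — a linear chain of 40 residues at 3.8 A alpha-carbon
  spacing, each with 1 Calpha plus up to 3 pseudo-heavy side atoms —
  with the second gate residue placed rigidly along the gate axis so the
  drawn distance is realized exactly, and all non-gate residues jittered
  independently (isotropic Gaussian, the same width).

What this emulates well: two-state distance distributions and their
summary statistics, occupancy kinetics, contact making/breaking at a
moving interface, and a dominant collective mode riding on thermal noise.
What it deliberately does not emulate: force-field physics, correlated
backbone motions (the jitter is independent per residue, so PCA modes
beyond the gate mode are isotropic), secondary structure, solvent, or
periodic-boundary imaging.  Passing tests therefore demonstrate that the
*analysis machinery* is correct — superposition, covariance, contact
counting, community detection, fitting — not that any force field is
reproduced.

Randomness: each generator spawns independent child streams from its seed
in a fixed documented order (ensemble: states, distances, jitter; rates:
one stream per replicate; traces: one stream per concentration), so
enlarging a design appends new draws without perturbing earlier ones, and
identical spec + seed is bit-reproducible.

## Synthetic kinetics

Initial rates are forward evaluations of the ping-pong bi-bi law
(`v0/e = A B kcat / (A Kb + B Ka + A B)`, with the `Kb A` term scaled by
`(1 + A/Kis)` when NADH substrate inhibition is active) on a full
(NADH x CoQ0) grid, replicated, with multiplicative Gaussian noise of
relative SD `noise_cv`.  The default grids span 30-100 uM NADH with
30-150 uM CoQ0 (wild-type-like design) or 10-100 uM NADH with 2-10 uM
CoQ0 (mutant-like design); stopped-flow traces use NADH from 90 to
500 uM.

The default `noise_cv = 0.01` (1% CV) is anchored to the precision of
published steady-state parameter tables for this system: a
Fisher-information (Cramer-Rao) calculation at the wild-type parameter
set over the wild-type grid shows that standard errors of the published
scale (about +/-1 on kcat ~ 11 s^-1, +/-6 on K_CoQ0 ~ 35 uM, +/-0.1 on
Kis ~ 1.1 uM) are achievable only if the effective rate noise is near 1%;
at 5% the information bound already exceeds those errors several-fold.
Since no instrument noise figure is available, matching the evident
precision of the published fits is the least-assumptive calibration.

Stopped-flow traces are double exponentials
`A(t) = B1 e^(-kobs1 t) + B2 e^(-kobs2 t) + C` with
`kobs1 = kred S/(Kd + S)`, a substrate-independent slow rate `kobs2`
(default 0.1 s^-1) carrying a small amplitude fraction (default 0.08,
constrained below 0.1 — the slow phase is a minor spectral component,
under 10% of the absorbance change), additive Gaussian noise (default
0.002 AU, an assumption at a typical instrument scale), and 400
log-spaced time points from 1 ms to `5/min(kobs1, kobs2)`.  The time
base extends beyond five fast-phase lifetimes whenever the slow phase is
slower, so both phases are resolvable by the biexponential fit —
log-spaced sampling mirrors stopped-flow acquisition.

## Trajectory operations

Coordinates are Angstrom throughout (PDB convention); residue identity is
the pair (chain id, residue index) so multi-chain topologies cannot
collide.  The PDB reader is strict: malformed ATOM/HETATM records and
missing coordinates raise a parse error naming the line, never silent
NaNs.  DCD and XYZ I/O go through mdtraj (DCD endianness auto-detected;
note the DCD header embeds a creation timestamp, so byte-level checksums
of otherwise identical trajectories differ while the coordinate payload
is bit-identical).  Superposition is the Kabsch SVD solution with a
determinant correction for proper rotations; collinear or coincident
selections are rejected.  The rotation is computed on the selected atoms
but applied to the whole frame, so contacts and distances downstream
share one frame of reference.  The selection mini-language (documented in
the README) covers atom-name lists, residue ranges, element filters and
boolean combinations.

## Ensemble PCA

The covariance is fitted over the POOLED frames of all supplied systems,
each frame superposed to one common reference (default: the first frame
of the first trajectory).  Pooling makes components comparable across
systems so their projections can be overlaid; a per-system fit is
available by passing a single trajectory.  Numerical conventions:
mass-unweighted Cartesian covariance, population (1/N) normalization,
eigenvalues clipped at zero and sorted descending, and each eigenvector's
largest-magnitude entry made positive for reproducible projections.
Densities are normalized 2D histograms on a grid shared across systems
(pooled range padded 5%), Gaussian-smoothed with a Scott-rule bandwidth
by default; the mode bin resolves ties to the lowest flat index.  The
most probable conformation is the frame nearest the 2D mode in PC space;
a 1D marginal variant (`most_probable_frame_1d`) is provided for the
per-component question, since marginal and joint modes can differ for
correlated scores.

## Contacts and difference networks

A residue pair is in contact in a frame when any of their heavy
(non-hydrogen) atoms are within 4.5 A (inclusive boundary) and the pair
is at least 3 positions apart in sequence; cross-chain pairs always pass
the separation filter.  The fast kernel uses a k-d tree neighbor search
and is tested for exact set equality against an all-pairs brute-force
reference on random structures.  Contact probability is the per-pair mean
of frame indicators, hence in [0, 1]; the difference network
`df = P(system B) - P(system A)` is antisymmetric under swapping systems,
with df > 0 a formed contact, df < 0 a broken one, and exactly 0 neither.

Communities: per trajectory block, residues are nodes and pairs with
occupancy >= 0.7 (configurable) are edges weighted by occupancy;
partitions maximize modularity (greedy CNM, deterministic).  The
consensus across blocks thresholds the co-classification fraction at
majority (> 1/2) and re-partitions that graph; per-residue stability is
the mean co-classification with consensus-community peers.  Residues with
no stable contact in any block are flagged singletons.  Any
modularity-based method satisfies the qualitative definition of
communities as densely connected residues through stable contacts; the
greedy algorithm was chosen for determinism and availability.  Community
interface values sum signed pair df, and interfaces plus interiors
conserve the total df exactly.

## Kinetic fitting

All fitters share one core: unweighted nonlinear least squares (a
relative, 1/v-weighted option is exposed — the consistent choice when
rate errors scale with signal, as with the generator's CV noise) over
log-transformed positive parameters, so positivity needs no active
bounds; multistart initialization from data-driven heuristics (rate
ceiling for kcat, concentration medians for the K's, half-life and
log-linear tail analysis for the exponential rates) with seeded
log-normal jitter; Levenberg-Marquardt with 1e-12 tolerances.  Standard
errors come from the delta method on the log-scale covariance, computed
with a pseudo-inverse of J^T J so that unidentifiable directions report
honest, very large (or infinite) uncertainties instead of failing — the
wild-type K_NADH under strong substrate inhibition is the canonical case.
R^2 is always reported on the natural scale.

Biexponential fits relabel phases so kobs1 >= kobs2 and flag rate ratios
below 1.5 as indistinguishable.  Saturation fits (`kobs = kred S/(Kd+S)`,
zero intercept) flag Kd estimates more than a decade outside the sampled
concentration range as unconstrained: far above max(S) the data are
linear in S, far below min(S) the enzyme is saturated everywhere and the
data only bound Kd from above.

Model selection between the plain and substrate-inhibition laws prefers
the richer model only when BOTH the corrected Akaike criterion favors it
AND the extra-sum-of-squares F-test rejects the simpler model at
alpha = 0.05.  AICc alone admits one boundary-constrained extra parameter
by chance in roughly 6% of realizations (half of P(chi2_1 > ~2.3), the
parameter sitting at its Kis -> infinity boundary under the null); the
combined rule holds that false-positive rate near 2% while leaving power
against genuine inhibition essentially untouched, since a real Kis of the
published magnitude produces overwhelming F statistics.

Derived quantities: catalytic efficiency kcat/K with uM -> M conversion
and first-order error propagation; fold changes as max/min ratios with
the direction read from the ordering.

## Known limitations and degenerate regimes

* The wild-type steady-state design (NADH far above Kis) identifies kcat,
  K_CoQ0 and Kis only weakly and K_NADH not at all; in a few percent of
  noise realizations the least-squares optimum collapses onto the
  boundary ridge Ka -> 0 or (Kb, Kis) -> 0 at fixed ratio, where Wald
  standard errors are not meaningful.  The acceptance machinery
  summarizes recoveries by the median over independent datasets for this
  reason.
* Gate statistics use the population SD; at thousands of frames the
  sample/population distinction is far below reporting precision.
  Equilibration trimming is the caller's responsibility
  (`trajectory.trim_equilibration`) so the statistics are transparent
  about which frames they describe.
* The linear toy chain cannot form long-range tertiary contacts away from
  the gate, so community analyses on generated ensembles are dominated by
  flagged singletons plus the gate-interface community; planted-partition
  matrices are used to exercise the community code properly.
* Whether reported spreads on gate distances are SDs or SEMs is treated
  as SD; whether published kinetic uncertainties are fit SEs or replicate
  SDs is treated as fit SEs.

## Problem sizes

Tests and the acceptance script run at sizes chosen to make Monte-Carlo
error bars small relative to the tolerances they check: ensembles of
150-4000 frames (50,000 for Markov-chain convergence checks), 40-residue
chains, rate tables of 90 points (30 grid points x 3 replicates),
stopped-flow sets of 5 traces x 400 points, 200 replicates per
model-selection arm, and recovery summaries as medians over 15
independent datasets.
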