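# Methods

This note records the models implemented in `noeme`, the conventions
and defaults chosen where the design was open, and what the synthetic
experiments do and do not demonstrate.

## NOE forward model and units

The forward model is the isolated-spin-pair approximation
f(d) = 1/d⁶, valid when conformational exchange is slow compared with
molecular tumbling; spin diffusion and full relaxation-matrix treatment
are out of scope.  Signals are carried in nm⁻⁶ throughout so the error
scale σ of the reweighting step (default 0.5 nm⁻⁶) applies without
conversion; restraint files and coordinates use Ångström and are
converted on load.  Signal classes map to maximum distances strong
= 3.6 Å, medium = 5.0 Å, weak/long = 6.5 Å; a maximum distance becomes
the lower threshold f_exp = d_exp⁻⁶ on the weighted ensemble average.
Minimum-distance columns in restraint tables are parsed and discarded
(with a log message): a lower distance bound cannot be imposed on an
ensemble average of 1/d⁶ without a model of the signal ceiling, and the
protocol does not use them.  A per-restraint violation is a relative
signal ⟨f⟩/f_exp strictly below 1; the default aggregate score sums the
shortfalls Σ max(0, 1 − ratio).  This aggregate is this package's own
definition (recorded in report metadata as `shortfall`); a count-based
mode is available.

## Maximum-entropy reweighting

Weights take the exponential-family form
w_t ∝ prior_t · exp(−Σ_i λ_i f_{i,t}) with λ_i ≤ 0, found by minimizing
the convex dual Γ(λ) = ln Σ_t prior_t e^{−λ·f_t} + λ·f_exp + σ²|λ|²/2
with L-BFGS-B under the sign bound, starting from λ = 0 with the
analytic gradient f_exp − ⟨f⟩_λ + σ²λ.  Two numerical choices matter:

- **Threshold scaling.** The dual is solved on signal ratios f/f_exp
  with μ_i = λ_i·f_exp_i.  Raw NOE signals span orders of magnitude in
  nm⁻⁶ (a 2.5 Å contact is ≈ 4000 nm⁻⁶, a 6.5 Å one ≈ 13 nm⁻⁶), which
  leaves the unscaled dual too ill-conditioned for reliable line
  searches; the scaled problem is equivalent term by term.
- **Convergence** is declared on the projected gradient in these
  relative units (default tolerance 1e-8): free multipliers need
  |∂Γ/∂μ| below tolerance, multipliers at the bound need ∂Γ/∂μ ≤ 0.

At the optimum an active restraint satisfies ⟨f_i⟩ = f_exp,i + σ²λ_i —
with σ > 0 active averages sit slightly *below* threshold, by exactly
the Gaussian error allowance; σ = 0 gives hard inequalities.  With
σ = 0 and an infeasible threshold the multiplier diverges; this is
reported as `converged=False` with diagnostics rather than raised,
since partial results (which restraint diverged) are the useful output.
Statistical efficiency is the normalized Kish size s = ⟨w⟩²/⟨w²⟩ ∈
(0, 1]; `kish_trace` recomputes it on growing snapshot prefixes, the
monitoring signal for deciding whether a simulation has sampled enough.

## Glycosidic classification and eRMSD

χ is the standard torsion O4′–C1′–N9–C4 (purines) / O4′–C1′–N1–C2
(pyrimidines), reported in [0, 360) so that the syn window is the open
interval 0 < χ < 115°; high-anti (~270–300°) then lands on the anti
side without wraparound cases.  A snapshot's χ conformation is the
bitstring with bit r = 1 iff residue r is syn.

The eRMSD compares base arrangements, not superposed coordinates.  Each
base carries a frame at the centroid of C2/C4/C6: x̂ toward C2, ẑ the
ring normal, ŷ completing the frame.  The ring traversal C2→C4→C6 runs
in opposite senses relative to the base faces in purines and
pyrimidines, so purines use the order (C2, C6, C4), keeping +ẑ on the
same chemical face for all bases.  The position of base j in frame i is
scaled anisotropically (x/5, y/5, z/3 in Å — one scaled unit ≈ "close
enough to interact" in any direction) and mapped to the smooth 4-vector

    G(r̃) = [ sin(γρ)·r̃/(γρ) , (1 + cos(γρ))/γ ],  γ = π/2.4,  ρ = |r̃|,

zero for ρ ≥ 2.4 (G is continuous there).  The eRMSD of two structures
is √(Σ_{i≠j} |G_A − G_B|² / N).  Because each structure maps to a fixed
embedding vector, the eRMSD is a Euclidean distance divided by √N —
hence a true metric; the motif search depends on its triangle
inequality, and the test suite checks the axioms and an independently
coded scalar implementation to 1e-8.  Cutoffs are used as published
alongside this definition: 0.7 for "same base-contact map" clustering,
1.0 for motif similarity.  Modified nucleotides are rejected with a
clear error; only unmodified A/G/C/U (common naming dialects) are
classified.

## Clustering

Stage one partitions snapshots by exact bitstring equality, so no
cluster can mix different syn/anti patterns — this prevents cluster
averages of d⁻⁶ signals from being dominated by a few syn outliers.
Stage two builds, per pre-cluster, the neighbor graph with edges at
eRMSD strictly below the cutoff and repeatedly removes the clique of
maximum total snapshot weight.  The clique search is an exact
branch-and-bound (bound: current weight plus remaining candidate
weight); among equal-weight cliques the lexicographically smallest
sorted member set wins, which makes extraction deterministic under
uniform weights.  A greedy fallback exists for very large graphs
(`exact=False`, recorded by the caller).  Pre-clusters whose members
all carry zero weight after reweighting are emitted as singletons with
zero population.  Clusters are numbered 1-based by descending
population P_c = Σ_{t∈c} w_t.  Per-cluster signal summaries are the
weighted average ⟨f_i⟩_wc and the weighted median — defined as the
largest signal value v such that the relative weight of {signals ≤ v}
is strictly below 0.5, falling back to the smallest value when even it
carries half the mass; comparing average and median flags clusters
whose average is carried by single extreme snapshots.

## Minimal cluster sets

Clusters with population above a floor (default 0.002) enter the
search.  For growing Y, every Y-subset of clusters and every weight
vector on the grid {multiples of step 0.01, each ≥ 0.01, summing to 1}
is tested against all thresholds; the search stops at the first Y with
a feasible combination and returns all of them.  Since full enumeration
over, say, C(69, 4) subsets times C(99, 3) grid points is intractable,
the default mode first solves a linear feasibility problem per subset
(HiGHS; weights on the simplex with lower bound = step) and enumerates
the grid only inside LP-feasible subsets.  Every grid point lies inside
the LP polytope, so the two modes are provably identical; the suite
verifies this on random instances.  Feasibility uses a relative
tolerance of 1e-12 to absorb floating-point noise at the boundary.
Feasible sets are ranked by D_KL(w′‖P) = Σ w′_y ln(w′_y/P_y) with the
populations entering **raw** (not renormalized over the set), matching
the printed formula of the protocol; a renormalized variant is
available via a flag for sensitivity analysis.  One consequence worth
knowing: with raw populations the KL minimum over a set sits at
w′ ∝ P, so the best composition can differ slightly from the planted
mixture when the selected clusters' populations do not sum to 1.

## Motif search

The query is a contiguous fragment window (for the hairpin system, the
nine central loop residues 11–19).  The centroid snapshot (minimum mean
squared eRMSD to all others) is scanned against every connected window
of every chain and model in the library at radius
cutoff + max_t eRMSD(centroid, t); the triangle inequality guarantees
this prefilter loses no window that any ensemble member matches below
the cutoff (verified against an exhaustive all-pairs scan).  Candidates
are refined per snapshot (strict < 1.0), restricted to the query's
exact bitstring, and windows with any consecutive O3′–P distance above
2.0 Å are discarded (covalent O3′–P ≈ 1.6 Å plus slack; the protocol
checks connectivity without stating a cutoff).  Multi-model library
entries contribute each model as a separate searchable structure, and
χ matching is evaluated per model.  Outputs are canonically sorted so
results do not depend on library file order.

## Synthetic fixtures: what they emulate and what they do not

The generator builds an RNA-like chain of idealized nucleotides
containing exactly the atoms the implemented metrics touch: the base
six-ring (plus N9/C8/N7 and H8 for purines, H6 for pyrimidines),
C1′/O4′/H1′ on the sugar side, and the O3′/P backbone pair.  Residues
sit on a tight helix (radius 4 Å, twist 60°, rise 2.2 Å) chosen so that
neighboring bases fall well inside the eRMSD interaction shell; sugar
pucker, full ribose geometry and base pairing are not modeled.  A
sub-state is imposed by rigidly rotating each base about its glycosidic
bond to a target χ (syn 60°, anti 200°, jitter ±2°, kept ≥ 12° from the
115° boundary), plus optional smooth per-state backbone deformation;
P(i+1) is placed 1.6 Å from O3′(i) by construction so connectivity
always holds.  Within-state Gaussian coordinate noise defaults to
0.03 Å.  Snapshot counts follow the planted populations by
largest-remainder apportionment, so the realized mixture matches the
plant as closely as T allows; all randomness flows from one seeded
generator and identical seeds give bit-identical fixtures.  After
generation the planted partition is verified on the eRMSD matrix
(within-state < 0.7, between-state > 0.7) and regenerated from a
derived sub-seed on failure (≤ 10 attempts).

Two properties of the toy system deserve emphasis.  First, a state
differing from another by a *single* glycosidic flip sits near the 0.7
eRMSD boundary (the metric averages over all base pairs, so one flipped
base on a 7–9-mer contributes ≈ 0.4–0.7 depending on position); the
bundled experiments therefore use states differing at two or more
non-terminal residues, which separate structurally rather than by luck.
Second, population recovery by inequality-restrained maximum entropy is
only as good as the within-state signal spread: because f = d⁻⁶, even
small coordinate noise produces a broad signal distribution that lets
the reweighting satisfy a bound by up-weighting extreme snapshots
*within* a state instead of shifting mass *between* states.  With the
defaults (noise 0.03 Å, χ jitter 2°, states differing at two residues,
thresholds at the exact mixture average) recovery of a 60/40 plant from
a 4:1-biased prior is accurate to ≈ 0.01; at 0.08 Å noise the same
experiment is off by ≈ 0.2.  Real ensembles are noisier than the toy in
this sense — so passing the recovery test shows the machinery is
correct under identifiable conditions, not that any real system's
populations are recoverable to ±0.05.

The restraint generator sets each pair's threshold to the planted
mixture average deflated by a slack fraction, guaranteeing the plant is
feasible; `classes="snap"` quantizes the distances to the 3.6/5.0/6.5 Å
classes as real restraint lists quote them (which breaks the exact
feasibility guarantee, as in reality).  The motif-library generator
embeds donor fragments at a chain position congruent to the query start
modulo the sequence cycle, so the purine/pyrimidine phase of the
planted window matches the query's.

## Deposited-entry analysis

For the 29-nt hairpin system the package bundles the critical-NOE panel
(23 proton pairs with classes, in 1-based hairpin numbering; a constant
offset of 63 maps to the deposited entry's author numbering, residue
16 → 79).  Given the deposited 10-model bundle, the tool splits it on
χ₁₆ (≈ 100° vs ≈ 40°, both syn), computes relative signals per subset
and counts violations — the workflow shown in
`examples/deposited_violations.py`.  The sub-state boundary between the
two syn conformers is not part of any published definition; the tool
exposes raw χ values and the examples use a ±15° window around 100°.

## Problem sizes

The bundled experiments run at desk scale by design: ensembles of
120–200 snapshots of 7–9 residues, 9–13 restraints, libraries of six
chains.  At these sizes the full suite and the acceptance script each
complete in well under a minute of CPU; the algorithms themselves
(embedding-based eRMSD matrices, LP-prefiltered parsimony search,
branch-and-bound cliques per pre-cluster) are the same ones that apply
at production scale.
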