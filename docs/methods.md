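# Methods

This note records the model, the numerical choices, and what the
synthetic test suite does and does not establish.

## Scoring model

A representation R maps every topology segment to beads of a fixed
number of contiguous residues; remainder residues at a segment end form
a smaller final bead, so bead size never exceeds the nominal
residues-per-bead. Bead radii conserve volume,
r = (3 n V_res / 4π)^(1/3) with V_res = 130 Å³ per residue. Structured
segments sharing a rigid-body id move as one unit with 6 degrees of
freedom; every other bead has 3, giving the 3n + 6m bound on free
parameters that guides the live-point count.

Three restraint families score a model:

- **Stereochemistry** (prior): quadratic soft walls on chain
  connectivity (consecutive beads within `slack` = 2 Å of touching) and
  excluded volume (non-bonded beads must not overlap), force constants
  k = 1 Å⁻². Pairs inside one rigid body are fixed by construction and
  skipped. The prior is truncated to a cubic box (half-side 300 Å) so
  its mass is proper.
- **Crosslinks**: per link, log[ψ + (1 − 2ψ)·S(d)] with
  S(d) = ½(1 − erf((d − d0)/(σ√2))), d the *bead-surface* distance
  (centre distance minus radii, floored at 0), d0 the linker length
  (DSS/BS3 default 21 Å), ψ = 0.05 the false-positive weight and
  σ = 10 Å the structural uncertainty. σ and ψ are fixed, not sampled:
  sampling nuisance parameters would make evidences incomparable
  across representations. Surface distance keeps big beads from being
  penalised merely for their size; it is also why coarse models
  satisfy intra-chain links easily (see Limitations).
- **EM density**: the data map is a Gaussian mixture; the model GMM
  places one isotropic component per bead (mean = centre, variance =
  radius², weight ∝ residue count). The score is w_em·log(cc) with cc
  the normalised Gaussian overlap ⟨f,g⟩/(‖f‖‖g‖), evaluated by
  closed-form Gaussian product integrals, clamped to [1e-12, 1];
  w_em = 1.

**Posterior repartitioning.** Nested sampling is accurate only when the
prior resembles the posterior, so a seeded random subset (default
fraction 0.3) of the crosslinks is moved from the likelihood into the
sampling prior alongside stereochemistry. The product π·L — and hence
the posterior — is invariant to the split (asserted to 1e-9 in the
tests); the evidence estimated is the likelihood of the *remaining*
restraints averaged over the modified prior, which is what makes the
estimate partition-dependent in absolute value while trends across
representations are conserved.

## Sampling

Replica-exchange Metropolis MCMC on the modified prior: one mover per
flexible bead (uniform-ball translation, step 4 Å) and per rigid body
(4 Å translation plus a ≤ 0.2 rad rotation about the body centroid).
Defaults: 4 replicas on a geometric ladder up to T = 2.5, swap attempts
every 10 steps, cold-replica snapshots every 10 steps. Replacement
draws for nested sampling start a fresh segment from a random live
point with a half-batch burn-in, so successive replacements are only
approximately independent — an accepted approximation, shared with the
batch-resampling design this implements. Per-step time is monotonic
wall clock over a segment divided by total steps across replicas.

## Nested sampling

N live points are initialised by short MCMC segments from random
chain-walk starts (structured beads sit at reference-CA centroids when
a PDB is given). Each iteration replaces the worst live point with a
constrained draw at log L ≥ log L\* (non-strict, so flat likelihoods
are handled; for continuous scores the distinction has measure zero)
and books the dead point against the deterministic shrinkage
X_i = exp(−i/N). Evidence uses trapezoid weights
ΔX_i = ½(X_{i−1} − X_{i+1}) with boundary weight
ΔX_1 = 1 − ½(X_1 + X_2) and remainder mass X_final = ½(X_k + X_{k+1}),
so ΣΔX + X_final = 1 exactly for any iteration count (a rectangle rule
is available); the surviving live points contribute the standard
remainder term mean(L_live)·X_final — without it, plateau-terminated
runs understate Z. Termination: 4 consecutive failed constrained-
sampling batches, or 20 consecutive plateau iterations
(L_{i+1}/L_i < X_i/X_{i+1}, i.e. log-growth < 1/N, strict), or an
iteration cap (default 10 000, set high so the first two fire).
Runs that find no finite-likelihood start raise a relaunch signal; the
workflow relaunches them with fresh deterministic seeds (per-run seed =
SeedSequence(master, crc32(scheme label), run index, attempt)), which
also makes results independent of the thread count.

Defaults follow the recommended operating point: 5 runs per
representation, 50 live points, 50 MCMC steps per batch. The analytic
toy (uniform prior on [−5, 5], standard-normal likelihood,
log Z = log[(Φ(5) − Φ(−5))/10]) is recovered within three standard
errors of 20 runs at N = 100, and the run-to-run error shrinks from
N = 25 to N = 100 as expected.

## Selection rule

Per representation: mean log Z, its standard error over runs
(sample SD/√n), and mean per-step time. The top-evidence group grows
from the best mean by ±1·sem interval overlap taken to transitive
closure; within the group, schemes within 3× the group's fastest
per-step time are optimal. Both the sem multiplier and the fold are
configurable; ties are reported as sets ordered by evidence then time,
because more than one representation can be optimal.

## Synthetic data

Chains are self-avoiding walks with exact 3.8 Å CA steps and a 2 Å
hard-sphere floor; a compactness parameter in [0, 1] biases steps
toward the running centroid (0 → coil, 1 → globule). Crosslinks are
drawn from reference CA pairs within d_max (true positives) or beyond
it (decoys, fraction fp_rate), excluding sequence separations < 5;
ground truth uses CA distances so it is representation-independent.
Densities are k-means partitions of the reference CAs, one Gaussian per
group with covariance = group scatter + blur²·I, blur 4.25 Å (≈ a 10 Å
map). Three fixed-seed presets define the study conditions: *extended*
(one 100-residue coil, 30 links, 10 components), *globular* (two
compact 60-residue chains, half of each rigid, 40 links, 8 components),
*mixed* (one compact + one extended 80-residue chain, 60 links,
fp 0.1, 10 components).

What these fixtures do not emulate: crosslinker chemistry and solvent
accessibility, ambiguous links between chain copies, voxel maps, and —
importantly — large rigid scaffolds threaded by disordered regions.
Passing tests therefore demonstrate the correctness and calibration of
the evidence machinery, not field realism of any particular ranking.

## Known limitations

- With the fixed-parameter sigmoid crosslink score on surface
  distances, every representation shares the same per-link likelihood
  ceiling, and a very coarse model of an *isolated* chain satisfies all
  of its links essentially everywhere in the prior. Its likelihood is
  then nearly flat at the ceiling, so the evidence of the coarsest
  scheme approaches the global maximum and finer schemes — which pay
  the full prior-concentration cost to reach the same ceiling — cannot
  out-rank it on these fixtures. Observing the opposite direction for
  extended systems requires forward models whose ceiling itself
  degrades with coarse-graining (e.g. a representation-dependent σ, or
  per-component EM likelihoods) and data that conflate residues of one
  coarse bead toward distant anchors; both are outside this package's
  deliberately simple restraint suite. The efficiency half of the
  trade-off (finer ⇒ more pair terms ⇒ larger per-step time) is
  reproduced robustly.
- Absolute evidences are partition-dependent (the modified prior's
  normaliser is not computed); only within-partition comparisons across
  representations are meaningful, and rankings of nearly-tied schemes
  can flip between partitions.
- "Independent" replacements come from finite MCMC segments; heavily
  multimodal priors would need longer batches or more replicas than the
  defaults.
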