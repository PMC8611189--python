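# Methods

## The parcellation model

Resting-state BOLD dynamics of neighboring voxels are strongly dependent, so
a voxelwise network analysis is both redundant and statistically fragile.
This package performs *functional parcellation*: it partitions an in-mask
voxel lattice into spatially contiguous modules whose member voxels share
similar dynamics, so that each module can later be reduced to a single
neural node (its mean time series).

The algorithm alternates two moves until the modular structure stabilizes:

1. **Split.** For each current module with voxel set $S$, the regional
   functional-connectivity matrix $R \in [-1,1]^{|S|\times|S|}$ of Pearson
   correlations between member voxel time series is submitted to Louvain
   community detection, maximizing the resolution-parametrized modularity

   $$Q = \frac{1}{2m}\sum_{ij}\Bigl[A_{ij} - \gamma\frac{k_ik_j}{2m}\Bigr]\,
   \delta(c_i,c_j),$$

   with $A$ the (nonnegative) edge weights, $k_i$ node strength, $m$ half
   the total weight and $\gamma$ the resolution factor. Larger $\gamma$
   inflates the null term and yields finer communities. Sub-communities
   that are not 26-connected in space are further separated into their
   connected components: only neighboring voxels may share a module.

2. **Unify.** Each module $u$ is summarized by its *global FC profile*
   $r_{u\cdot}$, the vector of correlations between its mean time series
   and every other module's mean. For each pair of 26-adjacent modules the
   similarity index

   $$d(u,v) = \sqrt{\frac{\sum_{k\notin\{u,v\}} n_k\,(r_{uk}-r_{vk})^2}
   {\sum_{k\notin\{u,v\}} n_k}}$$

   is the voxel-count-weighted RMS difference of the two profiles over all
   shared reference modules. Pairs with $d$ below a threshold (default
   0.05) are merged, greedily in ascending $d$ after a seeded permutation
   of module order, each module joining at most one merge per cycle (chains
   coalesce over subsequent iterations). Two modules whose mean signals
   correlate strongly but whose whole-volume profiles disagree are *not*
   merged — differentiability against the rest of the volume is the
   criterion, not local correlation.

At the start of every iteration, fragments smaller than `min_module_size`
(default 10 voxels) are absorbed into the 26-adjacent neighbor whose mean
signal correlates best with the fragment mean, when that correlation is at
least `absorb_min_corr` (default 0.50, inclusive). Iteration stops when two
successive parcellations are identical, or when their normalized mutual
information (NMI, arithmetic-mean normalization) exceeds `nmi_stop`
(default 0.95) while the relative module-count change is at most
`count_tolerance` (default 1%); a `max_iterations` guard (default 100)
defends against oscillation.

**Multi-resolution ladder.** Parcellations at several resolutions are
obtained by running an ascending sequence of $\gamma$ values (default 0.65
to 0.95, step 0.05), warm-starting each run from the previous, coarser
result. This is both faster than re-splitting the initial parcellation at a
high resolution and the reason module counts rise along the ladder: the
split stage only refines, while unify and absorb only make local repairs.

**Evaluation.** For a given parcellation, each module's *intra-module CC*
(mean off-diagonal voxel-pair correlation) is compared against its
*inter-module CC* (mean correlation of its mean signal with all other
module means) by a paired one-sample t-test of the per-module differences;
the *grand mean CC* (unweighted mean of intra-module CCs; a size-weighted
variant is available) summarizes homogeneity at one resolution, and paired
t-tests across resolutions use a Bonferroni threshold
$\alpha/\binom{C}{2}$ — 0.05/28 ≈ 0.0018 for 8 conditions (an atlas
baseline plus 7 ladder resolutions). An optional Fisher $z$ transform
(atanh, rejecting $|r| \ge 1$) may precede the tests; on synthetic tables
it does not change the signs of the paired differences. Second-level
community detection on the module-mean correlation matrix regroups modules
into large-scale networks: the resolution is tuned by geometric bisection
until the community count matches a requested target (spatial contiguity is
deliberately not enforced at this level — large-scale networks link distant
regions).

## Numerical and design choices

- **Negative correlations** are clamped to zero before community detection;
  the configuration-model null assumes nonnegative weights. A signed
  modularity mode was considered and rejected: the Louvain backend used
  here optimizes the unsigned objective, and a hand-rolled signed optimizer
  would not be better tested than the clamp convention. Self-correlations
  (the unit diagonal) are removed before modularity computation.
- **Louvain backend and determinism.** Community detection uses the greedy
  Louvain implementation of networkx with the resolution parameter above;
  the visit order and tie-breaks are driven by a seed. All randomness in a
  MOSI run flows from one master seed through a documented splitter keyed
  by (iteration, stage, module), so runs are bit-reproducible and
  independent of execution order. A graph with no positive edges is
  returned as singletons (no connectivity information); the split stage
  skips such modules, leaving them intact.
- **NMI convention.** Normalization by the arithmetic mean of the two
  partition entropies; two identical trivial partitions score 1. Successive
  partitions always cover the same voxel set, so no alignment is needed.
- **Similarity index normalization.** The profile entries of the pair
  itself are excluded ($r_{uu}$ is a self-correlation; $r_{uv}$ appears
  asymmetrically in the two profiles), and reference modules are weighted
  by voxel count. This keeps $d$ on a correlation-difference scale where
  the 0.05 threshold is meaningful. Raw correlations are used (no Fisher
  transform) in the similarity computation.
- **Absorption threshold** is inclusive at 0.50, implemented with a 1e-9
  slack so an exactly-boundary correlation merges despite float rounding.
- **Degenerate inputs.** Constant voxel time series make Pearson
  correlation undefined and are rejected at load time (the NIfTI reader
  drops them from the mask with a logged count). A module whose voxel
  signals cancel exactly has an undefined inter-module CC, reported as NaN
  and excluded from tests.
- **Disjoint mask components** (e.g. hemispheres) are processed
  independently by construction: absorption and unification act only on
  26-adjacent modules, so labels never cross a mask gap. Initial modules
  spanning disconnected voxel sets are split before the first iteration.
- **Run records.** Each CLI command writes its resolved configuration,
  seeds, package version and input digests; timings go to the log stream
  only, so all output files are byte-stable across repeated runs.

## The synthetic generator

Planted volumes emulate the statistical structure that standard resting
fMRI preprocessing produces — band-limited, spatially smooth, locally
homogeneous signal — without modeling hemodynamics:

- Contiguous regions are grown on the lattice by seeded multi-source
  frontier expansion (one voxel per region per round, keeping sizes
  balanced and every region 26-connected).
- Each region is driven by a unit-variance band-limited latent signal
  (white noise Fourier-masked to a passband expressed as fractions of
  Nyquist, default 0.05–0.5, emulating a 0.01–0.1 Hz bandpass at a 2.5 s
  sampling interval); voxel series are `snr * latent + white noise`, so the
  expected within-region correlation is `snr² / (1 + snr²)` (0.8 at the
  default SNR 2) — verified against this closed form in tests.
- Optional Gaussian spatial smoothing (FWHM in lattice units) mixes signal
  across boundaries, raising cross-boundary correlations as real smoothing
  does.
- **Two-level (hierarchical) mode** nests regions inside contiguous network
  territories; a region's latent is
  `sqrt(w)·network + κ·other_network + sqrt(1−w−κ²)·region`. The network
  weight default `w = 0.7` comes from a uniform-block modularity
  calculation: a network of equal regions splits when γ exceeds roughly
  twice its cross-region weight fraction, so `w = 0.7` places the
  network-to-region transition near γ ≈ 0.85–0.9, *inside* the default
  0.65–0.95 ladder; at `w = 0.5` both hierarchy levels fall below γ = 0.65
  and the ladder would probe only one scale. The graded cross-network
  coupling (`κ` up to 0.3, varying per region) gives regions of the same
  network structurally distinct global FC profiles — as real cortical areas
  have — so that unification decisions rest on planted structure rather
  than sampling noise. A `nested_networks=False` variant scatters the
  regions of each network spatially, exercising the second-level claim that
  networks link distant nodes.

What the generator does *not* emulate: hemodynamic response shape,
physiological noise and motion artifacts, spatially varying SNR, and the
continuous multi-scale organization of real cortex (the planted hierarchy
has exactly two scales). Passing recovery tests therefore demonstrate
algorithmic correctness under the stated signal model, not performance on
real data.

## Reference experiments and problem sizes

The test suite and `scripts/acceptance.py` use desk-scale study conditions
chosen so each experiment expresses the property it checks:

- **Recovery:** flat volume, 12×12×6 lattice (864 voxels), 8 planted
  regions, T = 150, SNR = 2; MOSI at γ = 0.8 from a 4-region initial
  parcellation. Recovery NMI against the planted labels is typically
  0.96–0.99.
- **Resolution ladder:** hierarchical volume (3 networks × 4 regions,
  same lattice and SNR), carved from a single whole-volume module along the
  warm-started ladder. Module counts step from the network scale (2–3) to
  the region scale (~12) and the grand mean CC rises in parallel; both are
  non-decreasing at every rung. Starting from one module makes scale
  selection purely split-driven — the unify distance does not depend on γ,
  so a γ-dependent consolidation path would make the count trend depend on
  threshold-marginal merges.
- **Second level:** network recovery on the hierarchical volume's planted
  regions at target count 3.
- **Homogeneity:** per-volume t-test on the recovery result (positive mean
  difference, p far below 10⁻³ at these sizes).

## Known limitations

- Only unsigned modularity; strong anticorrelation structure is invisible
  to the split stage.
- The similarity threshold (0.05) is an absolute correlation-scale
  constant; very short time series inflate profile sampling noise above it
  and will over-segment.
- `partition_to_target_count` assumes community count is monotone in γ,
  which holds only stochastically; it returns the closest achieved count
  with a flag when the exact target is unreachable.
- Anisotropic voxels and surface (vertex) parcellations are out of scope;
  adjacency is purely lattice-topological and the NIfTI affine is never
  interpreted.
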