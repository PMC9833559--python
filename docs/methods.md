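# Methods

This note documents the models, numerical choices and known limitations of
`afmhmm`. Units are nanometres throughout; probabilities and likelihoods
are handled as natural logarithms.

## Pseudo-AFM imaging

A molecule is a rigid set of beads with centres `x_i` and effective radii
`R_i` (for Cα input, one bead per residue; radii come from a configurable
per-residue table with a uniform 0.4 nm default, since published effective
radii vary between instruments and force fields). The tip is a hemisphere
of apex radius `r` blended tangent-continuously into a cone whose flank
makes the half angle θ (default 10°) with the vertical tip axis. Before
imaging, the molecule is rotated about its centroid, dropped so the minimum
bead-centre z is 0 (the stage), and shifted laterally by continuous
offsets (dx, dy).

For a pixel whose centre is at lateral distance `d` from a bead, the tip
first touches that bead at height

* `z − r + sqrt((r+R)² − d²)` when `d ≤ (r+R)·cos θ` (apex, sphere-sphere), or
* `z − r + (R + r − d·cos θ)/sin θ` otherwise (flank, sphere-cone),

and the image height is the maximum over beads, clipped at the stage. The
two regimes join exactly where the cone is tangent to the apex hemisphere;
the unit tests verify the full image against an independent brute-force
construction (grayscale dilation of densely sampled bead surfaces by the
tip profile) to within 0.05 nm.

Pixels are sampled at their centres; x maps to columns and y to rows, with
the coordinate origin at the image centre. The default raster is 80 × 60
pixels at 0.625 nm/pixel. Observed images add i.i.d. Gaussian pixel noise
(default σ = 0.3 nm, a typical HS-AFM noise width).

## Marginalized image likelihood

The full likelihood of an observed image given a posed template is Gaussian
in the pixel residuals with noise standard deviation λ and per-pixel
normalizer (2πλ²)^(−1/2). Because height calibration is unreliable, the
template enters as β·I + dz with unknown scale β and offset dz, and β, dz,
λ are integrated out: β and dz by exact Gaussian integrals, λ by a
saddle-point (Laplace) approximation. The result depends only on the five
pixel sums Co, Cc, Coo, Ccc, Coc and the pixel count N:

    log L = ½·log π + (1 − N/2)·log(2πe)
          + (3/2 − N/2)·log B1 + (N/2 − 2)·log B2,
    B1 = N(Ccc·Coo − Coc²) + 2·Co·Coc·Cc − Ccc·Co² − Coo·Cc²,
    B2 = (N − 2)(N·Ccc − Cc²).

B1 factorizes as S_min·(N·Ccc − Cc²) where S_min is the residual sum of
squares at the optimal (β, dz), and B2 > 0 whenever the template is not
constant. The constant prefactor is the exact Gaussian-integral constant:
with it, the expression agrees with brute-force marginalization (analytic
β, dz integrals plus numerical λ quadrature under a flat prior) up to the λ
saddle-point error, which is a constant ≈ 0.027 nats at N = 36 and O(1/N)
in general; the tests bound the relative log error at 2% on 6×6 images.
Consequences of the marginalization, verified as invariants: adding any
constant to the template leaves the value unchanged, and scaling the
template by a > 0 shifts the log value by exactly −log a (rank-preserving).

Numerical choices: everything is evaluated in log space (at N = 4800 the
bracket exponents are ≈ ±2400, far outside floating-point range if
exponentiated); B1 is floored at 1e−15 × N·Ccc·Coo so that a numerically
perfect template match yields a large finite value rather than +inf
(zero residual corresponds to λ → 0, where the likelihood diverges);
constant (zero-variance) templates are rejected as degenerate rather than
patched, and inside the batched fitting scan such states are assigned −inf
with a logged warning.

## Translation search

Of the five sums only Coc depends on the lateral shift, so the likelihood
is evaluated at every cyclic integer-pixel shift at once via FFT
cross-correlation (circular boundary conditions, matching the
shift-invariance of the other four sums) and the maximum slice is taken —
a max, not a marginalization, so off-target particles elsewhere in a real
field of view cannot bias the score. Ties are broken lexicographically on
(state index, dy, dx), making all outputs deterministic. There is no
sub-pixel refinement: the search resolution is exactly one pixel.

## Hidden Markov extension

The hidden state is s = (structure m, orientation φ) on a fixed orientation
grid; translations are excluded from the state because stage interactions
do not depend on lateral position. Emissions are fixed to the per-frame
marginalized likelihoods (max-translation slice); only the transition
matrix is estimated.

* **Orientation grid.** A deterministic layered Hopf-fibration grid: a
  Fibonacci lattice of n_S² points on the base sphere combined with n_ψ
  evenly spaced fiber angles, n_ψ ≈ n^(1/3) (576 = 72 × 8 by default; the
  reduced-scale tests use 60 = 15 × 4). The grid is bit-reproducible, has
  no duplicate rotations, and its dispersion beats i.i.d. random rotations.
  Published grids can be loaded from plain-text quaternion lists instead.
* **Rotational constraint.** Transitions between states whose quaternion
  distance d = 1 − (q⁽¹⁾·q⁽²⁾)² exceeds 0.1 (≈ 37° rotation) are pinned to
  zero. Because Baum-Welch re-estimates transitions proportionally to
  their current values, zeros are preserved exactly through all iterations.
* **Initial distribution.** p(s₁) is the stationary distribution of the
  current transition matrix (power iteration, tolerance 1e−12), refreshed
  after every Baum-Welch update — the molecule is assumed equilibrated when
  filming starts. Tying p(s₁) to the matrix couples the E and M steps, so
  an update can, very near convergence, lower the evidence by a hair; such
  an update is rejected and the previous model returned, keeping the
  evidence trace non-decreasing.
* **Recursions.** Forward-backward runs entirely in log space. This is not
  cosmetic: with near-deterministic emissions and a constrained matrix,
  the feasible paths' relative weights can be e^(−1000) and below — any
  linear-space scaling underflows them to zero, losing all the evidence.
  Viterbi breaks ties toward the lowest state index. Both recursions are
  verified against explicit path enumeration on small instances.
* **Pruning.** States whose log-likelihood is never within 20 nats of a
  frame's maximum (in any frame, any movie) are dropped before Baum-Welch;
  20 nats is far beyond plausible noise fluctuation at these image sizes,
  while removing the bulk of a 576-orientation grid. Each frame's argmax
  always survives.
* **Multiple movies.** Independent movies share one transition matrix;
  sufficient statistics are summed across movies. Convergence: evidence
  gain below 1e−6 nats or 200 iterations.

## MSM reconstruction

The estimated state-level matrix is reduced to structures by
stationary-probability weighting,

    T_struct(i, j) = Σ_{s∈i} Σ_{s'∈j} p(s) T(s, s') / Σ_{s∈i} p(s),

which preserves equilibrium structure populations (uniform weighting is
available as an option). The constrained state-level chain can be
reducible (disconnected orientation clusters), so the weights come from
power iteration started at the uniform vector, which is deterministic and
well defined in that case. The reduced matrix is projected onto detailed
balance by flux symmetrization F_ij = (p_i T_ij + p_j T_ji)/2,
T′_ij = F_ij / Σ_j F_ij, which is a fixed point for already-reversible
models and preserves the stationary distribution. Structures absent from
the estimated state space keep an identity (self-loop) row with a logged
warning so the matrix stays comparable with a ground truth. Model accuracy
is scored by the relative entropy D(T‖T^est) = Σ p_i T_ij log(T_ij/(T^est_ij
+ ε)) with ε = 1e−10 added to the estimate only; terms with T_ij = 0
contribute zero.

## Twin-experiment generator

The generator emulates a twin experiment: simulate a known structure-level
Markov chain, render movies, refit them, and score recovery.

* **Ground-truth MSM.** A random reversible 10-state matrix built from a
  symmetric weight matrix with boosted diagonal (T_ii ≈ 0.4–0.6, metastable
  but mixing fast enough that a 5 × 20-frame dataset visits every state)
  and one kinetically isolated state whose couplings are scaled by 0.1.
* **Conformers.** A pseudo-symmetric two-lobed bead molecule: a large lobe
  (60 beads, 1.8 nm ball, z-elongated) and a small lobe (45 beads, 1.2 nm
  ball) on the y axis, with rugged surfaces from varied bead radii
  (0.2–0.56 nm). Conformers lie on an out-of-plane opening coordinate —
  the small lobe pitches about x (±0.8 rad) while the large lobe rolls
  about y (±0.5 rad) — chosen so that conformational differences change
  the *height profile* rather than the lateral footprint, and therefore
  cannot be absorbed by a translation. Mean pairwise unaligned RMSD is on
  the ~1 nm scale. The unequal lobes make a 180° flip subtly wrong: at the
  matched tip radius the likelihood resolves the asymmetry, at mismatched
  radii flipped orientations become competitive — the regime the HMM's
  rotational constraint is designed to rescue. Because the grid's fiber
  angles come in π-separated pairs, the exact flip of every grid
  orientation is itself a grid member.
* **Per-movie protocol.** One orientation drawn uniformly from the grid and
  held fixed for the whole movie (strong stage binding); a structure
  sequence from the MSM; lateral drift as a cumulative Gaussian random walk
  (0.1 nm/step/axis), **rounded to the pixel lattice at the imaging step**;
  i.i.d. Gaussian pixel noise (0.3 nm). All randomness derives from
  (master seed, movie index), making reports byte-reproducible.

The pixel-rounding of drift deserves emphasis. The translation search is
integer-pixel by construction (the maximum FFT slice). A genuinely
sub-pixel molecule position leaves a residual misfit worth hundreds of nats
at σ = 0.3 nm — larger than the likelihood separation between neighbouring
conformers of any realistically sized ensemble — and systematically favours
whichever conformer best mimics the unmodelled fraction of a pixel.
Near-perfect frame-wise recovery under this protocol is therefore only
possible when the rendered positions sit on the pixel lattice, so the
generator places them there. The consequence is a known limitation: the
twin experiment exercises structure/orientation discrimination, drift
tracking at pixel resolution, noise robustness and tip-radius sensitivity,
but it does **not** probe sub-pixel registration error, which real
instruments do exhibit.

* **Scoring.** Estimates are scored by unaligned RMSD: each structure is
  centred, rotated by its orientation quaternion, and compared bead-wise
  with no superposition (translations excluded — lateral position is not
  part of the state). Zero RMSD therefore requires the exact (m, φ) match.
  A frame counts as "flipped" when the estimated orientation is more than
  90° from the truth (quaternion distance > 0.5). Flip robustness is
  compared on the flipped-frame count summed over the mismatched fitting
  radii of the scan: at this reduced scale any single radius sits, for
  some datasets, in the regime where flips already dominate whole movies
  and majority rule cannot help, whereas the aggregate isolates the
  systematic ordering.
* **Bootstrap.** Transition-probability uncertainty is estimated by
  resampling whole movies with replacement (preserving within-movie
  correlation), re-running Baum-Welch per replicate from the same
  initialization, and reporting the per-entry spread of the
  structure-level matrices.

## Reduced problem sizes

The package's end-to-end validation runs a reduced-scale twin experiment —
5 movies × 20 frames, 10 conformers × 60 orientations, full 80 × 60 frames,
fitting radii {1.5, 2.0, 2.5, 3.2, 3.5} nm against a 2.5 nm ground truth —
chosen so the complete scan (data generation, ~600-state emission tables
for five radii, Baum-Welch, Viterbi, MSM reconstruction) completes in a few
minutes on one CPU while preserving the qualitative structure of the
full-scale protocol: near-perfect recovery at the matched radius,
flip-dominated failure at strongly mismatched radii, HMM rescue in between,
and a relative-entropy minimum at the generating radius. Quantities that
depend on absolute dataset size (e.g. the sharpness of the relative-entropy
minimum, flip counts) carry the sampling noise of 100-frame datasets and
are asserted as orderings, not values.

## Known limitations

* Rigid-body states only: no flexible fitting or refinement between grid
  orientations; accuracy is bounded by the grid resolution.
* The tip is an ideal hemisphere+cone; double tips, adhesion artifacts and
  tip damage are out of scope, as is estimating tip shape from data.
* Emissions are fixed during Baum-Welch; only transitions are learned.
* The synthetic conformers are smooth two-lobed bodies with a single
  dominant motion coordinate; real conformational ensembles are
  higher-dimensional and less cleanly separated, so passing twin tests
  bounds implementation correctness, not real-data performance.
* Sub-pixel registration is not modelled (see above).
* The detailed-balance projection is a post-processing step; Baum-Welch
  itself does not constrain reversibility.
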